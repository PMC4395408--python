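"""End-to-end orchestration: clean -> group -> filter -> mine -> validate -> report.

A run reads a claims CSV, executes the full pipeline with one parameter
set, and writes every artifact (rule-set JSON, cross-validation CSV,
chapter table, viewer report, optional novelty CSV, run log) into an
output directory. Every JSON/CSV artifact embeds a hash of the canonical
config, so identically configured runs are identical byte-for-byte apart
from nothing — timestamps live only in the log.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as claims_io
from .analysis import chapter_distribution, chapter_table_frame, viewer_report
from .classify import metrics
from .core import RA
from .literature import FixtureClient, assess_rule_novelty
from .mining import RuleSet
from .preprocessing import assign_groups, clean, filter_by_record_count, to_transactions
from .validation import (
    DEFAULT_MIN_RECORDS_GRID,
    DEFAULT_SUPPORT_GRID,
    MiningParams,
    cross_validate,
    sweep_min_records,
    sweep_support,
)

logger = logging.getLogger("riskminer")


@dataclass
class RunConfig:
    """Parameters of one full pipeline run (defaults = production settings)."""

    claims_path: str = "claims.csv"
    out_dir: str = "run"
    window: tuple[str, str] = ("1997-01-01", "2008-12-31")
    min_records: int = 15
    min_sup_frac: float = 0.007
    min_conf: float = 0.5
    chi2_threshold: float = 3.84
    coverage_delta: int = 4
    max_len: int = 3
    k: int = 10
    seed: int = 0
    run_sweeps: bool = False
    novelty: str = "off"  # off | fixture | live
    novelty_fixture: str | None = None
    novelty_threshold: int = 0
    novelty_email: str = ""
    novelty_top: int = 20

    def mining_params(self) -> MiningParams:
        return MiningParams(
            min_sup_frac=self.min_sup_frac,
            min_conf=self.min_conf,
            chi2_threshold=self.chi2_threshold,
            coverage_delta=self.coverage_delta,
            max_len=self.max_len,
        )

    def config_hash(self) -> str:
        # hash the analysis-relevant configuration; the output location is
        # not part of a run's identity
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_csv(frame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, index=False)


def _write_json(obj, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        json.dump({"config_hash": config_hash, **obj}, fh, indent=1, sort_keys=True)


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s", chash)
        logger.info("config %s", json.dumps(dataclasses.asdict(config), sort_keys=True))

        claims = Path(config.claims_path)
        if not claims.exists():
            raise FileNotFoundError(f"claims file not found: {claims}")
        records = claims_io.read_claims_csv(claims)
        logger.info("read %d rows", len(records))

        kept, rejected = clean(records)
        reasons: dict[str, int] = {}
        for _, reason in rejected:
            reasons[reason] = reasons.get(reason, 0) + 1
        logger.info("cleaning kept %d rejected %d %s", len(kept), len(rejected), reasons)

        window = (
            dt.date.fromisoformat(config.window[0]),
            dt.date.fromisoformat(config.window[1]),
        )
        histories = assign_groups(kept, window)
        filtered = filter_by_record_count(histories, config.min_records)
        db = to_transactions(filtered)
        if len(db.class_counts) < 2:
            raise ValueError("degenerate cohort: fewer than two classes after filtering")
        logger.info("cohort: %s", db.class_counts)
        db.to_jsonl(out / "transactions.jsonl")

        params = config.mining_params()
        cv = cross_validate(db, k=config.k, params=params, seed=config.seed)
        _write_csv(cv.frame(), out / "cv_metrics.csv", chash)
        logger.info(
            "CV avg sensitivity %.3f avg specificity %.3f",
            cv.avg_sensitivity if cv.avg_sensitivity is not None else float("nan"),
            cv.avg_specificity if cv.avg_specificity is not None else float("nan"),
        )

        if config.run_sweeps:
            sw = sweep_support(db, DEFAULT_SUPPORT_GRID, config.k, params, config.seed)
            _write_csv(sw.frame(), out / "sweep_support.csv", chash)
            _write_json(sw.summary(), out / "sweep_support.json", chash)
            sw2, retained = sweep_min_records(
                histories, DEFAULT_MIN_RECORDS_GRID, config.k, params, config.seed
            )
            _write_csv(sw2.frame(), out / "sweep_min_records.csv", chash)
            _write_json(
                {**sw2.summary(), "retained": retained},
                out / "sweep_min_records.json",
                chash,
            )

        # final model on the full cohort
        clf = params.classifier()
        clf.fit([t.items for t in db], [t.label for t in db])
        ruleset: RuleSet = clf.rules_
        ruleset.params["config_hash"] = chash
        with open(out / "ruleset.json", "w") as fh:
            fh.write(ruleset.to_json())
        logger.info("final rule set: %d rules", len(ruleset))

        rows = chapter_distribution(ruleset)
        _write_csv(chapter_table_frame(rows), out / "chapter_table.csv", chash)
        _write_json(viewer_report(ruleset, db), out / "viewer_report.json", chash)

        resub = clf.confusion_matrix([t.items for t in db], [t.label for t in db])
        _write_json(
            {
                "class_counts": db.class_counts,
                "n_rules": len(ruleset),
                "cv_avg_sensitivity": cv.avg_sensitivity,
                "cv_avg_specificity": cv.avg_specificity,
                "resubstitution": metrics(resub),
            },
            out / "summary.json",
            chash,
        )

        if config.novelty != "off":
            _novelty_pass(config, ruleset, out, chash)
        logger.info("run complete: %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


def _novelty_pass(config: RunConfig, ruleset: RuleSet, out: Path, chash: str) -> None:
    import pandas as pd

    if config.novelty == "fixture":
        if not config.novelty_fixture:
            raise ValueError("novelty=fixture requires novelty_fixture path")
        client = FixtureClient(path=config.novelty_fixture)
    elif config.novelty == "live":
        from .literature import EntrezClient

        client = EntrezClient(email=config.novelty_email)
    else:
        raise ValueError(f"unknown novelty mode {config.novelty!r}")

    ra_rules = [r for r in ruleset.rules if r.consequent == RA]
    ra_rules = ra_rules[: config.novelty_top]
    rows = []
    for rule in ra_rules:
        res = assess_rule_novelty(
            rule, "Rheumatoid arthritis", client, config.novelty_threshold
        )
        rows.append(
            {
                "pattern": ";".join(sorted(rule.antecedent)),
                "diseases": ";".join(res.pattern),
                "joint_count": res.joint_count,
                "single_counts": ";".join(map(str, res.single_disease_counts)),
                "novelty_type": res.novelty_type,
            }
        )
    _write_csv(pd.DataFrame(rows), out / "novelty.csv", chash)
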