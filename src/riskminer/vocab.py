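"""Packaged ICD-9-CM vocabulary used by the synthetic generator and reports.

A small curated pool of common outpatient diagnosis codes spanning the 17
numeric ICD-9-CM chapters, with sampling weights loosely reflecting primary
care visit frequency, plus short human-readable descriptions for report and
literature-query construction. Real claims carry thousands of codes; this
pool only needs to exercise every chapter and give patterns plausible names.
"""

from __future__ import annotations

#: (code, sampling weight). Weights are relative, not normalised.
DEFAULT_BACKGROUND_POOL: list[tuple[str, float]] = [
    # 001-139 infectious and parasitic
    ("034.0", 2.0), ("054.9", 1.0), ("110.1", 1.0),
    # 140-239 neoplasms
    ("173.3", 0.5), ("217", 0.5), ("211.3", 0.5),
    # 240-279 endocrine, metabolic, immunity
    ("250.00", 3.0), ("272.4", 2.5), ("244.9", 1.0), ("274.9", 1.0),
    # 280-289 blood
    ("280.9", 1.0), ("285.9", 1.0),
    # 290-319 psychiatric
    ("300.00", 2.0), ("300.4", 1.5), ("311", 1.5), ("307.42", 1.0),
    # 320-389 nervous system and sense organs
    ("354.0", 1.5), ("366.9", 1.5), ("372.30", 1.5), ("386.00", 0.8),
    ("388.30", 0.8),
    # 390-459 circulatory
    ("401.9", 3.5), ("414.01", 1.5), ("424.0", 0.8), ("427.31", 0.8),
    ("455.6", 1.0),
    # 460-519 respiratory
    ("460", 5.0), ("462", 3.5), ("466.0", 3.0), ("477.9", 2.5),
    ("461.9", 1.5), ("464.00", 1.2), ("463", 1.5), ("493.90", 1.5),
    # 520-579 digestive
    ("521.00", 3.0), ("522.0", 1.5), ("523.40", 1.5), ("535.50", 2.5),
    ("530.81", 1.5), ("558.9", 2.5), ("564.00", 1.5), ("571.40", 0.8),
    # 580-629 genitourinary
    ("599.0", 2.0), ("595.0", 1.2), ("616.10", 1.2), ("614.9", 0.8),
    ("626.4", 1.0), ("627.2", 1.0),
    # 630-679 pregnancy/childbirth
    ("650", 0.4),
    # 680-709 skin
    ("682.9", 1.2), ("691.8", 1.2), ("692.9", 2.0), ("708.9", 1.0),
    # 710-739 musculoskeletal
    ("710.2", 0.4), ("715.90", 2.0), ("716.90", 1.5), ("719.40", 2.5),
    ("723.1", 1.8), ("724.2", 2.5), ("726.90", 1.2), ("727.00", 1.2),
    ("729.0", 1.0), ("729.1", 1.8), ("733.00", 1.2),
    # 740-759 congenital
    ("745.5", 0.2),
    # 780-799 symptoms, signs
    ("780.79", 1.5), ("780.4", 1.2), ("784.0", 2.0), ("786.2", 2.0),
    ("787.01", 1.0),
    # 800-999 injury and poisoning
    ("845.00", 1.5), ("847.0", 1.2), ("924.9", 1.0), ("959.9", 1.0),
]

#: Short disease/symptom descriptions for the pool (used in reports and
#: PubMed [TIAB] query construction for synthetic patterns).
CODE_NAMES: dict[str, str] = {
    "034.0": "Streptococcal sore throat",
    "054.9": "Herpes simplex",
    "110.1": "Dermatophytosis of nail",
    "173.3": "Skin neoplasm of face",
    "217": "Benign neoplasm of breast",
    "211.3": "Benign neoplasm of colon",
    "250.00": "Diabetes mellitus type II",
    "272.4": "Hyperlipidemia",
    "244.9": "Hypothyroidism",
    "274.9": "Gout",
    "280.9": "Iron deficiency anemia",
    "285.9": "Anemia",
    "300.00": "Anxiety state",
    "300.4": "Neurotic depression",
    "311": "Depressive disorder",
    "307.42": "Persistent insomnia",
    "354.0": "Carpal tunnel syndrome",
    "366.9": "Cataract",
    "372.30": "Conjunctivitis",
    "386.00": "Meniere's disease",
    "388.30": "Tinnitus",
    "401.9": "Essential hypertension",
    "414.01": "Coronary atherosclerosis",
    "424.0": "Mitral valve disorders",
    "427.31": "Atrial fibrillation",
    "455.6": "Hemorrhoids",
    "460": "Acute nasopharyngitis",
    "462": "Acute pharyngitis",
    "466.0": "Acute bronchitis",
    "477.9": "Allergic rhinitis",
    "461.9": "Acute sinusitis",
    "464.00": "Acute laryngitis",
    "463": "Acute tonsillitis",
    "493.90": "Asthma",
    "521.00": "Dental caries",
    "522.0": "Pulpitis",
    "523.40": "Periodontitis",
    "535.50": "Gastritis and duodenitis",
    "530.81": "Esophageal reflux",
    "558.9": "Gastroenteritis and colitis",
    "564.00": "Constipation",
    "571.40": "Chronic hepatitis",
    "599.0": "Urinary tract infection",
    "595.0": "Acute cystitis",
    "616.10": "Vaginitis and vulvovaginitis",
    "614.9": "Inflammatory disease of female pelvic organs",
    "626.4": "Irregular menstrual cycle",
    "627.2": "Menopausal disorder",
    "650": "Normal delivery",
    "682.9": "Cellulitis",
    "691.8": "Atopic dermatitis",
    "692.9": "Eczema",
    "708.9": "Urticaria",
    "710.2": "Sicca syndrome",
    "715.90": "Osteoarthrosis",
    "716.90": "Arthropathy",
    "719.40": "Joint pain",
    "723.1": "Cervicalgia",
    "724.2": "Lumbago",
    "726.90": "Enthesopathy",
    "727.00": "Synovitis and tenosynovitis",
    "729.0": "Rheumatism",
    "729.1": "Myalgia and myositis",
    "733.00": "Osteoporosis",
    "745.5": "Ostium secundum atrial septal defect",
    "780.79": "Malaise and fatigue",
    "780.4": "Dizziness",
    "784.0": "Headache",
    "786.2": "Cough",
    "787.01": "Nausea with vomiting",
    "845.00": "Ankle sprain",
    "847.0": "Neck sprain",
    "924.9": "Contusion",
    "959.9": "Injury, unspecified",
    "714.0": "Rheumatoid arthritis",
    # codes outside the default background pool, available for planted
    # signal patterns (zero background rate keeps planted statistics exact)
    "135": "Sarcoidosis",
    "390": "Rheumatic fever",
    "245.2": "Chronic lymphocytic thyroiditis",
    "443.0": "Raynaud's syndrome",
    "696.1": "Psoriasis",
    "710.0": "Systemic lupus erythematosus",
    "719.0": "Effusion of joint",
}


def code_name(code: str) -> str:
    """Description for a code, falling back to the code string itself."""
    return CODE_NAMES.get(code, code)
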