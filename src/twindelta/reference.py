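"""Published benchmark values for the two-cohort adult twin study design.

These are the printed per-trait intraclass correlations of the change score
(MZ and DZ) and the full/best biometric model assignments reported for a
Danish (226 MZ + 276 DZ complete pairs) and a Chinese (101 MZ + 80 DZ pairs)
adult metabolic twin cohort.  They serve as desk-check inputs: applying the
ICC rule (ADE iff rMZ > 2·rDZ) to the printed ICC pairs must reproduce the
published full-model column for every trait.
"""

from __future__ import annotations

from .biometric import choose_full_model_icc

__all__ = [
    "TRAITS",
    "REFERENCE_ICC",
    "REFERENCE_FULL_MODEL",
    "REFERENCE_BEST_MODEL",
    "icc_rule_assignments",
    "count_full_models",
]

TRAITS = ["TC", "TG", "HDL", "LDL", "GLU", "WT", "BMI", "WAIST", "HIP", "WHR", "SBP", "DBP"]

#: printed (ICC_MZ, ICC_DZ) of the change score per cohort and trait
REFERENCE_ICC = {
    "danish": {
        "TC": (0.50, 0.18),
        "TG": (0.29, 0.26),
        "HDL": (0.47, 0.12),
        "LDL": (0.51, 0.20),
        "GLU": (0.42, 0.12),
        "WT": (0.40, 0.17),
        "BMI": (0.41, 0.16),
        "WAIST": (0.41, 0.13),
        "HIP": (0.44, 0.41),
        "WHR": (0.48, 0.13),
        "SBP": (0.36, 0.20),
        "DBP": (0.49, 0.17),
    },
    "chinese": {
        "TC": (0.54, 0.29),
        "TG": (0.58, 0.37),
        "HDL": (0.68, 0.63),
        "LDL": (0.53, 0.34),
        "GLU": (0.56, 0.41),
        "WT": (0.38, 0.35),
        "BMI": (0.27, 0.35),
        "WAIST": (0.37, 0.46),
        "HIP": (0.36, 0.42),
        "WHR": (0.49, 0.43),
        "SBP": (0.30, 0.10),
        "DBP": (0.32, 0.23),
    },
}

#: published full-model column per cohort and trait
REFERENCE_FULL_MODEL = {
    "danish": {
        "TC": "ADE", "TG": "ACE", "HDL": "ADE", "LDL": "ADE", "GLU": "ADE",
        "WT": "ADE", "BMI": "ADE", "WAIST": "ADE", "HIP": "ACE", "WHR": "ADE",
        "SBP": "ACE", "DBP": "ADE",
    },
    "chinese": {
        "TC": "ACE", "TG": "ACE", "HDL": "ACE", "LDL": "ACE", "GLU": "ACE",
        "WT": "ACE", "BMI": "ACE", "WAIST": "ACE", "HIP": "ACE", "WHR": "ACE",
        "SBP": "ADE", "DBP": "ACE",
    },
}

#: published best-fitting model per cohort and trait
REFERENCE_BEST_MODEL = {
    "danish": {
        "TC": "AE", "TG": "CE", "HDL": "AE", "LDL": "AE", "GLU": "AE",
        "WT": "AE", "BMI": "AE", "WAIST": "AE", "HIP": "CE", "WHR": "AE",
        "SBP": "AE", "DBP": "AE",
    },
    "chinese": {
        "TC": "AE", "TG": "AE", "HDL": "CE", "LDL": "AE", "GLU": "AE",
        "WT": "CE", "BMI": "CE", "WAIST": "CE", "HIP": "CE", "WHR": "CE",
        "SBP": "AE", "DBP": "CE",
    },
}


def icc_rule_assignments(cohort: str) -> dict:
    """Full model per trait from the ICC rule applied to the printed ICC pairs."""
    return {
        trait: choose_full_model_icc(rmz, rdz)
        for trait, (rmz, rdz) in REFERENCE_ICC[cohort].items()
    }


def count_full_models(cohort: str, model: str) -> int:
    """How many traits the ICC rule assigns to ``model`` in ``cohort``."""
    return sum(1 for m in icc_rule_assignments(cohort).values() if m == model)
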