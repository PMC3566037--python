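"""Raw-scale calibration moments for the synthetic cohort.

Per-sex means and SDs of the measured quantities in the ALSPAC-like analytic
sample that the generator emulates (gestational age in weeks, masses in kg,
lengths/heights in cm, ages in months, blood pressures in mmHg).  These
anchor the synthetic reference tables and the back-construction of raw
columns from structural z-scores.
"""

from __future__ import annotations

# (mean, sd) per sex
TABLE1_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "male": {
        "gest_age_wk": (39.4, 1.8),
        "bw_kg": (3.49, 0.55),
        "blen_cm": (51.1, 2.4),
        "age7_mo": (89.7, 2.1),
        "wt7_kg": (25.5, 4.1),
        "ht7_cm": (126.0, 5.2),
        "age9_mo": (118.5, 3.9),
        "wt9_kg": (34.3, 6.8),
        "ht9_cm": (140.0, 6.0),
        "lm9_kg": (25.5, 2.9),
        "fm9_kg": (7.3, 4.6),
        "sbp": (102.5, 9.0),
        "dbp": (57.2, 6.4),
        "pp": (45.3, 7.6),
    },
    "female": {
        "gest_age_wk": (39.6, 1.7),
        "bw_kg": (3.39, 0.49),
        "blen_cm": (50.4, 2.2),
        "age7_mo": (89.7, 2.1),
        "wt7_kg": (25.6, 4.4),
        "ht7_cm": (125.1, 5.3),
        "age9_mo": (118.4, 3.9),
        "wt9_kg": (34.9, 7.5),
        "ht9_cm": (139.0, 6.0),
        "lm9_kg": (23.6, 3.1),
        "fm9_kg": (9.6, 4.9),
        "sbp": (102.9, 9.6),
        "dbp": (57.7, 6.4),
        "pp": (45.2, 7.9),
    },
}

SEXES = ("male", "female")

#: Enrolment arithmetic of the emulated analytic sample:
#: children with complete 9-year data, outliers removed, analysed.
ENROLLED_N = 6621
OUTLIERS_REMOVED_N = 42
ANALYTIC_N = {"male": 3261, "female": 3318}


def implied_bp_correlation(sex: str) -> float:
    """Correlation between systolic and diastolic BP implied by the
    calibration SDs through var(PP) = var(SBP) + var(DBP) - 2 cov."""
    m = TABLE1_MOMENTS[sex]
    ss, sd_, sp = m["sbp"][1], m["dbp"][1], m["pp"][1]
    return (ss**2 + sd_**2 - sp**2) / (2.0 * ss * sd_)
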