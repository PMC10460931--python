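"""Worked-example cohorts reproducing published validation-cohort tables.

These are synthetic stand-ins, not patient data: records are laid out in
contiguous blocks so that every indicator stratum has exactly the stratum
size and death count printed in the source tables, which makes the
case-fatality percentages computed by :func:`pmvalidate.cohort_summary`
reproduce the published figures exactly. Joint structure beyond the printed
margins (e.g. which deaths were both hypoxemic and malnourished) is
arbitrary.
"""

from __future__ import annotations

import numpy as np

from .cohort import PatientRecord

__all__ = ["pneumonia_validation_cohort", "infection_validation_cohort"]


def _block_flags(n_total: int, n_died_total: int, died_n: int, surv_n: int,
                 died_start: int = 0, surv_start: int = 0) -> np.ndarray:
    """Indicator with ``died_n`` members among the deaths (rows
    0..n_died_total) and ``surv_n`` among the survivors."""
    flags = np.zeros(n_total, bool)
    flags[died_start:died_start + died_n] = True
    s0 = n_died_total + surv_start
    flags[s0:s0 + surv_n] = True
    return flags


def pneumonia_validation_cohort() -> list[PatientRecord]:
    """50,669 admissions, 4,406 deaths, with the published pneumonia-cohort
    strata: female 22,184 (2,183 died), moderate hypoxemia 3,875 (284),
    severe hypoxemia 8,949 (1,253), moderate malnutrition 8,699 (711),
    severe malnutrition 3,042 (604), wheeze 6,666 (485), unconscious
    3,221 (1,281). Mutually exclusive grades use disjoint blocks."""
    n, d = 50_669, 4_406
    sev_hyp = _block_flags(n, d, 1_253, 7_696)
    mod_hyp = _block_flags(n, d, 284, 3_591, died_start=1_253, surv_start=7_696)
    sev_mal = _block_flags(n, d, 604, 2_438)
    mod_mal = _block_flags(n, d, 711, 7_988, died_start=604, surv_start=2_438)
    wheeze = _block_flags(n, d, 485, 6_181)
    unconscious = _block_flags(n, d, 1_281, 1_940)
    female = _block_flags(n, d, 2_183, 20_001)

    spo2 = np.where(sev_hyp, 85.0, np.where(mod_hyp, 91.0, 97.0))
    muac = np.where(sev_mal, 110.0, np.where(mod_mal, 125.0, 150.0))
    return [
        PatientRecord(
            patient_id=f"t2-{i:05d}",
            hospital_id="h01",
            age_months=12,
            sex="female" if female[i] else "male",
            outcome="died" if i < d else "survived",
            spo2_pct=float(spo2[i]),
            muac_mm=float(muac[i]),
            avpu="U" if unconscious[i] else "A",
            wheeze="yes" if wheeze[i] else "no",
            cough_or_difficulty_breathing="yes",
            danger_signs=frozenset({"chest_indrawing"}),
        )
        for i in range(n)
    ]


def infection_validation_cohort() -> list[PatientRecord]:
    """10,782 admissions, 570 deaths, with the published infection-cohort
    strata: female 4,508 (263 died), HIV positive 75 (12), abnormal
    Blantyre coma score 1,199 (236)."""
    n, d = 10_782, 570
    female = _block_flags(n, d, 263, 4_245)
    hiv = _block_flags(n, d, 12, 63)
    abnormal_bcs = _block_flags(n, d, 236, 963)
    return [
        PatientRecord(
            patient_id=f"t3-{i:05d}",
            hospital_id="h02",
            age_months=24,
            sex="female" if female[i] else "male",
            outcome="died" if i < d else "survived",
            bcs=4 if abnormal_bcs[i] else 5,
            hiv_positive="yes" if hiv[i] else "no",
            waz=-0.5,
            muac_mm=143.0,
            infection_suspected="yes",
        )
        for i in range(n)
    ]
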