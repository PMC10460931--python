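"""Patient records, eligibility rules, predictor encoding and cohort summaries.

One :class:`PatientRecord` is one hospital admission with the raw clinical
fields the validated models consume (SpO2, MUAC, weight-for-age z-score,
AVPU, Blantyre coma score, wheeze, danger signs, HIV status), plus general
exclusion flags and the in-hospital outcome.

Eligibility mirrors the validation cohorts' construction:

* general exclusions — burns, poisonings, trauma, children admitted during
  health-worker strikes, and healthy children accompanying sick babies are
  dropped before any model-specific rule;
* the pneumonia-score cohort (``risc``) — age 2-59 months with cough or
  difficulty breathing and at least one danger sign (or AVPU worse than
  voice); a sensitivity mode accepts a clinical pneumonia diagnosis instead;
* the infection-score cohort (``lowlaavar``) — age 6-60 months with proven
  or suspected infection, excluding diagnosed malnutrition, readmissions,
  cancer, heart conditions and non-infectious illness.

Encoders translate raw measurements into each model's predictors using the
published thresholds: hypoxemia moderate at SpO2 90-92%, severe below 90%;
malnutrition moderate at MUAC 11.5-13.5 cm, severe below 11.5 cm;
unconscious when AVPU is P or U; abnormal Blantyre coma score below 5 (or,
in a sensitivity mode, AVPU exactly V as a proxy).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

from .errors import CohortParseError, EmptyCohortError
from .models import EncodedPredictors

__all__ = [
    "PatientRecord",
    "CohortSummary",
    "DANGER_SIGNS",
    "GENERAL_EXCLUSION_FLAGS",
    "LOWLAAVAR_EXCLUSION_FLAGS",
    "apply_general_exclusions",
    "risc_eligible",
    "lowlaavar_eligible",
    "eligibility_fn",
    "encode_risc",
    "encode_lowlaavar",
    "encoder_fn",
    "cohort_summary",
    "read_cohort_csv",
    "write_cohort_csv",
]

DANGER_SIGNS = frozenset(
    {
        "central_cyanosis",
        "grunting",
        "chest_indrawing",
        "stridor",
        "inability_to_drink",
        "convulsion",
    }
)
GENERAL_EXCLUSION_FLAGS = frozenset(
    {"burn", "poisoning", "trauma", "strike_period", "accompanying_healthy"}
)
LOWLAAVAR_EXCLUSION_FLAGS = frozenset(
    {"malnutrition_dx", "readmission", "cancer", "heart_condition", "noninfectious_illness"}
)
ALL_EXCLUSION_FLAGS = GENERAL_EXCLUSION_FLAGS | LOWLAAVAR_EXCLUSION_FLAGS


@dataclass(frozen=True)
class PatientRecord:
    """One admission. Optional clinical fields use ``None`` for missing."""

    patient_id: str
    hospital_id: str
    age_months: int
    sex: str  # "male" | "female"
    outcome: str  # "died" | "survived"; outcome ascertainment is complete
    spo2_pct: float | None = None
    muac_mm: float | None = None
    waz: float | None = None
    avpu: str | None = None  # "A" | "V" | "P" | "U"
    bcs: int | None = None  # Blantyre coma score 0-5
    wheeze: str | None = None  # "yes" | "no"
    cough_or_difficulty_breathing: str = "no"
    danger_signs: frozenset[str] = frozenset()
    hiv_positive: str | None = None  # "yes" | "no"
    clinical_pneumonia_dx: str = "no"
    infection_suspected: str = "no"
    exclusion_flags: frozenset[str] = frozenset()

    def validate(self) -> list[str]:
        """Return a list of field-range violations (empty when clean)."""
        problems = []
        if self.age_months < 0:
            problems.append(f"age_months {self.age_months} < 0")
        if self.sex not in ("male", "female"):
            problems.append(f"sex {self.sex!r} not male/female")
        if self.outcome not in ("died", "survived"):
            problems.append(f"outcome {self.outcome!r} not died/survived")
        if self.spo2_pct is not None and not (0 <= self.spo2_pct <= 100):
            problems.append(f"spo2_pct {self.spo2_pct} outside 0-100")
        if self.muac_mm is not None and not (self.muac_mm > 0):
            problems.append(f"muac_mm {self.muac_mm} not positive")
        if self.avpu is not None and self.avpu not in ("A", "V", "P", "U"):
            problems.append(f"avpu {self.avpu!r} not in A/V/P/U")
        if self.bcs is not None and not (0 <= self.bcs <= 5):
            problems.append(f"bcs {self.bcs} outside 0-5")
        for fld in ("wheeze", "hiv_positive"):
            v = getattr(self, fld)
            if v is not None and v not in ("yes", "no"):
                problems.append(f"{fld} {v!r} not yes/no")
        for fld in ("cough_or_difficulty_breathing", "clinical_pneumonia_dx", "infection_suspected"):
            if getattr(self, fld) not in ("yes", "no"):
                problems.append(f"{fld} {getattr(self, fld)!r} not yes/no")
        bad_signs = set(self.danger_signs) - DANGER_SIGNS
        if bad_signs:
            problems.append(f"unknown danger signs {sorted(bad_signs)}")
        bad_flags = set(self.exclusion_flags) - ALL_EXCLUSION_FLAGS
        if bad_flags:
            problems.append(f"unknown exclusion flags {sorted(bad_flags)}")
        return problems


@dataclass
class CohortSummary:
    """Counts, per-stratum case-fatality ratios, and medians for a cohort."""

    n_total: int
    n_died: int
    strata: dict[str, tuple[int, int, float]]  # name -> (n, died, cfr_pct)
    medians: dict[str, tuple[float, float, float]]  # field -> (median, q1, q3)


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def apply_general_exclusions(records: Sequence[PatientRecord]) -> list[PatientRecord]:
    """Drop burns, poisonings, trauma, strike-period admissions and
    accompanying healthy children; order preserved."""
    return [r for r in records if not (r.exclusion_flags & GENERAL_EXCLUSION_FLAGS)]


def risc_eligible(record: PatientRecord, mode: str = "danger_sign") -> bool:
    """Pneumonia-cohort eligibility: age 2-59 months and pneumonia.

    ``danger_sign`` mode requires cough/difficulty breathing plus at least
    one danger sign or AVPU of P or U (the derivation study's definition);
    ``clinical_dx`` mode requires a clinical pneumonia diagnosis instead.
    """
    if not (2 <= record.age_months <= 59):
        return False
    if mode == "danger_sign":
        return record.cough_or_difficulty_breathing == "yes" and (
            bool(record.danger_signs) or record.avpu in ("P", "U")
        )
    if mode == "clinical_dx":
        return record.clinical_pneumonia_dx == "yes"
    raise ValueError(f"unknown eligibility mode {mode!r}")


def lowlaavar_eligible(record: PatientRecord) -> bool:
    """Infection-cohort eligibility: age 6-60 months, proven/suspected
    infection, no malnutrition diagnosis, readmission, cancer, heart
    condition or non-infectious illness."""
    return (
        6 <= record.age_months <= 60
        and record.infection_suspected == "yes"
        and not (record.exclusion_flags & LOWLAAVAR_EXCLUSION_FLAGS)
    )


def eligibility_fn(eligibility_id: str, mode: str = "danger_sign"):
    """Resolve an eligibility id to a predicate over records."""
    if eligibility_id == "risc":
        return lambda r: risc_eligible(r, mode=mode)
    if eligibility_id == "lowlaavar":
        return lowlaavar_eligible
    raise ValueError(f"unknown eligibility id {eligibility_id!r}")


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_risc(record: PatientRecord) -> EncodedPredictors:
    """Encode the pneumonia score's predictors from raw measurements.

    Hypoxemia: moderate iff 90 <= SpO2 <= 92, severe iff SpO2 < 90.
    Malnutrition: moderate iff 115 <= MUAC(mm) <= 135, severe iff MUAC < 115.
    Unconscious iff AVPU is P or U. Missing source fields propagate to
    ``missing`` for every predictor they feed.
    """
    enc = EncodedPredictors()
    if record.spo2_pct is None:
        enc.missing |= {"moderate_hypoxemia", "severe_hypoxemia"}
    else:
        enc.values["moderate_hypoxemia"] = float(90 <= record.spo2_pct <= 92)
        enc.values["severe_hypoxemia"] = float(record.spo2_pct < 90)
    if record.muac_mm is None:
        enc.missing |= {"moderately_malnourished", "severely_malnourished"}
    else:
        enc.values["moderately_malnourished"] = float(115 <= record.muac_mm <= 135)
        enc.values["severely_malnourished"] = float(record.muac_mm < 115)
    if record.avpu is None:
        enc.missing.add("unconscious")
    else:
        enc.values["unconscious"] = float(record.avpu in ("P", "U"))
    if record.wheeze is None:
        enc.missing.add("wheeze")
    else:
        enc.values["wheeze"] = float(record.wheeze == "yes")
    enc.values["female"] = float(record.sex == "female")
    return enc


def encode_lowlaavar(record: PatientRecord, bcs_source: str = "bcs") -> EncodedPredictors:
    """Encode the infection scores' predictors.

    ``bcs`` mode: abnormal_bcs iff Blantyre coma score < 5. ``avpu_proxy``
    mode: abnormal_bcs iff AVPU is exactly V (the sensitivity definition
    used where the coma score was not collected). HIV status, WAZ and MUAC
    pass through; missing sources propagate.
    """
    enc = EncodedPredictors()
    if bcs_source == "bcs":
        if record.bcs is None:
            enc.missing.add("abnormal_bcs")
        else:
            enc.values["abnormal_bcs"] = float(record.bcs < 5)
    elif bcs_source == "avpu_proxy":
        if record.avpu is None:
            enc.missing.add("abnormal_bcs")
        else:
            enc.values["abnormal_bcs"] = float(record.avpu == "V")
    else:
        raise ValueError(f"unknown bcs_source {bcs_source!r}")
    if record.hiv_positive is None:
        enc.missing.add("hiv_positive")
    else:
        enc.values["hiv_positive"] = float(record.hiv_positive == "yes")
    if record.waz is None:
        enc.missing.add("waz")
    else:
        enc.values["waz"] = float(record.waz)
    if record.muac_mm is None:
        enc.missing.add("muac_mm")
    else:
        enc.values["muac_mm"] = float(record.muac_mm)
    return enc


def encoder_fn(encoder_id: str, bcs_source: str = "bcs"):
    """Resolve an encoder id to a function over records."""
    if encoder_id == "risc":
        return encode_risc
    if encoder_id == "lowlaavar":
        return lambda r: encode_lowlaavar(r, bcs_source=bcs_source)
    raise ValueError(f"unknown encoder id {encoder_id!r}")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_SUMMARY_INDICATORS = {
    "risc": (
        "female",
        "moderate_hypoxemia",
        "severe_hypoxemia",
        "moderately_malnourished",
        "severely_malnourished",
        "wheeze",
        "unconscious",
    ),
    "lowlaavar": ("female", "hiv_positive", "abnormal_bcs"),
}
_SUMMARY_CONTINUOUS = {
    "risc": ("age_months", "spo2_pct", "muac_mm"),
    "lowlaavar": ("age_months", "waz", "muac_mm"),
}


def cohort_summary(records: Sequence[PatientRecord], encoder: str = "risc") -> CohortSummary:
    """Tabulate a cohort the way validation papers print it: total n and
    deaths, per-indicator stratum n/deaths/case-fatality percentage (one
    decimal, half away from zero), and median (IQR) for age and the
    continuous predictors."""
    if not records:
        raise EmptyCohortError("cohort_summary requires at least one record")
    enc_f = encoder_fn(encoder)
    died = np.array([r.outcome == "died" for r in records])
    encodings = [enc_f(r) for r in records]

    strata: dict[str, tuple[int, int, float]] = {}
    for name in _SUMMARY_INDICATORS[encoder]:
        if name == "female":
            flags = np.array([r.sex == "female" for r in records])
        else:
            flags = np.array([e.values.get(name) == 1.0 for e in encodings])
        n = int(flags.sum())
        if n == 0:
            continue
        d = int((flags & died).sum())
        strata[name] = (n, d, _round_half_up(100.0 * d / n))

    medians: dict[str, tuple[float, float, float]] = {}
    for fld in _SUMMARY_CONTINUOUS[encoder]:
        vals = np.array([getattr(r, fld) for r in records if getattr(r, fld) is not None], float)
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            medians[fld] = (float(med), float(q1), float(q3))

    return CohortSummary(
        n_total=len(records),
        n_died=int(died.sum()),
        strata=strata,
        medians=medians,
    )


# ---------------------------------------------------------------------------
# DataFrame bridge (bulk pipelines work on frames; records stay the API unit)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[PatientRecord]):
    """Tabulate records as a pandas DataFrame, one row per admission.

    Missing optional fields become NaN/None; set-valued fields become
    semicolon-joined strings (same convention as the CSV dialect).
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "hospital_id": [r.hospital_id for r in records],
            "age_months": [r.age_months for r in records],
            "sex": [r.sex for r in records],
            "outcome": [r.outcome for r in records],
            "spo2_pct": [np.nan if r.spo2_pct is None else r.spo2_pct for r in records],
            "muac_mm": [np.nan if r.muac_mm is None else r.muac_mm for r in records],
            "waz": [np.nan if r.waz is None else r.waz for r in records],
            "avpu": [r.avpu for r in records],
            "bcs": [np.nan if r.bcs is None else float(r.bcs) for r in records],
            "wheeze": [r.wheeze for r in records],
            "cough_or_difficulty_breathing": [r.cough_or_difficulty_breathing for r in records],
            "danger_signs": [";".join(sorted(r.danger_signs)) for r in records],
            "hiv_positive": [r.hiv_positive for r in records],
            "clinical_pneumonia_dx": [r.clinical_pneumonia_dx for r in records],
            "infection_suspected": [r.infection_suspected for r in records],
            "exclusion_flags": [";".join(sorted(r.exclusion_flags)) for r in records],
        }
    )


def frame_to_records(df) -> list[PatientRecord]:
    """Inverse of :func:`records_to_frame`."""
    import pandas as pd

    out = []
    for row in df.itertuples(index=False):
        out.append(
            PatientRecord(
                patient_id=str(row.patient_id),
                hospital_id=str(row.hospital_id),
                age_months=int(row.age_months),
                sex=row.sex,
                outcome=row.outcome,
                spo2_pct=None if pd.isna(row.spo2_pct) else float(row.spo2_pct),
                muac_mm=None if pd.isna(row.muac_mm) else float(row.muac_mm),
                waz=None if pd.isna(row.waz) else float(row.waz),
                avpu=None if (row.avpu is None or (isinstance(row.avpu, float) and pd.isna(row.avpu))) else row.avpu,
                bcs=None if pd.isna(row.bcs) else int(row.bcs),
                wheeze=None if (row.wheeze is None or (isinstance(row.wheeze, float) and pd.isna(row.wheeze))) else row.wheeze,
                cough_or_difficulty_breathing=row.cough_or_difficulty_breathing,
                danger_signs=frozenset(t for t in row.danger_signs.split(";") if t),
                hiv_positive=None if (row.hiv_positive is None or (isinstance(row.hiv_positive, float) and pd.isna(row.hiv_positive))) else row.hiv_positive,
                clinical_pneumonia_dx=row.clinical_pneumonia_dx,
                infection_suspected=row.infection_suspected,
                exclusion_flags=frozenset(t for t in row.exclusion_flags.split(";") if t),
            )
        )
    return out


def encode_frame(df, encoder_id: str, bcs_source: str = "bcs"):
    """Vectorised predictor encoding for a whole cohort frame.

    Returns a DataFrame with one column per predictor; rows whose source
    field is missing get NaN in the derived predictor columns. Threshold
    semantics are identical to :func:`encode_risc` / :func:`encode_lowlaavar`.
    """
    import pandas as pd

    out = pd.DataFrame(index=df.index)
    if encoder_id == "risc":
        spo2 = df["spo2_pct"].astype(float)
        out["moderate_hypoxemia"] = ((spo2 >= 90) & (spo2 <= 92)).astype(float).where(spo2.notna())
        out["severe_hypoxemia"] = (spo2 < 90).astype(float).where(spo2.notna())
        muac = df["muac_mm"].astype(float)
        out["moderately_malnourished"] = ((muac >= 115) & (muac <= 135)).astype(float).where(muac.notna())
        out["severely_malnourished"] = (muac < 115).astype(float).where(muac.notna())
        avpu = df["avpu"]
        out["unconscious"] = avpu.isin(["P", "U"]).astype(float).where(avpu.notna())
        wheeze = df["wheeze"]
        out["wheeze"] = (wheeze == "yes").astype(float).where(wheeze.notna())
        out["female"] = (df["sex"] == "female").astype(float)
    elif encoder_id == "lowlaavar":
        if bcs_source == "bcs":
            bcs = df["bcs"].astype(float)
            out["abnormal_bcs"] = (bcs < 5).astype(float).where(bcs.notna())
        elif bcs_source == "avpu_proxy":
            avpu = df["avpu"]
            out["abnormal_bcs"] = (avpu == "V").astype(float).where(avpu.notna())
        else:
            raise ValueError(f"unknown bcs_source {bcs_source!r}")
        hiv = df["hiv_positive"]
        out["hiv_positive"] = (hiv == "yes").astype(float).where(hiv.notna())
        out["waz"] = df["waz"].astype(float)
        out["muac_mm"] = df["muac_mm"].astype(float)
    else:
        raise ValueError(f"unknown encoder id {encoder_id!r}")
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id",
    "hospital_id",
    "age_months",
    "sex",
    "outcome",
    "spo2_pct",
    "muac_mm",
    "waz",
    "avpu",
    "bcs",
    "wheeze",
    "cough_or_difficulty_breathing",
    "danger_signs",
    "hiv_positive",
    "clinical_pneumonia_dx",
    "infection_suspected",
    "exclusion_flags",
]


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    """Write records in the shared cohort dialect (UTF-8, empty string for
    missing, semicolon-joined set fields)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.patient_id,
                    r.hospital_id,
                    r.age_months,
                    r.sex,
                    r.outcome,
                    "" if r.spo2_pct is None else repr(float(r.spo2_pct)),
                    "" if r.muac_mm is None else repr(float(r.muac_mm)),
                    "" if r.waz is None else repr(float(r.waz)),
                    r.avpu or "",
                    "" if r.bcs is None else r.bcs,
                    r.wheeze or "",
                    r.cough_or_difficulty_breathing,
                    ";".join(sorted(r.danger_signs)),
                    r.hiv_positive or "",
                    r.clinical_pneumonia_dx,
                    r.infection_suspected,
                    ";".join(sorted(r.exclusion_flags)),
                ]
            )


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; violations raise with row numbers."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(_CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise CohortParseError(
                f"missing columns: {sorted(missing_cols)}", row=1
            )
        for i, row in enumerate(reader, start=2):
            try:
                rec = PatientRecord(
                    patient_id=row["patient_id"],
                    hospital_id=row["hospital_id"],
                    age_months=int(row["age_months"]),
                    sex=row["sex"],
                    outcome=row["outcome"],
                    spo2_pct=float(row["spo2_pct"]) if row["spo2_pct"] else None,
                    muac_mm=float(row["muac_mm"]) if row["muac_mm"] else None,
                    waz=float(row["waz"]) if row["waz"] else None,
                    avpu=row["avpu"] or None,
                    bcs=int(row["bcs"]) if row["bcs"] else None,
                    wheeze=row["wheeze"] or None,
                    cough_or_difficulty_breathing=row["cough_or_difficulty_breathing"],
                    danger_signs=frozenset(t for t in row["danger_signs"].split(";") if t),
                    hiv_positive=row["hiv_positive"] or None,
                    clinical_pneumonia_dx=row["clinical_pneumonia_dx"],
                    infection_suspected=row["infection_suspected"],
                    exclusion_flags=frozenset(t for t in row["exclusion_flags"].split(";") if t),
                )
            except (ValueError, KeyError) as exc:
                raise CohortParseError(f"unparseable row: {exc}", row=i) from exc
            problems = rec.validate()
            if problems:
                raise CohortParseError("; ".join(problems), row=i)
            records.append(rec)
    return records
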