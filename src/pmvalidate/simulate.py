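"""Synthetic admission cohorts with known ground truth.

The real validation cohort is access-restricted, so every pipeline stage is
exercised on simulated cohorts that emulate its printed structure: predictor
prevalences (female 43.8%, wheeze 13.2%, unconscious 6.4%, moderate
hypoxemia 7.6%, severe 17.7%, moderate malnutrition 17.2%, severe 6.0%) and
field-level missingness (SpO2 41.3%, MUAC 49.8%, wheeze 2.6%, AVPU 3.0%).

SpO2 and MUAC are drawn as continuous values from component distributions
chosen so the induced category rates hit the configured prevalences exactly
in expectation — the encoder and post-imputation re-derivation of the
indicator categories are therefore genuinely exercised. Predictors are
independent except one built-in positive dependence: severe hypoxemia and
unconsciousness share an odds ratio of 2 (configurable), giving
missing-at-random imputation some signal to exploit.

Outcomes are drawn Bernoulli from a chosen true model with controllable
miscalibration: logit p = delta + gamma * lp_true. Positive delta makes the
true risks higher than the model's predictions, so a validation run should
recover a calibration intercept near delta (underestimation) and a slope
near gamma. A hidden truth table keeps the complete pre-masking values and
true risks for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import PatientRecord, encode_frame, frame_to_records
from .errors import InfeasiblePrevalenceError, RateInfeasibilityError, UnknownRecordError
from .models import ModelSpec, builtin_models

__all__ = [
    "GeneratorConfig",
    "MissingnessSpec",
    "DEFAULT_PREVALENCES",
    "DEFAULT_MISSINGNESS",
    "generate_cohort",
    "inject_missingness",
    "simulate_cohort",
    "true_risk",
]

DEFAULT_PREVALENCES = {
    "female": 0.438,
    "wheeze": 0.132,
    "unconscious": 0.064,
    "moderate_hypoxemia": 0.076,
    "severe_hypoxemia": 0.177,
    "moderately_malnourished": 0.172,
    "severely_malnourished": 0.060,
    "hiv_positive": 0.007,
    "avpu_v": 0.023,
    "cough": 0.90,
    "danger_sign": 0.80,
    "infection_suspected": 0.95,
    "general_exclusion": 0.01,
}


@dataclass(frozen=True)
class MissingnessSpec:
    rate: float
    mechanism: str = "MCAR"  # or "MAR"
    dependence: tuple[str, ...] = ()
    coefficients: tuple[float, ...] | None = None  # per dependence field; default 1


DEFAULT_MISSINGNESS = {
    "spo2_pct": MissingnessSpec(0.413),
    "muac_mm": MissingnessSpec(0.498),
    "wheeze": MissingnessSpec(0.026),
    "avpu": MissingnessSpec(0.030),
}


@dataclass
class GeneratorConfig:
    """Recipe for one synthetic cohort."""

    n: int = 10000
    seed: int = 0
    prevalences: dict = dc_field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    true_model: ModelSpec | str = "risc_malawi"
    intercept_shift: float = 0.0  # delta
    slope_scale: float = 1.0  # gamma
    missingness: dict = dc_field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    hypox_unconscious_or: float = 2.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.slope_scale < 0:
            raise ValueError("slope_scale (gamma) must be >= 0")
        for k, v in self.prevalences.items():
            if not (0 <= v <= 1):
                raise ValueError(f"prevalence {k}={v} outside [0, 1]")

    def resolved_model(self) -> ModelSpec:
        if isinstance(self.true_model, ModelSpec):
            return self.true_model
        return builtin_models()[self.true_model]


def _severe_given_consciousness(p_sev: float, p_unc: float, oratio: float):
    """Split a marginal severe-hypoxemia rate into conditional rates for
    unconscious vs conscious children at a given odds ratio."""
    if oratio == 1.0:
        return p_sev, p_sev

    def gap(b):
        odds_b = b / (1 - b)
        a = oratio * odds_b / (1 + oratio * odds_b)
        return p_unc * a + (1 - p_unc) * b - p_sev

    try:
        b = brentq(gap, 1e-9, 1 - 1e-9)
    except ValueError as exc:
        raise InfeasiblePrevalenceError(
            f"no conditional split for severe={p_sev}, unconscious={p_unc}, OR={oratio}"
        ) from exc
    odds_b = b / (1 - b)
    a = oratio * odds_b / (1 + oratio * odds_b)
    return a, b


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal; fast for mild truncation."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: GeneratorConfig):
    """Draw a complete cohort plus its hidden truth table.

    Returns ``(records, truth)`` where truth is a DataFrame indexed by
    patient id holding the complete (pre-masking) fields, the true linear
    predictor and the true risk. Records returned here are complete;
    :func:`inject_missingness` applies the masking.
    """
    prev = {**DEFAULT_PREVALENCES, **config.prevalences}
    p_mod, p_sev = prev["moderate_hypoxemia"], prev["severe_hypoxemia"]
    if p_mod + p_sev >= 1:
        raise InfeasiblePrevalenceError("hypoxemia categories exceed probability 1")
    p_mmal, p_smal = prev["moderately_malnourished"], prev["severely_malnourished"]
    if p_mmal + p_smal >= 1:
        raise InfeasiblePrevalenceError("malnutrition categories exceed probability 1")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n

    age = np.clip(np.round(rng.lognormal(np.log(13), 0.913, n)), 0, 71).astype(int)
    female = rng.random(n) < prev["female"]
    unconscious = rng.random(n) < prev["unconscious"]
    p_unc = prev["unconscious"]

    # AVPU: P/U when unconscious, V at its marginal rate among the conscious
    avpu = np.where(rng.random(n) < 0.5, "P", "U")
    p_v_given_c = prev["avpu_v"] / (1 - p_unc) if p_unc < 1 else 0.0
    if p_v_given_c > 1:
        raise InfeasiblePrevalenceError("avpu_v rate infeasible given unconscious rate")
    conscious = ~unconscious
    v_draw = rng.random(n) < p_v_given_c
    avpu = np.where(conscious, np.where(v_draw, "V", "A"), avpu)

    # SpO2: severe rate split by consciousness at the configured odds ratio,
    # moderate assigned among the non-severe to keep its marginal exact
    a_sev, b_sev = _severe_given_consciousness(p_sev, p_unc, config.hypox_unconscious_or)
    severe = rng.random(n) < np.where(unconscious, a_sev, b_sev)
    moderate = (~severe) & (rng.random(n) < p_mod / (1 - p_sev))
    spo2 = np.empty(n)
    spo2[severe] = _truncated_normal(rng, 84.0, 6.0, 40.0, 89.9, severe.sum())
    spo2[moderate] = rng.uniform(90.0, 92.0, moderate.sum())
    normal_ox = ~(severe | moderate)
    spo2[normal_ox] = _truncated_normal(rng, 97.5, 2.0, 92.1, 100.0, normal_ox.sum())
    spo2 = np.round(spo2, 1)

    smal = rng.random(n) < p_smal
    mmal = (~smal) & (rng.random(n) < p_mmal / (1 - p_smal))
    muac = np.empty(n)
    muac[smal] = _truncated_normal(rng, 108.0, 6.0, 60.0, 114.9, smal.sum())
    muac[mmal] = rng.uniform(115.0, 135.0, mmal.sum())
    normal_mal = ~(smal | mmal)
    muac[normal_mal] = _truncated_normal(rng, 145.0, 9.0, 135.1, 220.0, normal_mal.sum())
    muac = np.round(muac, 1)

    waz = np.round(rng.normal(-0.5, 1.1, n), 2)
    hiv = rng.random(n) < prev["hiv_positive"]
    wheeze = rng.random(n) < prev["wheeze"]
    cough = rng.random(n) < prev["cough"]
    danger = rng.random(n) < prev["danger_sign"]
    infection = rng.random(n) < prev["infection_suspected"]

    # Blantyre coma score tied to the disability scale
    bcs = np.full(n, 5)
    bcs[avpu == "V"] = 4
    bcs[avpu == "P"] = rng.integers(2, 4, (avpu == "P").sum())
    bcs[avpu == "U"] = rng.integers(0, 2, (avpu == "U").sum())

    # clinical pneumonia diagnosis loosely tracks the danger-sign definition
    sign_pneumonia = cough & (danger | unconscious)
    dx = np.where(sign_pneumonia, rng.random(n) < 0.85, rng.random(n) < 0.15)

    excl = rng.random(n) < prev["general_exclusion"]
    excl_flag = rng.choice(["burn", "poisoning", "trauma"], n)

    df = pd.DataFrame(
        {
            "patient_id": [f"p{i:07d}" for i in range(n)],
            "hospital_id": rng.choice([f"h{j:02d}" for j in range(20)], n),
            "age_months": age,
            "sex": np.where(female, "female", "male"),
            "outcome": "survived",
            "spo2_pct": spo2,
            "muac_mm": muac,
            "waz": waz,
            "avpu": avpu,
            "bcs": bcs.astype(float),
            "wheeze": np.where(wheeze, "yes", "no"),
            "cough_or_difficulty_breathing": np.where(cough, "yes", "no"),
            "danger_signs": np.where(danger, "chest_indrawing", ""),
            "hiv_positive": np.where(hiv, "yes", "no"),
            "clinical_pneumonia_dx": np.where(dx, "yes", "no"),
            "infection_suspected": np.where(infection, "yes", "no"),
            "exclusion_flags": np.where(excl, excl_flag, ""),
        }
    )

    model = config.resolved_model()
    enc = encode_frame(df, model.encoder_id)
    lp = np.full(n, model.intercept)
    for name, beta in model.coefficients.items():
        lp = lp + beta * enc[name].to_numpy(float)
    risk = expit(config.intercept_shift + config.slope_scale * lp)
    died = rng.random(n) < risk
    df["outcome"] = np.where(died, "died", "survived")

    truth = df.copy().set_index("patient_id")
    truth["lp_true"] = lp
    truth["true_risk"] = risk

    return frame_to_records(df), truth


def inject_missingness(records: Sequence[PatientRecord], truth: pd.DataFrame,
                       config: GeneratorConfig) -> list[PatientRecord]:
    """Mask fields per the configured missingness spec; truth is untouched.

    MCAR masks uniformly at the configured rate. MAR masks with probability
    logistic(alpha + sum c_j z_j) over the standardized dependence fields
    (taken from the complete truth values), with alpha calibrated by root
    finding so the marginal rate is hit in expectation.
    """
    from .cohort import records_to_frame

    df = records_to_frame(list(records))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    tr = truth.loc[df["patient_id"]]

    for fld, spec in config.missingness.items():
        if spec.rate == 0:
            continue
        if spec.mechanism == "MCAR":
            mask = rng.random(len(df)) < spec.rate
        elif spec.mechanism == "MAR":
            if not spec.dependence:
                raise RateInfeasibilityError(f"MAR for {fld!r} needs dependence fields")
            coefs = spec.coefficients or tuple(1.0 for _ in spec.dependence)
            score = np.zeros(len(df))
            for c, dep in zip(coefs, spec.dependence):
                v = tr[dep]
                if v.dtype == object:
                    v = (v.isin(["yes", "died", "female", "P", "U"])).astype(float)
                z = np.asarray(v, float)
                sd = z.std()
                z = (z - z.mean()) / (sd if sd > 0 else 1.0)
                score += c * z

            def gap(alpha):
                return expit(alpha + score).mean() - spec.rate

            try:
                alpha = brentq(gap, -30, 30)
            except ValueError as exc:
                raise RateInfeasibilityError(
                    f"cannot calibrate MAR rate {spec.rate} for {fld!r}"
                ) from exc
            mask = rng.random(len(df)) < expit(alpha + score)
        else:
            raise ValueError(f"unknown mechanism {spec.mechanism!r}")
        df.loc[mask, fld] = None if df[fld].dtype == object else np.nan

    return frame_to_records(df)


def simulate_cohort(config: GeneratorConfig):
    """Generate a cohort and apply the configured missingness in one call."""
    records, truth = generate_cohort(config)
    return inject_missingness(records, truth, config), truth


def true_risk(truth: pd.DataFrame, record_id: str) -> float:
    """The generating-model risk for one record (complete, pre-masking)."""
    try:
        return float(truth.loc[record_id, "true_risk"])
    except KeyError as exc:
        raise UnknownRecordError(f"unknown record id {record_id!r}") from exc
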