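"""End-to-end external validation: exclusions -> eligibility -> multiple
imputation -> per-imputation scoring and metrics with bootstrap variance ->
Rubin pooling -> report.

The stage order mirrors how validation cohorts are built in practice:
general exclusions first, then the model-specific eligibility rule, then
imputation of the raw measurements, and only then encoding and scoring, so
the published threshold definitions are applied to completed data. Metrics
are computed in each completed dataset (point estimate plus bootstrap
variance) and combined with Rubin's rules; calibration curves are evaluated
on a common predicted-risk grid and averaged pointwise across imputations.

One master seed deterministically spawns the per-stage seeds, so a report
is reproducible from (records, model, options, seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .cohort import (
    PatientRecord,
    apply_general_exclusions,
    eligibility_fn,
    encode_frame,
    read_cohort_csv,
    records_to_frame,
    write_cohort_csv,
)
from .errors import EmptyCohortError
from .imputation import (
    ImputationConfig,
    imputation_diagnostics,
    mice_impute_frame,
    rubin_pool,
)
from .metrics import (
    _RISK_EPS,
    c_statistic,
    calibration_intercept,
    calibration_slope,
    classify_auc,
    flexible_calibration_curve,
)
from .models import ModelSpec
from .resampling import BootstrapConfig, bootstrap_ci

__all__ = [
    "ValidationReport",
    "run_external_validation",
    "write_report",
    "read_report",
    "read_cohort_csv",
    "write_cohort_csv",
]

_SOURCE_FIELDS = {
    ("risc", "bcs"): ["spo2_pct", "muac_mm", "avpu", "wheeze"],
    ("risc", "avpu_proxy"): ["spo2_pct", "muac_mm", "avpu", "wheeze"],
    ("lowlaavar", "bcs"): ["bcs", "hiv_positive", "waz", "muac_mm"],
    ("lowlaavar", "avpu_proxy"): ["avpu", "hiv_positive", "waz", "muac_mm"],
}


@dataclass
class ValidationReport:
    """Pooled external-validation results for one model on one cohort."""

    model: str
    n: int
    n_events: int
    eligibility_mode: str
    bcs_source: str
    auc: float
    auc_ci: tuple[float, float]
    auc_band: str
    cal_slope: float
    cal_slope_ci: tuple[float, float]
    cal_intercept: float
    cal_intercept_ci: tuple[float, float]
    curve: list[tuple[float, float]]
    diagnostics: dict = dc_field(default_factory=dict)
    stage_log: list[tuple[str, int]] = dc_field(default_factory=list)
    metadata: dict = dc_field(default_factory=dict)


def _lp_from_frame(df, model: ModelSpec, bcs_source: str) -> np.ndarray:
    enc = encode_frame(df, model.encoder_id, bcs_source=bcs_source)
    lp = np.full(len(df), model.intercept)
    for name, beta in model.coefficients.items():
        lp = lp + beta * enc[name].to_numpy(float)
    return lp


def _slope_metric(risks, outcomes):
    return calibration_slope(logit(np.clip(risks, _RISK_EPS, 1 - _RISK_EPS)), outcomes)


def _intercept_metric(risks, outcomes):
    return calibration_intercept(logit(np.clip(risks, _RISK_EPS, 1 - _RISK_EPS)), outcomes)


def run_external_validation(
    records: Sequence[PatientRecord],
    model: ModelSpec,
    *,
    eligibility_mode: str = "danger_sign",
    bcs_source: str = "bcs",
    imputation: ImputationConfig | None = None,
    bootstrap: BootstrapConfig | None = None,
    n_curve_points: int = 50,
    timestamp: str | None = None,
) -> ValidationReport:
    """Validate one model on a cohort and pool across imputations.

    Raises
    ------
    EmptyCohortError
        When no record survives exclusions and eligibility.
    """
    if not records:
        raise EmptyCohortError("no input records")
    imputation = imputation or ImputationConfig(m=5, n_iter=10, seed=0)
    bootstrap = bootstrap or BootstrapConfig(n_boot=200, seed=0)

    stage_log = [("input", len(records))]
    kept = apply_general_exclusions(list(records))
    stage_log.append(("general_exclusions", len(kept)))
    elig = eligibility_fn(model.eligibility_id, mode=eligibility_mode)
    eligible = [r for r in kept if elig(r)]
    stage_log.append(("eligibility", len(eligible)))
    if not eligible:
        raise EmptyCohortError(
            f"no records eligible for model {model.name!r} "
            f"(mode={eligibility_mode!r})"
        )

    master = np.random.SeedSequence(imputation.seed)
    imp_seed, boot_seed = (int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(2))

    df = records_to_frame(eligible)
    fields = _SOURCE_FIELDS[(model.encoder_id, bcs_source)]
    any_missing = bool(df[fields].isna().any().any())
    if any_missing:
        cfg = dataclasses.replace(imputation, seed=imp_seed)
        frames = mice_impute_frame(df, fields, cfg)
        stage_log.append(("imputation", len(frames)))
    else:
        frames = [df]
        stage_log.append(("imputation", 0))

    outcomes = (df["outcome"] == "died").to_numpy(int)
    m = imputation.m

    per_imp = {"auc": [], "slope": [], "intercept": []}
    per_var = {"auc": [], "slope": [], "intercept": []}
    all_risks = []
    for j, fr in enumerate(frames):
        lp = _lp_from_frame(fr, model, bcs_source)
        risks = expit(lp)
        all_risks.append(risks)
        for offset, (name, metric) in enumerate(
            (
                ("auc", c_statistic),
                ("slope", _slope_metric),
                ("intercept", _intercept_metric),
            )
        ):
            res = bootstrap_ci(metric, risks, outcomes,
                               BootstrapConfig(n_boot=bootstrap.n_boot,
                                               ci_level=bootstrap.ci_level,
                                               seed=boot_seed + 7919 * j + offset))
            per_imp[name].append(res.point)
            per_var[name].append(float(np.var(res.replicates, ddof=1)))
    if len(frames) == 1 and m > 1:  # complete data: m notional identical imputations
        for name in per_imp:
            per_imp[name] = per_imp[name] * m
            per_var[name] = per_var[name] * m

    pooled = {k: rubin_pool(per_imp[k], per_var[k], ci_level=bootstrap.ci_level)
              for k in per_imp}

    # curves on a common predicted-risk grid, averaged pointwise
    lo = min(r.min() for r in all_risks)
    hi = max(r.max() for r in all_risks)
    grid = expit(np.linspace(logit(max(lo, _RISK_EPS)), logit(min(hi, 1 - _RISK_EPS)),
                             n_curve_points))
    curves = []
    for fr, risks in zip(frames, all_risks):
        pts = flexible_calibration_curve(risks, outcomes, grid_risks=grid)
        curves.append([o for _, o in pts])
    curve = list(zip(grid.tolist(), np.mean(curves, axis=0).tolist()))

    diagnostics = {}
    if any_missing:
        for f in fields:
            col = df[f]
            if not col.isna().any():
                continue
            obs = _diag_numeric(col.dropna())
            imps = [_diag_numeric(fr.loc[col.isna(), f]) for fr in frames]
            diagnostics[f] = imputation_diagnostics(obs, imps)

    return ValidationReport(
        model=model.name,
        n=len(eligible),
        n_events=int(outcomes.sum()),
        eligibility_mode=eligibility_mode,
        bcs_source=bcs_source,
        auc=pooled["auc"].point,
        auc_ci=pooled["auc"].ci,
        auc_band=classify_auc(min(max(pooled["auc"].point, 0.0), 1.0)),
        cal_slope=pooled["slope"].point,
        cal_slope_ci=pooled["slope"].ci,
        cal_intercept=pooled["intercept"].point,
        cal_intercept_ci=pooled["intercept"].ci,
        curve=curve,
        diagnostics=diagnostics,
        stage_log=stage_log,
        metadata={
            "seed": imputation.seed,
            "m": m,
            "n_iter": imputation.n_iter,
            "n_boot": bootstrap.n_boot,
            "timestamp": timestamp,
        },
    )


def _diag_numeric(series):
    """Map a raw field column to numbers for the distribution diagnostic."""
    if series.dtype == object:
        return series.map({"yes": 1.0, "no": 0.0, "A": 0.0, "V": 1.0, "P": 2.0, "U": 3.0}).to_numpy(float)
    return series.to_numpy(float)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def write_report(report: ValidationReport, path, fmt: str = "json") -> None:
    """Persist a report. ``json`` writes one document with stable key order;
    ``csv`` writes a metric table at ``path`` and the curve next to it with
    a ``.curve.csv`` suffix."""
    if fmt == "json":
        doc = {"schema_version": _SCHEMA_VERSION, **dataclasses.asdict(report)}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        import csv as _csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = _csv.writer(fh)
            w.writerow(["metric", "point", "ci_lower", "ci_upper"])
            w.writerow(["auc", repr(report.auc), repr(report.auc_ci[0]), repr(report.auc_ci[1])])
            w.writerow(["cal_slope", repr(report.cal_slope),
                        repr(report.cal_slope_ci[0]), repr(report.cal_slope_ci[1])])
            w.writerow(["cal_intercept", repr(report.cal_intercept),
                        repr(report.cal_intercept_ci[0]), repr(report.cal_intercept_ci[1])])
        curve_path = str(path) + ".curve.csv"
        with open(curve_path, "w", newline="", encoding="utf-8") as fh:
            w = _csv.writer(fh)
            w.writerow(["predicted", "observed"])
            for p, o in report.curve:
                w.writerow([repr(p), repr(o)])
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path) -> ValidationReport:
    """Read a JSON report back into a :class:`ValidationReport`."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    doc.pop("schema_version", None)
    doc["auc_ci"] = tuple(doc["auc_ci"])
    doc["cal_slope_ci"] = tuple(doc["cal_slope_ci"])
    doc["cal_intercept_ci"] = tuple(doc["cal_intercept_ci"])
    doc["curve"] = [tuple(p) for p in doc["curve"]]
    doc["stage_log"] = [tuple(s) for s in doc["stage_log"]]
    return ValidationReport(**doc)
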