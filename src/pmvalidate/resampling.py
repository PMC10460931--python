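"""Bootstrap confidence intervals for scalar validation metrics.

Patients are resampled with replacement at the original cohort size and the
metric recomputed on each resample; the interval is the percentile interval
of the bootstrap distribution. Resamples that lose one of the outcome
classes (possible at low event rates) are redrawn up to ten times each and
otherwise skipped, with the skip count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PMValidateError

__all__ = ["BootstrapConfig", "BootstrapResult", "bootstrap_ci"]


@dataclass
class BootstrapConfig:
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    method: str = "percentile"

    def __post_init__(self):
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100 for CI output")
        if self.method != "percentile":
            raise ValueError(f"unsupported bootstrap method {self.method!r}")


@dataclass
class BootstrapResult:
    point: float
    lower: float
    upper: float
    n_skipped: int = 0
    replicates: np.ndarray | None = None

    def __iter__(self):  # unpack as (point, lower, upper)
        return iter((self.point, self.lower, self.upper))


def bootstrap_ci(metric, risks, outcomes, config: BootstrapConfig) -> BootstrapResult:
    """Percentile bootstrap CI for ``metric(risks, outcomes)``.

    The point estimate is the metric on the full data; any error it raises
    there propagates. Single-class resamples are redrawn (max 10 attempts)
    or skipped and counted in ``n_skipped``.
    """
    risks = np.asarray(risks, float)
    outcomes = np.asarray(outcomes)
    point = float(metric(risks, outcomes))
    rng = np.random.default_rng(config.seed)
    n = len(risks)
    stats = np.empty(config.n_boot)
    kept = 0
    skipped = 0
    for _ in range(config.n_boot):
        for _attempt in range(10):
            idx = rng.integers(0, n, n)
            yb = outcomes[idx]
            if yb.min() == yb.max():
                continue
            try:
                stats[kept] = metric(risks[idx], yb)
            except PMValidateError:
                continue  # e.g. separation in a calibration refit; redraw
            kept += 1
            break
        else:
            skipped += 1
    stats = stats[:kept]
    alpha = 1 - config.ci_level
    lower, upper = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(point, float(lower), float(upper), skipped, stats)
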