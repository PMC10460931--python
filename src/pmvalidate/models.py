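"""Registry of published pediatric in-hospital-mortality risk scores.

Each model is a logistic score: a published intercept beta0 and per-predictor
weights beta_i on the log-odds scale. Scoring a patient means encoding the
raw clinical measurements into the model's predictors (indicators in {0, 1}
or continuous values such as MUAC in mm or a weight-for-age z-score),
forming the linear predictor beta0 + sum(beta_i * x_i), and mapping it
through the logistic function to a predicted probability of dying in
hospital.

Four models ship built in:

``risc_malawi``
    Respiratory Index of Severity in Children, derived on Malawian children
    aged 2-59 months admitted with pneumonia. Predictors: hypoxemia grade
    (SpO2), malnutrition grade (MUAC), sex, wheeze, unconsciousness (AVPU).
``lowlaavar_primary`` / ``lowlaavar_2`` / ``lowlaavar_3``
    Three models derived on Ugandan children aged 6-60 months admitted with
    proven or suspected infection, built on abnormal Blantyre coma score,
    HIV status, weight-for-age z-score and MUAC.

The MUAC coefficient in the Lowlaavar models is interpreted per millimetre:
at the published weight (-0.03) a per-centimetre reading would leave the
baseline risk implausibly high for a well-nourished child, while per-mm
values reproduce sensible risks across the observed MUAC range (115-160 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from scipy.special import expit

from .errors import MissingPredictorError

__all__ = [
    "ModelSpec",
    "EncodedPredictors",
    "builtin_models",
    "linear_predictor",
    "predicted_risk",
    "model_to_json",
    "model_from_json",
]


@dataclass(frozen=True)
class ModelSpec:
    """A published prognostic model.

    Parameters
    ----------
    name
        Registry identifier, e.g. ``"risc_malawi"``.
    intercept
        beta0 on the log-odds scale.
    coefficients
        Map predictor name -> beta_i (log-odds per unit / per indicator).
    predictor_kinds
        Map predictor name -> ``"indicator"`` or ``"continuous"``.
    encoder_id
        Which cohort encoder produces this model's predictors.
    eligibility_id
        Which eligibility rule defines this model's validation cohort.
    derivation_auc
        ``(point, lower, upper)`` AUC reported by the derivation study;
        metadata only, not used in any computation.
    """

    name: str
    intercept: float
    coefficients: Mapping[str, float]
    predictor_kinds: Mapping[str, str]
    encoder_id: str
    eligibility_id: str
    derivation_auc: tuple[float, float, float] | None = None

    def __post_init__(self):
        missing_kinds = set(self.coefficients) - set(self.predictor_kinds)
        if missing_kinds:
            raise ValueError(
                f"coefficients without a declared kind: {sorted(missing_kinds)}"
            )


@dataclass
class EncodedPredictors:
    """Predictor values for one patient, plus the set that could not be derived.

    Indicator predictors are exactly 0 or 1 when present; continuous
    predictors carry the raw measurement. ``missing`` lists predictor names
    whose source field was absent.
    """

    values: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)


_BUILTINS: dict[str, ModelSpec] = {
    "risc_malawi": ModelSpec(
        name="risc_malawi",
        intercept=-4.67,
        coefficients={
            "moderate_hypoxemia": 0.43,
            "severe_hypoxemia": 1.62,
            "moderately_malnourished": 0.55,
            "severely_malnourished": 1.53,
            "female": 0.22,
            "wheeze": -0.35,
            "unconscious": 1.74,
        },
        predictor_kinds={
            "moderate_hypoxemia": "indicator",
            "severe_hypoxemia": "indicator",
            "moderately_malnourished": "indicator",
            "severely_malnourished": "indicator",
            "female": "indicator",
            "wheeze": "indicator",
            "unconscious": "indicator",
        },
        encoder_id="risc",
        eligibility_id="risc",
        derivation_auc=(0.79, 0.76, 0.82),
    ),
    "lowlaavar_primary": ModelSpec(
        name="lowlaavar_primary",
        intercept=-4.280,
        coefficients={"abnormal_bcs": 2.51, "hiv_positive": 1.32, "waz": -0.2},
        predictor_kinds={
            "abnormal_bcs": "indicator",
            "hiv_positive": "indicator",
            "waz": "continuous",
        },
        encoder_id="lowlaavar",
        eligibility_id="lowlaavar",
        derivation_auc=(0.85, 0.80, 0.89),
    ),
    "lowlaavar_2": ModelSpec(
        name="lowlaavar_2",
        intercept=-0.523,
        coefficients={"abnormal_bcs": 2.54, "hiv_positive": 2.27, "muac_mm": -0.03},
        predictor_kinds={
            "abnormal_bcs": "indicator",
            "hiv_positive": "indicator",
            "muac_mm": "continuous",
        },
        encoder_id="lowlaavar",
        eligibility_id="lowlaavar",
        derivation_auc=(0.84, 0.79, 0.89),
    ),
    "lowlaavar_3": ModelSpec(
        name="lowlaavar_3",
        intercept=0.303,
        coefficients={"abnormal_bcs": 2.47, "muac_mm": -0.03},
        predictor_kinds={"abnormal_bcs": "indicator", "muac_mm": "continuous"},
        encoder_id="lowlaavar",
        eligibility_id="lowlaavar",
        derivation_auc=(0.82, 0.72, 0.91),
    ),
}


def builtin_models() -> dict[str, ModelSpec]:
    """Return the four built-in model specs, keyed by name."""
    return dict(_BUILTINS)


def linear_predictor(model: ModelSpec, enc: EncodedPredictors) -> float:
    """beta0 + sum(beta_i * x_i) for one encoded patient.

    Raises
    ------
    MissingPredictorError
        If any predictor the model weights is absent from the encoding.
    """
    needed = set(model.coefficients)
    absent = (needed & enc.missing) | (needed - set(enc.values))
    if absent:
        raise MissingPredictorError(absent)
    lp = model.intercept
    for name, beta in model.coefficients.items():
        x = enc.values[name]
        if model.predictor_kinds[name] == "indicator" and x not in (0, 1):
            raise ValueError(f"indicator predictor {name!r} must be 0 or 1, got {x}")
        lp += beta * x
    return lp


def predicted_risk(model: ModelSpec, enc: EncodedPredictors) -> float:
    """Predicted in-hospital mortality probability, logistic(linear predictor)."""
    return float(expit(linear_predictor(model, enc)))


def model_to_json(model: ModelSpec) -> str:
    """Serialize a spec to a JSON document (users can register new models)."""
    doc = {
        "name": model.name,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "predictor_kinds": dict(model.predictor_kinds),
        "encoder_id": model.encoder_id,
        "eligibility_id": model.eligibility_id,
        "derivation_auc": list(model.derivation_auc) if model.derivation_auc else None,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def model_from_json(text: str) -> ModelSpec:
    """Inverse of :func:`model_to_json`."""
    doc = json.loads(text)
    auc = doc.get("derivation_auc")
    return ModelSpec(
        name=doc["name"],
        intercept=float(doc["intercept"]),
        coefficients={k: float(v) for k, v in doc["coefficients"].items()},
        predictor_kinds=dict(doc["predictor_kinds"]),
        encoder_id=doc["encoder_id"],
        eligibility_id=doc["eligibility_id"],
        derivation_auc=tuple(auc) if auc else None,
    )
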