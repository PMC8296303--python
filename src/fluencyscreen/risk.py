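"""Weighted-sum logistic risk score and screening classification.

The screening instrument combines demographics with four of the fluency
indices in a fixed, previously estimated logistic equation:

    ws = b0 + b_sex*sex + b_age*age + b_edu*education
         - |b_fh|*first_half - |b_sw|*switching - |b_cl|*clustering
         + b_pe*perseveration

Higher ws means more AD-like. ws is a logit; ``ws_probability`` maps it to
a probability via the standard logistic function, and ``classify`` screens
positive when ws is at or above the cutoff (ties positive: a screening
instrument errs toward sensitivity). Total, second-half and intrusion
scores are deliberately not part of the equation and are never added.

Coefficients are data, not code. Two presets ship:

``sex_age``
    0.474 multiplies the sex indicator and 0.003 multiplies age. Default.
``as_printed``
    both 0.474 and 0.003 multiply age (the equation exactly as published).

The published equation lists two age terms and no sex term; taken at face
value it yields ws far outside the reported group means (2.3 ± 1.4 cases,
−0.1 ± 1.7 controls), whereas reading the 0.474 term as a male indicator
lands in range — hence the ``sex_age`` default. The active preset is
logged loudly on every use; arbitrary coefficient files can be loaded.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

from .scoring import IndexScores

__all__ = [
    "PREDICTORS",
    "Demographics",
    "CoefficientSet",
    "RiskResult",
    "PRESETS",
    "DEFAULT_PRESET",
    "DEFAULT_CUTOFF",
    "DEFAULT_BANDS",
    "get_preset",
    "load_coefficients",
    "weighted_sum",
    "ws_probability",
    "classify",
    "traffic_band",
    "assess_risk",
]

logger = logging.getLogger(__name__)

PREDICTORS = (
    "sex",
    "age",
    "education",
    "first_half",
    "switching",
    "clustering",
    "perseveration",
)

DEFAULT_CUTOFF = 1.143
DEFAULT_BANDS = (0.33, 0.66)


@dataclass(frozen=True)
class Demographics:
    """Age in years, education in years, sex as 0=female / 1=male."""

    age: float
    education: float
    sex: int

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.education < 0:
            raise ValueError("education must be non-negative")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (female) or 1 (male)")


@dataclass(frozen=True)
class CoefficientSet:
    intercept: float
    coefficients: dict[str, float]
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(PREDICTORS) - set(self.coefficients)
        extra = set(self.coefficients) - set(PREDICTORS)
        if missing or extra:
            raise ValueError(
                f"coefficient set must name exactly {PREDICTORS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )


PRESETS: dict[str, CoefficientSet] = {
    # Published equation with its first term read as a male-sex indicator.
    "sex_age": CoefficientSet(
        intercept=1.160,
        coefficients={
            "sex": 0.474,
            "age": 0.003,
            "education": 0.226,
            "first_half": -0.089,
            "switching": -0.516,
            "clustering": -0.303,
            "perseveration": 0.534,
        },
        preset_name="sex_age",
    ),
    # Published equation verbatim: 0.474*age + 0.003*age, no sex term.
    "as_printed": CoefficientSet(
        intercept=1.160,
        coefficients={
            "sex": 0.0,
            "age": 0.474 + 0.003,
            "education": 0.226,
            "first_half": -0.089,
            "switching": -0.516,
            "clustering": -0.303,
            "perseveration": 0.534,
        },
        preset_name="as_printed",
    ),
}

DEFAULT_PRESET = "sex_age"


def get_preset(name: str = DEFAULT_PRESET) -> CoefficientSet:
    """Look up a named coefficient preset, logging which one is active."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    logger.warning(
        "risk: using coefficient preset %r (intercept=%.3f); the published "
        "equation's first term is read as %s",
        preset.preset_name,
        preset.intercept,
        "a sex indicator" if name == "sex_age" else "an age term, verbatim",
    )
    return preset


def load_coefficients(path: str | Path) -> CoefficientSet:
    """Load a coefficient set from JSON:
    ``{"preset": str, "intercept": num, "coefficients": {name: num}}``."""
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return CoefficientSet(
        intercept=float(obj["intercept"]),
        coefficients={k: float(v) for k, v in obj["coefficients"].items()},
        preset_name=str(obj.get("preset", Path(path).stem)),
    )


@dataclass(frozen=True)
class RiskResult:
    ws: float
    probability: float
    cutoff: float
    screen: str  # "positive" / "negative"
    band: str  # "green" / "yellow" / "red"


def weighted_sum(
    demo: Demographics, scores: IndexScores, coeffs: CoefficientSet
) -> float:
    """Pure dot product of the seven predictors with the coefficient set.

    Refuses untimed scores (``first_half is None``); rescore with the
    index-split fallback first if an untimed transcript must be assessed.
    """
    if scores.first_half is None:
        raise ValueError(
            "first_half score unavailable (untimed transcript); "
            "rescore with untimed_index_split=True to enable the fallback"
        )
    values = {
        "sex": float(demo.sex),
        "age": float(demo.age),
        "education": float(demo.education),
        "first_half": float(scores.first_half),
        "switching": float(scores.switching),
        "clustering": float(scores.clustering),
        "perseveration": float(scores.perseveration),
    }
    return coeffs.intercept + sum(
        coeffs.coefficients[name] * values[name] for name in PREDICTORS
    )


def ws_probability(ws: float) -> float:
    """Logistic transform of the logit score: 1 / (1 + exp(-ws))."""
    if not math.isfinite(ws):
        raise ValueError("ws must be finite")
    # guard against overflow for very negative ws
    if ws >= 0:
        return 1.0 / (1.0 + math.exp(-ws))
    e = math.exp(ws)
    return e / (1.0 + e)


def classify(ws: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Screen classification: positive iff ws >= cutoff (ties positive)."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return "positive" if ws >= cutoff else "negative"


def traffic_band(
    probability: float, thresholds: tuple[float, float] = DEFAULT_BANDS
) -> str:
    """Three-way probability band: green < low <= yellow < high <= red."""
    low, high = thresholds
    if not (0 <= low < high <= 1):
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    if probability < low:
        return "green"
    if probability < high:
        return "yellow"
    return "red"


def assess_risk(
    demo: Demographics,
    scores: IndexScores,
    coeffs: CoefficientSet | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    bands: tuple[float, float] = DEFAULT_BANDS,
) -> RiskResult:
    """Full risk assessment: ws, probability, screen and traffic band."""
    if coeffs is None:
        coeffs = get_preset(DEFAULT_PRESET)
    ws = weighted_sum(demo, scores, coeffs)
    p = ws_probability(ws)
    return RiskResult(
        ws=ws,
        probability=p,
        cutoff=cutoff,
        screen=classify(ws, cutoff),
        band=traffic_band(p, bands),
    )
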