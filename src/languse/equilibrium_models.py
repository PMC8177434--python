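"""Empirical equilibrium function and predictive models of minority-language use.

The theoretical ESS fraction of Reveal-players is turned into a fittable
three-parameter curve

    p*(alpha) = beta1 (1 - alpha) (alpha**beta3 - alpha)**(beta2 - 1),

with beta1 > 0 and beta3 in (0, 1).  The inner term alpha**beta3 - alpha
is positive and bounded on (0, 1) for beta3 in (0, 1); beta3 drifting
toward zero corresponds to rising aspirations for the minority language.

From p* follow the two observable-use models.  Street use (minority
conversations counted in public space) under purely random matching is

    2 alpha^2 p* - alpha^2 p*^2                            (random match)

-- the probability that a random pair contains at least one Reveal-player
and both members are bilingual.  Non-random sociality among language
militants scales this to PKE = c1 (2 alpha^2 p* - c2 alpha^2 p*^2); the
default c2 = 0 absorbs the scale into a single identified coefficient
beta1_tilde = 2 c1 beta1.  Daily use (survey respondents reporting
everyday minority-language use) is PDU = c0 alpha p*, with the identified
coefficient beta1_check = c0 beta1.

The module also carries the aggregation-pitfall calculus: population-
weighted aggregation of locality tables and the random-matching ceiling
alpha^2, which together show how aggregate figures can mask language
shift that disaggregated data reveal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InvalidInputError

__all__ = [
    "EmpiricalParams",
    "empirical_p_star",
    "street_use_random_match",
    "street_use_structural",
    "predict_street_use",
    "predict_daily_use",
    "aggregate_localities",
    "random_match_ceiling",
]

MODEL_KINDS = ("equilibrium", "street", "daily")


@dataclass(frozen=True)
class EmpiricalParams:
    """Parameters of the empirical equilibrium / predictive curves.

    ``beta1`` is the identified scale: beta1 itself for the equilibrium
    curve, beta1_tilde = 2*c1*beta1 for street use, beta1_check =
    c0*beta1 for daily use (the structural constants cannot be separated
    from beta1 and are never estimated on their own).  ``c2`` is the
    militant-pairing adjustment of the street model, default 0.
    """

    beta1: float
    beta2: float
    beta3: float
    c2: float = 0.0
    model_kind: str = "equilibrium"

    def __post_init__(self) -> None:
        if not self.beta1 > 0:
            raise InvalidInputError(f"beta1 must be > 0, got {self.beta1}")
        if not 0 < self.beta3 < 1:
            raise InvalidInputError(f"beta3 must lie in (0, 1), got {self.beta3}")
        if not 0 <= self.c2 <= 1:
            raise InvalidInputError(f"c2 must lie in [0, 1], got {self.c2}")
        if self.model_kind not in MODEL_KINDS:
            raise InvalidInputError(
                f"model_kind must be one of {MODEL_KINDS}, got {self.model_kind!r}"
            )


def _inner(alpha: np.ndarray, beta3: float) -> np.ndarray:
    inner = alpha**beta3 - alpha
    if np.any(inner <= 0):
        raise DomainError(
            "inner term alpha**beta3 - alpha is non-positive; "
            "require alpha in (0, 1) and beta3 in (0, 1)"
        )
    return inner


def _check_alpha(alpha) -> np.ndarray:
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0) or np.any(a >= 1):
        raise InvalidInputError("alpha must lie in (0, 1)")
    return a


def empirical_p_star(alpha, params: EmpiricalParams):
    """Empirical equilibrium fraction of Reveal-players at ``alpha``.

    Vectorised over ``alpha``.  Values outside (0, 1) are returned as
    computed (clamping would bias least squares) but trigger a warning.
    """
    a = _check_alpha(alpha)
    val = params.beta1 * (1.0 - a) * _inner(a, params.beta3) ** (params.beta2 - 1.0)
    if np.any((val <= 0) | (val >= 1)):
        warnings.warn(
            "empirical p* left the open interval (0, 1) at some alpha",
            stacklevel=2,
        )
    return val if np.ndim(alpha) else float(val)


def street_use_random_match(alpha, p_star):
    """Expected street-use share under purely random pairwise matching.

    Probability that a random pair is bilingual-bilingual with at least
    one Reveal-player: 2 alpha^2 p* - alpha^2 p*^2, identically equal to
    alpha^2 p*^2 + 2 alpha^2 p* (1 - p*).
    """
    a = np.asarray(alpha, dtype=float)
    p = np.asarray(p_star, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((p < 0) | (p > 1)):
        raise InvalidInputError("alpha and p_star must lie in [0, 1]")
    val = 2.0 * a**2 * p - a**2 * p**2
    return val if (np.ndim(alpha) or np.ndim(p_star)) else float(val)


def street_use_structural(alpha, p_star, c1: float = 1.0, c2: float = 0.0):
    """Structural street-use model c1 (2 alpha^2 p* - c2 alpha^2 p*^2).

    c1 scales for the overall surplus of non-random matches; c2 <= 1
    discounts the double-counting correction because militant-militant
    matches are over-represented.  c1 = c2 = 1 recovers the pure
    random-matching share.
    """
    a = np.asarray(alpha, dtype=float)
    p = np.asarray(p_star, dtype=float)
    val = c1 * (2.0 * a**2 * p - c2 * a**2 * p**2)
    return val if (np.ndim(alpha) or np.ndim(p_star)) else float(val)


def predict_street_use(alpha, params: EmpiricalParams, c1: float = 1.0):
    """Predicted street-use share PKE(alpha).

    With the default ``params.c2 == 0`` this is the reduced form
    ``beta1_tilde * alpha^2 (1-alpha) (alpha^beta3 - alpha)^(beta2-1)``
    where ``params.beta1`` is the absorbed coefficient beta1_tilde.  With
    a non-zero c2, ``params.beta1`` is interpreted as the structural
    beta1 and the prediction is c1 (2 alpha^2 p* - c2 alpha^2 p*^2).
    """
    if params.model_kind != "street":
        raise InvalidInputError(
            f"predict_street_use requires model_kind='street', got "
            f"{params.model_kind!r}"
        )
    a = _check_alpha(alpha)
    if params.c2 == 0.0:
        val = (
            params.beta1
            * a**2
            * (1.0 - a)
            * _inner(a, params.beta3) ** (params.beta2 - 1.0)
        )
        return val if np.ndim(alpha) else float(val)
    base = EmpiricalParams(
        beta1=params.beta1, beta2=params.beta2, beta3=params.beta3,
        model_kind="equilibrium",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = empirical_p_star(alpha, base)
    return street_use_structural(alpha, p, c1=c1, c2=params.c2)


def predict_daily_use(alpha, params: EmpiricalParams):
    """Predicted daily-use share PDU(alpha) =
    beta1_check * alpha (1-alpha) (alpha^beta3 - alpha)^(beta2-1),
    with ``params.beta1`` the absorbed coefficient beta1_check."""
    if params.model_kind != "daily":
        raise InvalidInputError(
            f"predict_daily_use requires model_kind='daily', got "
            f"{params.model_kind!r}"
        )
    a = _check_alpha(alpha)
    val = params.beta1 * a * (1.0 - a) * _inner(a, params.beta3) ** (params.beta2 - 1.0)
    return val if np.ndim(alpha) else float(val)


def predict_use(alpha, params: EmpiricalParams):
    """Dispatch to the street or daily predictive curve by model_kind."""
    if params.model_kind == "street":
        return predict_street_use(alpha, params)
    if params.model_kind == "daily":
        return predict_daily_use(alpha, params)
    return empirical_p_star(alpha, params)


def aggregate_localities(
    rows: Iterable[Sequence[float]],
) -> tuple[float, float]:
    """Population-weighted aggregate (alpha, use) over localities.

    ``rows`` are (population weight, alpha, observed use) triples.  The
    result illustrates the aggregation pitfall: aggregates can suggest a
    healthy use level while every disaggregated locality shows shift.
    """
    rows = list(rows)
    if not rows:
        raise InvalidInputError("aggregate_localities needs at least one row")
    w = np.array([r[0] for r in rows], dtype=float)
    a = np.array([r[1] for r in rows], dtype=float)
    u = np.array([r[2] for r in rows], dtype=float)
    if np.any(w <= 0):
        raise InvalidInputError("weights must be positive")
    if np.any((a < 0) | (a > 1)) or np.any((u < 0) | (u > 1)):
        raise InvalidInputError("proportions must lie in [0, 1]")
    return float(np.average(a, weights=w)), float(np.average(u, weights=w))


def random_match_ceiling(alpha) -> float:
    """Maximal street-use share under random matching: alpha^2.

    Both partners must be bilingual and every bilingual pair converses in
    the minority language (the p* = 1 case of the random-match model).
    """
    a = np.asarray(alpha, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise InvalidInputError("alpha must lie in [0, 1]")
    val = a**2
    return val if np.ndim(alpha) else float(val)
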