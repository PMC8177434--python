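"""The Language Use Game (LUG): payoff structure, assumptions, ESS equilibrium.

A bilingual society has a majority language A spoken by everyone and a
minority language B spoken by a bilingual fraction ``alpha`` of the
population.  Bilinguals repeatedly meet random partners whose linguistic
type is private information and choose between two pure strategies:

* **R (Reveal)** -- always signal bilingualism, so B is spoken with any
  bilingual partner, at the risk of a frustration cost ``c(alpha)`` when
  the partner turns out to be monolingual;
* **H (Hide)** -- open in A and simply match the partner's language,
  which avoids the cost but reinforces the imperfect information.

Payoffs: an interaction in B is worth ``m(alpha)``, one in A is worth the
constant ``n``, and an R-player forced to switch earns ``n - c(alpha)``.
On the admissible domain ``alpha in (0, alpha_star)`` the model assumes
``m(alpha) > n > c(alpha) > 0`` with both ``m`` and ``c`` strictly
decreasing and approaching ``n`` and ``0`` at the aspiration level
``alpha_star`` -- the bilingual share at which B would be felt to be out
of danger.

Under those assumptions the game has a unique interior Nash equilibrium
which is an evolutionarily stable strategy (ESS),

    p* = 1 - (1 - alpha) c(alpha) / [alpha (m(alpha) - n)],

the emergent linguistic convention: a fraction ``p*`` of bilinguals play
R and the rest play H.  ``(1 - p*)**2`` is the equilibrium probability
that a random bilingual-bilingual meeting is conducted in A -- the
probability of language shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, EquilibriumDomainError, InvalidInputError

__all__ = [
    "PayoffSpec",
    "LocalityRecord",
    "EquilibriumResult",
    "validate_assumptions",
    "expected_payoffs",
    "ess_equilibrium",
    "weighted_benefit",
]


@dataclass(frozen=True)
class PayoffSpec:
    """Payoff primitives of the LUG.

    Parameters
    ----------
    n
        Payoff of an interaction conducted in the majority language A.
    alpha_star
        Country-level aspiration: the bilingual proportion at which B
        would be considered non-endangered.  Upper end of the admissible
        alpha domain.
    m_fn
        ``alpha -> m(alpha)``: payoff of an interaction in B.
    c_fn
        ``alpha -> c(alpha)``: frustration cost of a forced switch to A.
    family_params
        Parameters of the built-in parametric family, if used.
    """

    n: float
    alpha_star: float
    m_fn: Callable[[float], float]
    c_fn: Callable[[float], float]
    family_params: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise InvalidInputError(f"n must be positive, got {self.n}")
        if not 0 < self.alpha_star < 1:
            raise InvalidInputError(
                f"alpha_star must lie in (0, 1), got {self.alpha_star}"
            )

    # -- domain-checked evaluation ------------------------------------
    def _check_alpha(self, alpha: float) -> None:
        if not 0 < alpha < 1:
            raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
        if alpha >= self.alpha_star:
            raise DomainError(
                f"alpha={alpha} is outside the model domain (0, alpha_star="
                f"{self.alpha_star})"
            )

    def m(self, alpha: float) -> float:
        """Payoff m(alpha) of a conversation in B."""
        self._check_alpha(alpha)
        return float(self.m_fn(alpha))

    def c(self, alpha: float) -> float:
        """Frustration cost c(alpha) of a forced switch to A."""
        self._check_alpha(alpha)
        return float(self.c_fn(alpha))

    @classmethod
    def from_family(
        cls,
        mu: float,
        kappa: float,
        a: float = 1.0,
        d: float = 1.0,
        n: float = 1.0,
        alpha_star: float = 0.9,
    ) -> "PayoffSpec":
        """Built-in parametric family
        ``m(alpha) = n + mu*(alpha_star - alpha)**a`` and
        ``c(alpha) = kappa*(alpha_star - alpha)**d``.

        The simplest family with all required properties: both mappings
        strictly decreasing, with limits ``n`` and ``0`` at ``alpha_star``.
        """
        if min(mu, kappa, a, d) <= 0:
            raise InvalidInputError("family parameters mu, kappa, a, d must be > 0")
        return cls(
            n=n,
            alpha_star=alpha_star,
            m_fn=lambda alpha: n + mu * (alpha_star - alpha) ** a,
            c_fn=lambda alpha: kappa * (alpha_star - alpha) ** d,
            family_params={"mu": mu, "kappa": kappa, "a": a, "d": d},
        )

    @classmethod
    def from_constants(
        cls, m: float, c: float, n: float = 1.0, alpha_star: float = 0.9
    ) -> "PayoffSpec":
        """Spec with constant m and c (handy for pointwise calculations;
        constant mappings do not satisfy the monotonicity assumption)."""
        return cls(n=n, alpha_star=alpha_star, m_fn=lambda _a: m, c_fn=lambda _a: c)


@dataclass(frozen=True)
class LocalityRecord:
    """One locality-year survey observation.

    ``observed_use`` is the street-use share (Basque KE, from counted
    street conversations) or the daily-use share (Irish/Welsh DU, from
    census/survey respondents) depending on ``use_kind``.
    """

    locality_id: str
    year: int
    n_bilinguals: int
    alpha: float
    observed_use: float
    use_kind: str  # "street" | "daily"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InvalidInputError(
                f"{self.locality_id}: alpha must lie in (0, 1), got {self.alpha}"
            )
        if not 0 <= self.observed_use <= 1:
            raise InvalidInputError(
                f"{self.locality_id}: observed_use must lie in [0, 1], "
                f"got {self.observed_use}"
            )
        if self.n_bilinguals < 0:
            raise InvalidInputError(
                f"{self.locality_id}: n_bilinguals must be >= 0, "
                f"got {self.n_bilinguals}"
            )
        if self.use_kind not in ("street", "daily"):
            raise InvalidInputError(
                f"{self.locality_id}: use_kind must be 'street' or 'daily', "
                f"got {self.use_kind!r}"
            )


@dataclass(frozen=True)
class EquilibriumResult:
    """ESS of the LUG at one locality.

    ``shift_prob`` = (1-p*)^2 is the equilibrium probability that two
    randomly matched bilinguals both play H and converse in A;
    ``use_prob_bilingual_pair`` = p*^2 + 2 p* (1-p*) is the complementary
    probability that at least one R-player is involved and B is used.
    """

    p_star: float
    rest_points: tuple[tuple[float, str], ...]
    shift_prob: float
    use_prob_bilingual_pair: float


def weighted_benefit(spec: PayoffSpec, alpha: float) -> float:
    """The weighted-benefit bound b(alpha) = (m(alpha)-n) * alpha/(1-alpha).

    The frustration cost must stay below this bound for an interior
    equilibrium to exist.
    """
    m = spec.m(alpha)
    return (m - spec.n) * alpha / (1.0 - alpha)


def validate_assumptions(
    spec: PayoffSpec,
    alpha_grid: Sequence[float] | None = None,
    *,
    country_alpha: float | None = None,
    tol: float = 1e-9,
) -> list[str]:
    """Check the payoff assumptions on a grid; return the violations.

    Pointwise, for every grid alpha: ``m(alpha) > n``, ``n > c(alpha) > 0``
    and the weighted-benefit condition ``c(alpha) < b(alpha)``.  Across
    the grid: strict monotone decrease of both mappings (tolerance
    ``tol``), and limits ``m -> n``, ``c -> 0`` on a tail grid approaching
    ``alpha_star``.  An empty return value means the spec is admissible
    on the grid.

    A country-level aggregate ``country_alpha >= 0.5`` only warns: the
    model targets societies where bilinguals are a minority nationally,
    but individual localities may well have bilingual majorities.
    """
    if alpha_grid is None:
        alpha_grid = np.linspace(0.01 * spec.alpha_star, 0.99 * spec.alpha_star, 50)
    grid = np.asarray(list(alpha_grid), dtype=float)
    if grid.size == 0:
        raise InvalidInputError("alpha_grid must be non-empty")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise InvalidInputError("all grid alphas must lie in (0, 1)")
    if np.any(grid >= spec.alpha_star):
        raise DomainError(
            "grid contains alpha >= alpha_star; assumptions are defined on "
            "(0, alpha_star)"
        )

    if country_alpha is not None and country_alpha >= 0.5:
        warnings.warn(
            f"country-level alpha={country_alpha} >= 0.5: the model assumes "
            "bilinguals are a national minority (alpha < 1 - alpha)",
            stacklevel=2,
        )

    violations: list[str] = []
    order = np.argsort(grid)
    g = grid[order]
    m_vals = np.array([spec.m(a) for a in g])
    c_vals = np.array([spec.c(a) for a in g])

    for a, m, c in zip(g, m_vals, c_vals):
        if not m > spec.n:
            violations.append(f"m(alpha) > n fails at alpha={a:.6g} (m={m:.6g})")
        if not (spec.n > c > 0):
            violations.append(f"n > c(alpha) > 0 fails at alpha={a:.6g} (c={c:.6g})")
        b = (m - spec.n) * a / (1.0 - a)
        if not c < b:
            violations.append(
                f"weighted-benefit c < b fails at alpha={a:.6g} "
                f"(c={c:.6g}, b={b:.6g})"
            )

    if g.size >= 2:
        if not np.all(np.diff(m_vals) < -tol):
            violations.append("m(alpha) is not strictly decreasing on the grid")
        if not np.all(np.diff(c_vals) < -tol):
            violations.append("c(alpha) is not strictly decreasing on the grid")

    # Limits at alpha_star, checked on a tail grid: the gaps m - n and c
    # must shrink essentially to zero as alpha -> alpha_star.
    deltas = spec.alpha_star * np.array([1e-2, 1e-4, 1e-6])
    tail = spec.alpha_star - deltas
    m_gap = np.array([spec.m(a) - spec.n for a in tail])
    c_gap = np.array([spec.c(a) for a in tail])
    for name, gap in (("m(alpha) -> n", m_gap), ("c(alpha) -> 0", c_gap)):
        if not (np.all(np.diff(gap) <= tol) and gap[-1] < max(1e-3, 1e-2 * gap[0])):
            violations.append(f"limit {name} as alpha -> alpha_star fails")

    return violations


def expected_payoffs(spec: PayoffSpec, alpha: float, p: float) -> tuple[float, float]:
    """Expected payoffs (u_R, u_H) when a fraction ``p`` of bilinguals play R.

    The partner is bilingual with probability ``alpha``.  An R-player
    earns ``m`` against any bilingual (an H-respondent answers in the
    speaker's language) and ``n - c`` against a monolingual; an H-player
    earns ``m`` only when the bilingual partner is an R-player, ``n``
    otherwise.  Hence

        u_R - u_H = alpha (1-p) (m - n) - (1-alpha) c.
    """
    if not 0 <= p <= 1:
        raise InvalidInputError(f"p must lie in [0, 1], got {p}")
    m, c, n = spec.m(alpha), spec.c(alpha), spec.n
    u_r = alpha * m + (1.0 - alpha) * (n - c)
    u_h = alpha * (p * m + (1.0 - p) * n) + (1.0 - alpha) * n
    return u_r, u_h


def ess_equilibrium(spec: PayoffSpec, alpha: float) -> EquilibriumResult:
    """Closed-form ESS of the LUG at bilingual proportion ``alpha``.

    Requires the pointwise admissibility conditions ``m > n``,
    ``n > c > 0`` and ``c < b(alpha)``; under them the interior rest
    point

        p* = 1 - (1-alpha) c / [alpha (m - n)]

    lies in (0, 1), is the unique Nash equilibrium and an ESS, and the
    boundary rest points 0 and 1 are unstable.
    """
    m, c, n = spec.m(alpha), spec.c(alpha), spec.n
    if not m > n:
        raise EquilibriumDomainError(f"m(alpha)={m} must exceed n={n}")
    if not (n > c > 0):
        raise EquilibriumDomainError(f"need n > c(alpha) > 0, got c={c}, n={n}")
    b = (m - n) * alpha / (1.0 - alpha)
    if not c < b:
        raise EquilibriumDomainError(
            f"weighted-benefit condition violated: c={c:.6g} >= b={b:.6g}; "
            "the interior equilibrium would leave (0, 1)"
        )
    p_star = 1.0 - (1.0 - alpha) * c / (alpha * (m - n))
    shift = (1.0 - p_star) ** 2
    return EquilibriumResult(
        p_star=p_star,
        rest_points=((0.0, "unstable"), (p_star, "stable"), (1.0, "unstable")),
        shift_prob=shift,
        use_prob_bilingual_pair=1.0 - shift,
    )
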