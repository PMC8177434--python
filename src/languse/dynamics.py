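"""Replicator dynamics of the LUG and a finite-population imitation check.

The fraction p(t) of R-players in a locality follows the scalar
replicator equation

    dp/dt = p (1-p) [ alpha (m-n) (1-p) - c (1-alpha) ],

whose interior rest point is the closed-form ESS p* and whose boundary
rest points 0 and 1 are unstable.  ``integrate_rd`` integrates this ODE
to steady state; ``simulate_abm`` runs a pairwise proportional-imitation
process whose mean-field limit is the same ODE, validating the
infinite-population prediction at finite N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidInputError
from .game_core import PayoffSpec, ess_equilibrium

__all__ = [
    "Trajectory",
    "AbmState",
    "rd_rhs",
    "integrate_rd",
    "classify_rest_points",
    "simulate_abm",
]


@dataclass(frozen=True)
class Trajectory:
    """A replicator trajectory p(t) for one locality."""

    times: np.ndarray
    p_values: np.ndarray
    alpha: float
    converged_to: float

    def to_table(self):
        """Return the trajectory as a two-column pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame({"time": self.times, "p": self.p_values})


@dataclass(frozen=True)
class AbmState:
    """Initial state of the finite-population imitation process."""

    n_agents: int
    n_revealers: int
    alpha: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise InvalidInputError("need at least 2 agents")
        if not 0 <= self.n_revealers <= self.n_agents:
            raise InvalidInputError("n_revealers must lie in [0, n_agents]")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must lie in (0, 1)")


def rd_rhs(p: float, alpha: float, spec: PayoffSpec) -> float:
    """Right-hand side of the replicator equation at state ``p``."""
    if not 0 <= p <= 1:
        raise InvalidInputError(f"p must lie in [0, 1], got {p}")
    m, c = spec.m(alpha), spec.c(alpha)
    return p * (1.0 - p) * (alpha * (m - spec.n) * (1.0 - p) - c * (1.0 - alpha))


def integrate_rd(
    p0: float,
    alpha: float,
    spec: PayoffSpec,
    horizon: float = 5_000.0,
    tolerance: float = 1e-12,
) -> Trajectory:
    """Integrate the replicator ODE from interior start ``p0``.

    Adaptive explicit integration (RK45, rtol 1e-8 / atol 1e-10 -- the
    ODE is scalar and smooth, stiffness is not expected) with a terminal
    steady-state event |dp/dt| < ``tolerance``.  Boundary starts are
    rejected: at p0 in {0, 1} the flow is identically zero and the
    convergence statement does not apply.
    """
    if not 0 < p0 < 1:
        raise InvalidInputError(f"p0 must lie in the open interval (0, 1), got {p0}")
    m, c, n = spec.m(alpha), spec.c(alpha), spec.n

    def rhs(_t, y):
        p = y[0]
        return [p * (1.0 - p) * (alpha * (m - n) * (1.0 - p) - c * (1.0 - alpha))]

    def steady(_t, y):
        return abs(rhs(_t, y)[0]) - tolerance

    steady.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [p0],
        rtol=1e-8,
        atol=1e-10,
        events=steady,
        dense_output=False,
    )
    times = sol.t
    p_values = np.clip(sol.y[0], 0.0, 1.0)
    return Trajectory(
        times=times, p_values=p_values, alpha=alpha, converged_to=float(p_values[-1])
    )


def classify_rest_points(
    alpha: float, spec: PayoffSpec, eps: float = 1e-4
) -> list[tuple[float, str]]:
    """Rest points of the replicator equation with stability labels.

    Classification is by the sign of the flow in punctured neighbourhoods
    of radius ``eps``: a rest point attracting from both sides is stable.
    """
    p_star = ess_equilibrium(spec, alpha).p_star

    def label(p: float) -> str:
        lo = max(p - eps, 0.5 * eps)
        hi = min(p + eps, 1.0 - 0.5 * eps)
        attracting_left = p <= eps or rd_rhs(lo, alpha, spec) > 0
        attracting_right = p >= 1.0 - eps or rd_rhs(hi, alpha, spec) < 0
        if p <= eps:  # boundary 0: only the right side exists
            return "stable" if rd_rhs(hi, alpha, spec) < 0 else "unstable"
        if p >= 1.0 - eps:  # boundary 1: only the left side exists
            return "stable" if rd_rhs(lo, alpha, spec) > 0 else "unstable"
        return "stable" if (attracting_left and attracting_right) else "unstable"

    return [(p, label(p)) for p in (0.0, p_star, 1.0)]


def simulate_abm(state: AbmState, spec: PayoffSpec, n_rounds: int) -> np.ndarray:
    """Pairwise proportional-imitation dynamics among ``n_agents`` bilinguals.

    Each round a focal agent and a role model are drawn uniformly at
    random (without replacement).  Each of the two plays the LUG against
    one random partner whose type is bilingual with probability ``alpha``
    (types are private, so only the realized payoff is observed); a
    bilingual partner plays R with the current population frequency.  The
    focal agent adopts the role model's strategy with probability equal
    to the positive part of the payoff difference divided by the payoff
    range m - (n - c).  The mean-field limit of this update rule is the
    replicator equation.

    Returns the count of R-players after each round; reproducible given
    ``state.rng_seed``.
    """
    if n_rounds < 0:
        raise InvalidInputError("n_rounds must be >= 0")
    n_ag = state.n_agents
    alpha = state.alpha
    m, c, n = spec.m(alpha), spec.c(alpha), spec.n
    span = m - (n - c)  # maximum payoff minus minimum payoff
    if span <= 0:
        raise InvalidInputError("degenerate payoffs: m <= n - c")

    rng = np.random.default_rng(state.rng_seed)
    k = state.n_revealers
    out = np.empty(n_rounds, dtype=np.int64)

    def realized_payoff(is_r: bool, u_bil: float, u_strat: float, p_frac: float):
        if u_bil < alpha:  # partner is bilingual
            if is_r:
                return m
            return m if u_strat < p_frac else n  # H earns m only vs an R partner
        return (n - c) if is_r else n

    chunk = 1 << 14
    done = 0
    while done < n_rounds:
        todo = min(chunk, n_rounds - done)
        u = rng.random((todo, 7))
        for i in range(todo):
            u0, u1, u2, u3, u4, u5, u6 = u[i]
            p_frac = k / n_ag
            focal_r = u0 < p_frac
            model_r = u1 < (k - focal_r) / (n_ag - 1)
            if focal_r != model_r:
                pf = realized_payoff(focal_r, u2, u3, p_frac)
                pm = realized_payoff(model_r, u4, u5, p_frac)
                if pm > pf and u6 < (pm - pf) / span:
                    k += 1 if model_r else -1
            out[done + i] = k
        done += todo
    return out
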