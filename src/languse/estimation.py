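"""Fitting the predictive use curves to locality tables.

Per survey year and language the observable-use curve (street or daily)
is fitted to locality pairs (alpha_i, use_i) by unweighted nonlinear
least squares -- every locality counts the same regardless of its
population -- under the constraints beta1 > 0 and beta3 in (0, 1); beta2
is free up to a wide guard box.  Uncertainty comes from a pairs (case)
bootstrap over localities with pointwise percentile bands, and a
local-linear kernel regression serves as a nonparametric specification
check: a well-specified parametric curve should contain the nonparametric
fit inside its confidence band most of the time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    BandUnreliableError,
    InsufficientDataError,
    InvalidInputError,
    UnidentifiableError,
)
from .equilibrium_models import EmpiricalParams, predict_use
from .game_core import LocalityRecord

__all__ = [
    "FitResult",
    "fit_predictive_model",
    "bootstrap_band",
    "nonparametric_check",
]

# beta2 guard box: the objective can be multimodal in beta2/beta3 and an
# unbounded beta2 lets the optimizer escape along flat ridges.
_BETA2_BOUND = 10.0
_BOUNDS = (
    np.array([1e-10, -_BETA2_BOUND, 1e-8]),
    np.array([np.inf, _BETA2_BOUND, 1.0 - 1e-8]),
)


@dataclass
class FitResult:
    """Outcome of one per-year, per-language curve fit."""

    params: EmpiricalParams
    objective: float
    converged: bool
    n_localities: int
    model_kind: str
    diagnostics: dict = field(default_factory=dict)
    band: pd.DataFrame | None = None
    np_check: pd.DataFrame | None = None
    np_inside_share: float | None = None

    def report(self) -> dict:
        """Plain-dict summary suitable for JSON serialisation."""
        return {
            "model_kind": self.model_kind,
            "beta1": self.params.beta1,
            "beta2": self.params.beta2,
            "beta3": self.params.beta3,
            "c2": self.params.c2,
            "objective": self.objective,
            "converged": self.converged,
            "n_localities": self.n_localities,
            "diagnostics": self.diagnostics,
            "np_inside_share": self.np_inside_share,
        }


def _as_arrays(rows, model_kind: str | None = None):
    """Extract (alpha, use) arrays from records or a DataFrame."""
    if isinstance(rows, pd.DataFrame):
        alpha = rows["alpha"].to_numpy(dtype=float)
        use = rows["observed_use"].to_numpy(dtype=float)
        years = rows["year"].to_numpy() if "year" in rows else None
        kinds = rows["use_kind"].to_numpy() if "use_kind" in rows else None
    else:
        rows = list(rows)
        alpha = np.array([r.alpha for r in rows], dtype=float)
        use = np.array([r.observed_use for r in rows], dtype=float)
        years = np.array([r.year for r in rows])
        kinds = np.array([r.use_kind for r in rows])
    if years is not None and len(set(years.tolist())) > 1:
        raise InvalidInputError("all rows must share the same survey year")
    if kinds is not None:
        uniq = set(kinds.tolist())
        if len(uniq) > 1:
            raise InvalidInputError("all rows must share the same use_kind")
        if model_kind is not None and uniq and uniq != {model_kind}:
            raise InvalidInputError(
                f"rows have use_kind {uniq}, but model_kind={model_kind!r}"
            )
    if np.any((alpha <= 0) | (alpha >= 1)):
        raise InvalidInputError("all alpha must lie in (0, 1)")
    return alpha, use


def _shape(alpha: np.ndarray, beta2: float, beta3: float, model_kind: str):
    """Model curve with beta1 = 1 (the model is linear in beta1)."""
    inner = alpha**beta3 - alpha
    core = (1.0 - alpha) * inner ** (beta2 - 1.0)
    if model_kind == "street":
        return alpha**2 * core
    if model_kind == "daily":
        return alpha * core
    return core


def _default_starts(alpha, use, model_kind):
    """3x3x3 multi-start grid; beta1 starts are profiled analytically
    (the curve is linear in beta1, so the conditionally optimal scale is
    a one-line least-squares projection)."""
    starts = []
    for b2 in (0.8, 1.4, 2.2):
        for b3 in (0.15, 0.35, 0.6):
            h = _shape(alpha, b2, b3, model_kind)
            denom = float(h @ h)
            b1_opt = float(h @ use) / denom if denom > 0 else 1.0
            b1_opt = max(b1_opt, 1e-6)
            for mult in (0.5, 1.0, 2.0):
                starts.append((b1_opt * mult, b2, b3))
    return starts


def fit_predictive_model(
    rows,
    model_kind: str,
    starts: Sequence[tuple[float, float, float]] | None = None,
) -> FitResult:
    """Constrained nonlinear least squares fit of the use curve.

    Minimises sum_i (use_i - model(alpha_i; beta))^2 over beta1 > 0,
    beta3 in (0, 1), beta2 in a wide guard box, unweighted across
    localities.  The best of the multi-start solutions is returned;
    non-convergence is propagated in ``converged``, never dropped.
    """
    if model_kind not in ("street", "daily"):
        raise InvalidInputError("model_kind must be 'street' or 'daily'")
    alpha, use = _as_arrays(rows, model_kind)
    if alpha.size < 8:
        raise InsufficientDataError(
            f"need at least 8 localities, got {alpha.size}"
        )
    if np.ptp(alpha) < 1e-12:
        raise UnidentifiableError("all alpha identical: no curve information")

    if starts is None:
        starts = _default_starts(alpha, use, model_kind)

    log_alpha = np.log(alpha)

    def resid(theta):
        b1, b2, b3 = theta
        return use - b1 * _shape(alpha, b2, b3, model_kind)

    def jac(theta):
        b1, b2, b3 = theta
        inner = alpha**b3 - alpha
        f = b1 * _shape(alpha, b2, b3, model_kind)
        J = np.empty((alpha.size, 3))
        J[:, 0] = -f / b1
        J[:, 1] = -f * np.log(inner)
        J[:, 2] = -f * (b2 - 1.0) * (alpha**b3) * log_alpha / inner
        return J

    best = None  # best converged solution
    best_any = None  # fallback if nothing converged
    n_fail = 0
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), _BOUNDS[0], _BOUNDS[1])
        try:
            sol = least_squares(
                resid, x0, jac=jac, bounds=_BOUNDS, method="trf", max_nfev=2000
            )
        except Exception:
            n_fail += 1
            continue
        if sol.success:
            if best is None or sol.cost < best.cost:
                best = sol
        else:
            n_fail += 1
        if best_any is None or sol.cost < best_any.cost:
            best_any = sol
    if best is None:
        best = best_any
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    b1, b2, b3 = best.x
    if abs(b2) >= _BETA2_BOUND - 1e-6:
        warnings.warn(
            f"beta2 estimate {b2:.3g} sits on the guard bound |beta2| <= "
            f"{_BETA2_BOUND}", stacklevel=2,
        )
    params = EmpiricalParams(
        beta1=float(b1), beta2=float(b2), beta3=float(b3), model_kind=model_kind
    )
    return FitResult(
        params=params,
        objective=float(2.0 * best.cost),  # least_squares cost is 0.5 * SSR
        converged=bool(best.success),
        n_localities=int(alpha.size),
        model_kind=model_kind,
        diagnostics={
            "optimizer_status": int(best.status),
            "optimizer_message": best.message,
            "n_starts": len(starts),
            "n_failed_starts": n_fail,
            "band_type": "pointwise percentile (pairs bootstrap)",
        },
    )


def bootstrap_band(
    rows,
    model_kind: str,
    fit: FitResult,
    n_boot: int = 999,
    level: float = 0.90,
    alpha_grid: np.ndarray | None = None,
    seed: int | None = None,
    max_fail_rate: float = 0.20,
) -> pd.DataFrame:
    """Pairs-bootstrap pointwise percentile band for the fitted curve.

    Localities are resampled with replacement (the locality is the
    sampling unit and the binomial observation noise is heteroscedastic,
    which rules out a residual bootstrap), the model is refitted on each
    replicate from the point estimate, and the band is the pointwise
    (1-level)/2 and (1+level)/2 percentile of replicate predictions on
    ``alpha_grid``.
    """
    if not fit.converged:
        raise InvalidInputError("bootstrap_band requires a converged fit")
    if n_boot < 199:
        raise InvalidInputError("n_boot must be at least 199")
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    alpha, use = _as_arrays(rows, model_kind)
    if alpha_grid is None:
        alpha_grid = np.linspace(alpha.min(), alpha.max(), 25)
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    rng = np.random.default_rng(seed)
    point_start = (fit.params.beta1, fit.params.beta2, fit.params.beta3)
    preds = []
    n_bad = 0
    n = alpha.size
    df = pd.DataFrame(
        {"alpha": alpha, "observed_use": use}
    )
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            rfit = fit_predictive_model(
                df.iloc[idx], model_kind, starts=[point_start]
            )
        except (UnidentifiableError, RuntimeError):
            n_bad += 1
            continue
        if not rfit.converged:
            n_bad += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds.append(np.asarray(predict_use(alpha_grid, rfit.params)))
    if n_bad / n_boot > max_fail_rate:
        raise BandUnreliableError(
            f"{n_bad}/{n_boot} bootstrap replicates failed to converge"
        )
    preds = np.vstack(preds)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = np.asarray(predict_use(alpha_grid, fit.params))
    return pd.DataFrame(
        {
            "alpha": alpha_grid,
            "lower": np.percentile(preds, lo_q, axis=0),
            "point": point,
            "upper": np.percentile(preds, hi_q, axis=0),
        }
    )


def _rule_of_thumb_bw(x: np.ndarray) -> float:
    return 1.06 * np.std(x) * x.size ** (-1.0 / 5.0)


def nonparametric_check(rows, band: pd.DataFrame):
    """Local-linear kernel regression check of the parametric curve.

    Fits use on alpha with a cross-validated bandwidth, evaluates the
    fit on the band's alpha grid, and reports the share of grid points
    where the nonparametric curve lies inside the bootstrap band.  A
    failed bandwidth search falls back to the normal-reference rule of
    thumb with a warning.

    Returns ``(table, inside_share)``.
    """
    alpha, use = _as_arrays(rows)
    if alpha.size < 8:
        raise InsufficientDataError(
            f"need at least 8 localities, got {alpha.size}"
        )
    from statsmodels.nonparametric.kernel_regression import KernelReg

    grid = band["alpha"].to_numpy(dtype=float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kr = KernelReg(use, alpha, var_type="c", reg_type="ll", bw="cv_ls")
        bw = float(kr.bw[0])
        if not np.isfinite(bw) or bw <= 0:
            raise ValueError("degenerate bandwidth")
    except Exception:
        bw = _rule_of_thumb_bw(alpha)
        warnings.warn(
            f"cross-validated bandwidth selection failed; falling back to "
            f"rule-of-thumb bw={bw:.4g}", stacklevel=2,
        )
        kr = KernelReg(use, alpha, var_type="c", reg_type="ll", bw=[bw])
    np_fit = kr.fit(grid)[0]
    inside = (np_fit >= band["lower"].to_numpy()) & (
        np_fit <= band["upper"].to_numpy()
    )
    table = pd.DataFrame(
        {
            "alpha": grid,
            "np_fit": np_fit,
            "lower": band["lower"].to_numpy(),
            "upper": band["upper"].to_numpy(),
            "inside": inside,
        }
    )
    return table, float(inside.mean())
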