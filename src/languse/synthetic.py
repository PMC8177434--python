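"""Synthetic locality survey tables with the statistical structure the
analysis assumes.

Each synthetic locality draws its bilingual proportion alpha_i from a
right-skewed distribution on (eps, alpha_star - eps) -- most localities
have few bilinguals, a handful have many, mirroring the real municipal
distributions.  The true use level is the predictive curve evaluated at
alpha_i, and the observed use adds binomial noise from a finite number
of recorded conversations (street use) or survey respondents (daily
use): observed_i = Binomial(k_i, mu_i) / k_i.

The generator is the package's stand-in for real survey exports: it
emits the same canonical table schema the readers consume, with the true
noise-free use level carried in a separate ``true_use`` column consumed
only by recovery tests, never by the estimation module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError
from .equilibrium_models import EmpiricalParams, predict_use
from .game_core import LocalityRecord

__all__ = [
    "SyntheticConfig",
    "generate_localities",
    "generate_panel",
    "drifting_configs",
    "records_from_table",
    "pitfall_rows",
]

# The two-locality aggregation-pitfall inputs: (population weight, alpha,
# observed street use) for a small high-alpha locality and a five times
# larger low-alpha one.
PITFALL_ROWS = ((1.0, 0.8, 0.5), (5.0, 0.2, 0.02))


def pitfall_rows() -> tuple[tuple[float, float, float], ...]:
    """The canonical two-locality aggregation-pitfall inputs."""
    return PITFALL_ROWS


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic survey year.

    ``alpha_distribution`` holds the Beta(a, b) shape parameters of the
    bilingual-proportion distribution before stretching to
    ``alpha_range``; the default Beta(2, 4) puts most mass at low alpha.
    ``obs_counts`` is the per-locality number of recorded conversations
    (street) or respondents (daily), scalar or per-locality sequence.
    ``alpha_override`` / ``use_override`` pin exact values instead of
    sampling (used e.g. to reproduce textbook two-locality examples).
    """

    true_params: EmpiricalParams
    n_localities: int = 200
    use_kind: str = "street"
    obs_counts: int | Sequence[int] = 500
    alpha_distribution: tuple[float, float] = (2.0, 4.0)
    alpha_range: tuple[float, float] = (0.02, 0.88)
    seed: int | None = None
    year_label: int = 2016
    alpha_override: Sequence[float] | None = None
    use_override: Sequence[float] | None = None
    max_clip_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_localities < 1:
            raise ConfigError("n_localities must be >= 1")
        if self.use_kind not in ("street", "daily"):
            raise ConfigError("use_kind must be 'street' or 'daily'")
        counts = np.atleast_1d(np.asarray(self.obs_counts))
        if np.any(counts < 1):
            raise ConfigError("obs_counts must be >= 1")
        lo, hi = self.alpha_range
        if not 0 < lo < hi < 1:
            raise ConfigError("alpha_range must satisfy 0 < lo < hi < 1")


def generate_localities(config: SyntheticConfig) -> pd.DataFrame:
    """Generate one synthetic survey year as a canonical locality table.

    Returns a DataFrame with columns locality_id, year, n_bilinguals,
    alpha, observed_use, use_kind, plus the side-channel column
    ``true_use`` (the noise-free model value, for recovery tests only).
    Reproducible given ``config.seed``.  If the true curve leaves [0, 1]
    on more than ``max_clip_fraction`` of localities the configuration is
    rejected; occasional clipping only warns.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_localities

    if config.alpha_override is not None:
        alpha = np.asarray(config.alpha_override, dtype=float)
        if alpha.size != L:
            raise ConfigError("alpha_override length must equal n_localities")
    else:
        a, b = config.alpha_distribution
        lo, hi = config.alpha_range
        alpha = lo + (hi - lo) * rng.beta(a, b, size=L)

    kind = config.use_kind
    params = config.true_params
    if params.model_kind != kind:
        params = replace(params, model_kind=kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu = np.asarray(predict_use(alpha, params), dtype=float)
    out_of_range = (mu < 0) | (mu > 1)
    if out_of_range.mean() > config.max_clip_fraction:
        raise ConfigError(
            f"true use curve leaves [0, 1] on {out_of_range.mean():.0%} of "
            "localities; choose saner true parameters"
        )
    if out_of_range.any():
        warnings.warn(
            f"true use clipped to [0, 1] on {int(out_of_range.sum())} "
            "localities", stacklevel=2,
        )
        mu = np.clip(mu, 0.0, 1.0)

    counts = np.broadcast_to(
        np.asarray(config.obs_counts, dtype=int), (L,)
    ).copy()
    if config.use_override is not None:
        observed = np.asarray(config.use_override, dtype=float)
        if observed.size != L:
            raise ConfigError("use_override length must equal n_localities")
    else:
        observed = rng.binomial(counts, mu) / counts

    return pd.DataFrame(
        {
            "locality_id": [f"L{i:04d}" for i in range(L)],
            "year": config.year_label,
            "n_bilinguals": counts,
            "alpha": alpha,
            "observed_use": observed,
            "use_kind": kind,
            "true_use": mu,
        }
    )


def drifting_configs(
    base: SyntheticConfig,
    years: Sequence[int],
    alpha_shift_per_year: float = 0.0,
) -> list[SyntheticConfig]:
    """Per-year configs with the alpha distribution's support shifted
    upward by a constant amount each year (localities gaining bilinguals
    over time).  Seeds are derived from the base seed per year."""
    configs = []
    for j, year in enumerate(years):
        lo, hi = base.alpha_range
        shift = j * alpha_shift_per_year
        lo2, hi2 = min(lo + shift, 0.95), min(hi + shift, 0.97)
        seed = None if base.seed is None else base.seed + 1000 * j
        configs.append(
            replace(base, year_label=int(year), alpha_range=(lo2, hi2), seed=seed)
        )
    return configs


def generate_panel(configs: Sequence[SyntheticConfig]) -> pd.DataFrame:
    """Concatenate per-year synthetic tables into a multi-year panel."""
    if len(configs) < 1:
        raise ConfigError("need at least one per-year config")
    tables = [generate_localities(c) for c in configs]
    panel = pd.concat(tables, ignore_index=True)
    if panel.duplicated(subset=["year", "locality_id"]).any():
        raise ConfigError("duplicated (year, locality_id) in panel")
    return panel


def records_from_table(table: pd.DataFrame) -> list[LocalityRecord]:
    """Convert a canonical table to LocalityRecord objects, dropping any
    side-channel columns (the estimation surface never sees true_use)."""
    return [
        LocalityRecord(
            locality_id=str(r.locality_id),
            year=int(r.year),
            n_bilinguals=int(r.n_bilinguals),
            alpha=float(r.alpha),
            observed_use=float(r.observed_use),
            use_kind=str(r.use_kind),
        )
        for r in table.itertuples(index=False)
    ]
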