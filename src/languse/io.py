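"""Readers/writers for locality survey tables and the pipeline driver.

The canonical on-disk schema is a UTF-8 comma-separated table with a
header row and columns ``locality_id, year, n_bilinguals, alpha,
observed_use, use_kind``.  Spreadsheet exports are converted once to
this schema (``import_spreadsheet``) rather than parsed everywhere, so
there is a single parsing path.  Proportions are unit-interval fractions
internally; a ``percent_columns`` flag divides alpha and observed_use by
100 at the boundary for tables following the percentage convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, SchemaError
from .equilibrium_models import EmpiricalParams, predict_use
from .estimation import bootstrap_band, fit_predictive_model, nonparametric_check
from .game_core import LocalityRecord
from .synthetic import SyntheticConfig, generate_localities, generate_panel

__all__ = [
    "REQUIRED_COLUMNS",
    "read_locality_table",
    "write_locality_table",
    "import_spreadsheet",
    "PipelineConfig",
    "run_pipeline",
]

REQUIRED_COLUMNS = (
    "locality_id",
    "year",
    "n_bilinguals",
    "alpha",
    "observed_use",
    "use_kind",
)


def read_locality_table(
    path,
    *,
    percent_columns: bool = False,
    column_map: dict[str, str] | None = None,
    delimiter: str = ",",
    max_reject_fraction: float = 0.10,
) -> list[LocalityRecord]:
    """Read a canonical locality table into LocalityRecord objects.

    ``column_map`` remaps source column names to canonical ones.  Rows
    violating the record invariants are rejected with their line numbers
    in a warning; the read aborts if more than ``max_reject_fraction`` of
    rows fail.  Values above 1 without the percent flag fail loudly via
    the invariants rather than being silently rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if percent_columns:
        df = df.copy()
        df["alpha"] = df["alpha"] / 100.0
        df["observed_use"] = df["observed_use"] / 100.0

    records: list[LocalityRecord] = []
    failures: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            records.append(
                LocalityRecord(
                    locality_id=str(row.locality_id),
                    year=int(row.year),
                    n_bilinguals=int(row.n_bilinguals),
                    alpha=float(row.alpha),
                    observed_use=float(row.observed_use),
                    use_kind=str(row.use_kind),
                )
            )
        except (InvalidInputError, ValueError, TypeError) as exc:
            failures.append(f"line {line_no}: {exc}")
    if failures:
        if len(failures) / len(df) > max_reject_fraction:
            raise SchemaError(
                f"{len(failures)}/{len(df)} rows failed validation:\n"
                + "\n".join(failures[:20])
            )
        warnings.warn(
            f"rejected {len(failures)} invalid rows:\n" + "\n".join(failures),
            stacklevel=2,
        )
    return records


def write_locality_table(records, path) -> Path:
    """Write records (or a canonical DataFrame) as a canonical CSV."""
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records[list(REQUIRED_COLUMNS)]
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        df = df[list(REQUIRED_COLUMNS)]
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def import_spreadsheet(
    path,
    out_csv,
    *,
    sheet: str | int = 0,
    column_map: dict[str, str] | None = None,
    percent_columns: bool = False,
) -> Path:
    """Convert a spreadsheet survey export to the canonical CSV schema."""
    df = pd.read_excel(path, sheet_name=sheet)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns after remapping: {missing}")
    if percent_columns:
        df["alpha"] = df["alpha"] / 100.0
        df["observed_use"] = df["observed_use"] / 100.0
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    df[list(REQUIRED_COLUMNS)].to_csv(out_csv, index=False)
    return out_csv


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``input_path`` (canonical CSV) or ``synthetic``
    (generator config or list of per-year configs) must be given.
    """

    model_kind: str
    language_label: str = "custom"
    input_path: str | None = None
    synthetic: SyntheticConfig | Sequence[SyntheticConfig] | None = None
    percent_columns: bool = False
    n_boot: int = 999
    level: float = 0.90
    n_grid: int = 25
    seed: int = 0
    out_dir: str = "languse_run"
    run_np_check: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of input_path / synthetic must be provided"
            )
        if not 0 < self.level < 1:
            raise ConfigError("level must lie in (0, 1)")
        if self.model_kind not in ("street", "daily"):
            raise ConfigError("model_kind must be 'street' or 'daily'")


def _table_from_config(config: PipelineConfig) -> pd.DataFrame:
    if config.input_path is not None:
        records = read_locality_table(
            config.input_path, percent_columns=config.percent_columns
        )
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    syn = config.synthetic
    if isinstance(syn, SyntheticConfig):
        table = generate_localities(syn)
    else:
        table = generate_panel(list(syn))
    return table.drop(columns=["true_use"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run fit + bootstrap band + nonparametric check per survey year.

    Writes, per year: a JSON fit report, the band table, the
    nonparametric-check table and a prediction curve over the alpha
    grid, plus a machine-readable run manifest with an input hash, the
    seed and package versions.  Deterministic given the config and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = _table_from_config(config)
    table_csv = table.to_csv(index=False)
    input_hash = hashlib.sha256(table_csv.encode()).hexdigest()

    artifacts: dict = {"years": {}, "out_dir": str(out_dir)}
    errors: dict[str, str] = {}
    for j, (year, sub) in enumerate(sorted(table.groupby("year"))):
        tag = f"{config.language_label}_{year}"
        year_seed = config.seed + 7919 * j
        try:
            fit = fit_predictive_model(sub, config.model_kind)
            grid = np.linspace(
                sub["alpha"].min(), sub["alpha"].max(), config.n_grid
            )
            band = bootstrap_band(
                sub,
                config.model_kind,
                fit,
                n_boot=config.n_boot,
                level=config.level,
                alpha_grid=grid,
                seed=year_seed,
            )
            fit.band = band
            if config.run_np_check:
                np_table, share = nonparametric_check(sub, band)
                fit.np_check = np_table
                fit.np_inside_share = share
                np_table.to_csv(out_dir / f"np_check_{tag}.csv", index=False)
            band.to_csv(out_dir / f"band_{tag}.csv", index=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = pd.DataFrame(
                    {"alpha": grid, "predicted_use": predict_use(grid, fit.params)}
                )
            curve.to_csv(out_dir / f"curve_{tag}.csv", index=False)
            report = fit.report()
            report["year"] = int(year)
            report["level"] = config.level
            report["n_boot"] = config.n_boot
            with open(out_dir / f"fit_{tag}.json", "w") as fh:
                json.dump(report, fh, indent=2)
            artifacts["years"][int(year)] = fit
        except Exception as exc:  # propagate per-stage failures loudly
            errors[tag] = f"{type(exc).__name__}: {exc}"

    import languse

    manifest = {
        "language_label": config.language_label,
        "model_kind": config.model_kind,
        "input_hash": input_hash,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "level": config.level,
        "package_version": languse.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "years": sorted(int(y) for y in table["year"].unique()),
        "errors": errors,
        "complete": not errors,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = manifest
    if errors:
        raise RuntimeError(f"pipeline stages failed: {errors}")
    return artifacts
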