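"""CSV readers/writers for timestamped series and experiment configs.

The on-disk carrier for a signal is a two-column CSV — absolute seconds from
recording start, then the sample value — so any capture pipeline that logs
frame timestamps can feed the correction chain.  Experiment configuration
files are flat ``key = value`` text mirroring the ExperimentConfig fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .evaluation import ExperimentConfig
from .hr import SpectrumBand
from .interpolators import CICConfig
from .synthesis import SampledSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesFileDialect:
    """CSV shape of a series file: delimiter, column names, header flag."""

    delimiter: str = ","
    timestamp_column: str = "timestamp_s"
    value_column: str = "value"
    header: bool = True


DEFAULT_DIALECT = SeriesFileDialect()


def read_series(
    path, dialect: SeriesFileDialect = DEFAULT_DIALECT
) -> SampledSeries:
    """Read a timestamped series from CSV, sorted by timestamp.

    Rows with non-finite timestamp or value are dropped with a logged count.
    """
    if dialect.header:
        df = pd.read_csv(path, sep=dialect.delimiter)
        for col in (dialect.timestamp_column, dialect.value_column):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r} in {path}")
        df = df[[dialect.timestamp_column, dialect.value_column]]
    else:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=None,
            names=[dialect.timestamp_column, dialect.value_column],
        )
    t = pd.to_numeric(df[dialect.timestamp_column], errors="coerce").to_numpy(float)
    v = pd.to_numeric(df[dialect.value_column], errors="coerce").to_numpy(float)
    ok = np.isfinite(t) & np.isfinite(v)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("read_series: dropped %d non-finite row(s) from %s", dropped, path)
    t, v = t[ok], v[ok]
    if len(t) < 1:
        raise ValueError(f"no valid rows in {path}")
    order = np.argsort(t, kind="stable")
    return SampledSeries(t[order], v[order])


def write_series(
    series: SampledSeries, path, dialect: SeriesFileDialect = DEFAULT_DIALECT
) -> None:
    """Write a series as CSV at full double precision (locale-independent)."""
    df = pd.DataFrame(
        {
            dialect.timestamp_column: series.timestamps,
            dialect.value_column: series.values,
        }
    )
    df.to_csv(
        path,
        sep=dialect.delimiter,
        index=False,
        header=dialect.header,
        float_format="%.17g",
    )


# ---------------------------------------------------------------------------
# Flat key=value experiment configuration
# ---------------------------------------------------------------------------

_LIST_KEYS = {"loss_grid", "ratio_grid", "methods"}
_INT_KEYS = {"n_trials", "master_seed", "cic_r", "cic_n", "cic_m", "n_sources"}
_FLOAT_KEYS = {
    "duration_s",
    "nominal_rate_hz",
    "gen_rate_hz",
    "band_lo_hz",
    "band_hi_hz",
    "amplitude",
    "hr_bpm",
}
_BOOL_KEYS = {"normalize_by_amplitude"}


def parse_config_text(text: str) -> dict:
    """Parse flat ``key = value`` lines (# comments, blank lines ignored)."""
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _LIST_KEYS:
            items = [s.strip() for s in value.split(",") if s.strip()]
            out[key] = (
                items if key == "methods" else [float(s) for s in items]
            )
        elif key in _INT_KEYS:
            out[key] = int(value)
        elif key in _FLOAT_KEYS:
            out[key] = float(value)
        elif key in _BOOL_KEYS:
            out[key] = value.lower() in ("1", "true", "yes", "on")
        else:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
    return out


def experiment_config_from_mapping(mapping: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a parsed flat config mapping.

    Keys not belonging to ExperimentConfig (hr_bpm, n_sources) are ignored
    here; callers that need them read the mapping directly.
    """
    kwargs: dict = {}
    for key in (
        "duration_s",
        "nominal_rate_hz",
        "gen_rate_hz",
        "n_trials",
        "master_seed",
        "amplitude",
        "normalize_by_amplitude",
    ):
        if key in mapping:
            kwargs[key] = mapping[key]
    if "loss_grid" in mapping:
        kwargs["loss_grid"] = tuple(int(k) for k in mapping["loss_grid"])
    if "ratio_grid" in mapping:
        kwargs["ratio_grid"] = tuple(float(r) for r in mapping["ratio_grid"])
    if "methods" in mapping:
        kwargs["methods"] = tuple(mapping["methods"])
    if "band_lo_hz" in mapping or "band_hi_hz" in mapping:
        kwargs["band"] = SpectrumBand(
            mapping.get("band_lo_hz", 0.8), mapping.get("band_hi_hz", 1.8)
        )
    if any(k in mapping for k in ("cic_r", "cic_n", "cic_m")):
        kwargs["cic_cfg"] = CICConfig(
            R=mapping.get("cic_r", 10), N=mapping.get("cic_n", 4), M=mapping.get("cic_m", 2)
        )
    return ExperimentConfig(**kwargs)


def load_experiment_config(path) -> tuple:
    """Read a flat config file; returns (ExperimentConfig, raw mapping)."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = parse_config_text(fh.read())
    return experiment_config_from_mapping(mapping), mapping
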