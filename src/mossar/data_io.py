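"""Shared data model and CSV input/output.

Defines the plot environment table, per-scale presence/absence matrices,
nested subplot scales, per-plot richness and sample-based rarefaction.
All tables are plain CSV (UTF-8, comma separated, header row, "." decimal);
plot identifiers are opaque strings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTORS",
    "ENVIRONMENTS",
    "SIDE_LENGTHS",
    "SubplotScale",
    "PlotTable",
    "OccurrenceMatrix",
    "RarefactionCurve",
    "DataLoadError",
    "read_environment_table",
    "write_environment_table",
    "read_occurrence_matrix",
    "write_occurrence_matrix",
    "richness_by_scale",
    "rarefaction_curve",
    "write_metadata_sidecar",
]

#: canonical predictor column names, in reporting order
PREDICTORS = ("Bio1", "Bio6", "Bio7", "Bio12", "Bio14", "WS", "NPP", "NDVI", "HD")

ENVIRONMENTS = ("grassland", "forest", "alpine meadow", "alpine rocky meadow")

#: nested subplot side lengths in metres, smallest to largest
SIDE_LENGTHS = (0.01, 0.1, 0.5, 1.0, 5.0, 10.0)

_REQUIRED_COLUMNS = ("plot_id", "lon", "lat", "elevation", "environment") + PREDICTORS


class DataLoadError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass(frozen=True, order=True)
class SubplotScale:
    """One level of the nested design, identified by subplot side length (m)."""

    side_length: float

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError(f"side_length must be positive, got {self.side_length}")

    @property
    def area(self) -> float:
        """Subplot area in m² (side length squared, exactly)."""
        return self.side_length * self.side_length

    @classmethod
    def from_side(cls, side_length: float) -> "SubplotScale":
        return cls(float(side_length))

    @classmethod
    def from_area(cls, area: float) -> "SubplotScale":
        return cls(float(np.sqrt(area)))

    @classmethod
    def standard(cls) -> tuple["SubplotScale", ...]:
        """The six scales of the standard nested design, ascending."""
        return tuple(cls(s) for s in SIDE_LENGTHS)

    def label(self) -> str:
        side = self.side_length
        return f"{side:g}m"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SubplotScale(side={self.side_length:g} m, area={self.area:g} m²)"


@dataclass
class PlotTable:
    """Per-plot coordinates, elevation, environment class and covariates.

    ``data`` is indexed by ``plot_id`` (string) and carries columns
    ``lon``, ``lat``, ``elevation``, ``environment`` and the nine canonical
    predictors in :data:`PREDICTORS` order.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "plot_id":
            raise DataLoadError("PlotTable index must be named 'plot_id'")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataLoadError(f"duplicate plot_id values: {dupes}")
        missing = [c for c in ("lon", "lat", "elevation", "environment") + PREDICTORS
                   if c not in df.columns]
        if missing:
            raise DataLoadError(f"missing required columns: {missing}")
        numeric = ["lon", "lat", "elevation", *PREDICTORS]
        bad = df[numeric].columns[df[numeric].isna().any()].tolist()
        if bad:
            raise DataLoadError(f"missing or non-numeric values in columns: {bad}")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_plots(self) -> int:
        return len(self.data)

    @property
    def elevation(self) -> pd.Series:
        return self.data["elevation"]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lon, lat) in decimal degrees."""
        return self.data[["lon", "lat"]].to_numpy(float)

    def covariates(self, names: Sequence[str] = PREDICTORS) -> pd.DataFrame:
        return self.data[list(names)].copy()

    def order_by_elevation(self) -> "PlotTable":
        """Plots sorted by elevation, ties broken by plot_id."""
        df = self.data.copy()
        df["_pid"] = df.index
        df = df.sort_values(["elevation", "_pid"]).drop(columns="_pid")
        return PlotTable(df)


@dataclass
class OccurrenceMatrix:
    """Presence/absence of species in plots at one subplot scale.

    ``data`` is indexed by plot_id with one 0/1 integer column per species.
    """

    scale: SubplotScale
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "plot_id":
            raise DataLoadError("OccurrenceMatrix index must be named 'plot_id'")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataLoadError(f"duplicate species columns: {dupes}")
        values = df.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataLoadError(
                f"occurrence cell not in {{0,1}}: value {values[i, j]!r} at "
                f"plot {df.index[i]!r}, species {df.columns[j]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int8))

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_species(self) -> int:
        return self.data.shape[1]

    @property
    def presence(self) -> np.ndarray:
        return self.data.to_numpy()

    def align_to(self, plots: PlotTable) -> "OccurrenceMatrix":
        """Reorder rows to match a PlotTable; every plot must be present."""
        missing = [p for p in plots.plot_ids if p not in self.data.index]
        if missing:
            raise DataLoadError(f"occurrence matrix lacks plots: {missing}")
        extra = [p for p in self.data.index if p not in set(plots.plot_ids)]
        if extra:
            raise DataLoadError(f"occurrence matrix has unknown plots: {extra}")
        return OccurrenceMatrix(self.scale, self.data.loc[plots.plot_ids])


@dataclass
class RarefactionCurve:
    """Sample-based rarefaction: expected richness in random plot subsets."""

    n_plots: np.ndarray
    mean_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


# ---------------------------------------------------------------------------
# CSV I/O

def _normalize_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical names, case-insensitively."""
    canon = {c.lower(): c for c in _REQUIRED_COLUMNS}
    out = {}
    for col in columns:
        key = col.strip().lower()
        if key in canon:
            out[col] = canon[key]
    return out


def read_environment_table(path: str | Path) -> PlotTable:
    """Load and validate a plot environment CSV.

    Column names are matched case-insensitively against the canonical set.
    Rows with missing covariates are rejected with an explicit error.
    """
    raw = pd.read_csv(path, dtype={"plot_id": str})
    raw = raw.rename(columns=_normalize_columns(raw.columns))
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise DataLoadError(f"{path}: missing required column(s) {missing}")
    raw["plot_id"] = raw["plot_id"].astype(str)
    for col in ("lon", "lat", "elevation", *PREDICTORS):
        try:
            raw[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise DataLoadError(f"{path}: non-numeric value in column {col!r}: {exc}") from exc
    df = raw.set_index("plot_id")
    keep = ["lon", "lat", "elevation", "environment", *PREDICTORS]
    extra = [c for c in df.columns if c not in keep]
    return PlotTable(df[keep + extra])


def write_environment_table(plots: PlotTable, path: str | Path) -> None:
    plots.data.to_csv(path, index=True)


def read_occurrence_matrix(
    path: str | Path,
    scale: SubplotScale,
    plots: PlotTable | None = None,
) -> OccurrenceMatrix:
    """Load a plots × species 0/1 CSV; optionally align rows to a PlotTable."""
    raw = pd.read_csv(path, dtype={0: str})
    first = raw.columns[0]
    raw = raw.rename(columns={first: "plot_id"})
    raw["plot_id"] = raw["plot_id"].astype(str)
    df = raw.set_index("plot_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1])
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DataLoadError(
                f"{path}: cell not in {{0,1}} at plot {row!r}, species {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = vals.astype(np.int8)
    occ = OccurrenceMatrix(scale, df)
    if plots is not None:
        occ = occ.align_to(plots)
    return occ


def write_occurrence_matrix(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.data.to_csv(path, index=True)


def write_metadata_sidecar(path: str | Path, **fields) -> None:
    """Write a JSON run-metadata sidecar next to an output CSV."""
    import mossar

    meta = {"mossar_version": mossar.__version__, **fields}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# Richness summaries

def richness_by_scale(occ: OccurrenceMatrix) -> pd.Series:
    """Per-plot species richness (row sums) at one scale."""
    return occ.data.sum(axis=1).astype(int)


def check_nestedness(
    matrices: dict[SubplotScale, OccurrenceMatrix], strict: bool = False
) -> list[str]:
    """Verify presence at a smaller scale implies presence at every larger one.

    Returns human-readable violation messages; warns (or raises when
    ``strict``) if any are found. Field data may legitimately violate
    nesting through recording noise, so the default is a warning.
    """
    scales = sorted(matrices)
    problems: list[str] = []
    for small, large in zip(scales, scales[1:]):
        a, b = matrices[small].data, matrices[large].data
        common = [s for s in a.columns if s in b.columns]
        diff = a[common].to_numpy() > b[common].to_numpy()
        if diff.any():
            n = int(diff.sum())
            problems.append(
                f"{n} presence(s) at {small.label()} absent at {large.label()}"
            )
    if problems:
        msg = "nestedness violations: " + "; ".join(problems)
        if strict:
            raise DataLoadError(msg)
        warnings.warn(msg, stacklevel=2)
    return problems


def rarefaction_curve(
    occ: OccurrenceMatrix, n_resamples: int = 200, seed: int = 0
) -> RarefactionCurve:
    """Sample-based rarefaction with percentile confidence bands.

    For each m = 1..N, draws ``n_resamples`` random m-plot subsets without
    replacement and records the pooled species count; the curve reports the
    mean and the 2.5/97.5 percentiles. At m = N every subset is the full
    sample, so the mean equals total richness and the band has zero width.
    """
    if n_resamples < 1:
        raise ValueError(f"n_resamples must be >= 1, got {n_resamples}")
    rng = np.random.default_rng(seed)
    pres = occ.presence.astype(bool)
    n = pres.shape[0]
    mean = np.empty(n)
    lo = np.empty(n)
    hi = np.empty(n)
    for m in range(1, n + 1):
        counts = np.empty(n_resamples)
        for b in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            counts[b] = pres[idx].any(axis=0).sum()
        mean[m - 1] = counts.mean()
        lo[m - 1] = np.percentile(counts, 2.5)
        hi[m - 1] = np.percentile(counts, 97.5)
    return RarefactionCurve(np.arange(1, n + 1), mean, lo, hi)


def rarefaction_exact_mean(occ: OccurrenceMatrix) -> np.ndarray:
    """Closed-form expected rarefaction curve (hypergeometric mean).

    E[S(m)] = sum_s 1 - C(N - n_s, m) / C(N, m), where n_s is the number of
    plots occupied by species s. Deterministic alternative backend to the
    resampling estimate.
    """
    from scipy.special import gammaln

    pres = occ.presence
    n = pres.shape[0]
    occ_counts = pres.sum(axis=0)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(n)
    for m in range(1, n + 1):
        with np.errstate(invalid="ignore"):
            log_p_absent = log_comb(n - occ_counts, m) - log_comb(n, m)
        p_absent = np.where(n - occ_counts >= m, np.exp(log_p_absent), 0.0)
        out[m - 1] = np.sum(1.0 - p_absent)
    return out
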