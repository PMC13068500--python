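"""Synthetic nested-plot communities with known ground truth.

Generates a plot environment table along an elevational transect with
coarse-grained covariates, and presence/absence matrices at the six nested
scales whose expected richness tracks plantable c(elev)·A^z(elev) power
laws. Every stochastic draw flows from one seeded generator, so identical
seed + parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from mossar.data_io import (
    ENVIRONMENTS,
    PREDICTORS,
    OccurrenceMatrix,
    PlotTable,
    SubplotScale,
)

__all__ = [
    "SyntheticTruth",
    "generate_environment",
    "generate_community",
    "make_truth",
    "default_truth",
    "hump_truth",
]

#: elevation band edges assigning the four environment classes
_ENV_BANDS = (2300.0, 2600.0, 2850.0)


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic community.

    ``c_fun`` and ``z_fun`` are the true SAR parameter surfaces over
    elevation (z values must stay in (0, 1)); ``species_ranges`` are
    per-species elevational intervals that drive range-based (mid-domain)
    structure.
    """

    c_fun: Callable[[np.ndarray], np.ndarray]
    z_fun: Callable[[np.ndarray], np.ndarray]
    species_ranges: np.ndarray  # (S, 2) lo/hi elevations, metres
    seed: int = 0

    def __post_init__(self) -> None:
        ranges = np.asarray(self.species_ranges, float)
        if ranges.ndim != 2 or ranges.shape[1] != 2:
            raise ValueError("species_ranges must be (S, 2)")
        if (ranges[:, 0] > ranges[:, 1]).any():
            raise ValueError("species range lo > hi")
        self.species_ranges = ranges

    @property
    def n_species(self) -> int:
        return len(self.species_ranges)

    @property
    def species_names(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{str(i + 1).zfill(width)}" for i in range(self.n_species)]


# ---------------------------------------------------------------------------
# Environment generation

# smooth covariate surfaces over elevation; monotone unless noted unimodal
def _covariate_functions(elev_min: float, elev_max: float):
    span = elev_max - elev_min

    def t(e):  # 0..1 along the gradient
        return (np.asarray(e, float) - elev_min) / span

    return {
        "Bio1": lambda e: 4.0 - 10.0 * t(e),             # °C, decreasing
        "Bio6": lambda e: -12.0 - 9.0 * t(e),            # °C, decreasing
        "Bio7": lambda e: 34.0 + 4.0 * t(e),             # °C, increasing
        "Bio12": lambda e: 450.0 + 250.0 * t(e),         # mm, increasing
        "Bio14": lambda e: 3.0 + 6.0 * t(e),             # mm, increasing
        "WS": lambda e: 2.0 + 2.5 * t(e),                # m/s, increasing
        "NPP": lambda e: 0.2 + 0.5 * np.exp(-((t(e) - 0.4) ** 2) / 0.08),  # unimodal
        "NDVI": lambda e: 0.3 + 0.25 * np.exp(-((t(e) - 0.35) ** 2) / 0.1),  # unimodal
    }


def _environment_class(elevation: np.ndarray) -> np.ndarray:
    labels = np.empty(len(elevation), dtype=object)
    labels[:] = ENVIRONMENTS[0]
    labels[elevation >= _ENV_BANDS[0]] = ENVIRONMENTS[1]
    labels[elevation >= _ENV_BANDS[1]] = ENVIRONMENTS[2]
    labels[elevation >= _ENV_BANDS[2]] = ENVIRONMENTS[3]
    return labels


def generate_environment(
    n_plots: int = 56,
    elev_min: float = 1960.0,
    elev_max: float = 3060.0,
    grid_size: float = 1000.0,
    seed: int = 0,
    plot_spacing: float = 150.0,
) -> PlotTable:
    """Plots at even elevation spacing along a transect with coarse covariates.

    Covariates are smooth functions of elevation evaluated at the plot's
    position snapped to a ``grid_size``-metre lattice along the transect, so
    with a coarse grid consecutive plots share identical covariate values
    (few unique values). ``grid_size`` → 0 recovers strictly smooth values.
    """
    if n_plots < 2:
        raise ValueError("need at least 2 plots")
    if elev_max <= elev_min:
        raise ValueError("degenerate elevation span")
    if grid_size < 0:
        raise ValueError("grid_size must be >= 0")

    rng = np.random.default_rng(seed)
    elevation = np.linspace(elev_min, elev_max, n_plots)
    # transect distance in metres, proportional to elevation
    distance = np.arange(n_plots) * plot_spacing
    if grid_size > 0:
        snapped = (np.floor(distance / grid_size) + 0.5) * grid_size
    else:
        snapped = distance
    # elevation at the snapped position, linear along the transect
    slope = (elev_max - elev_min) / (distance[-1] if distance[-1] > 0 else 1.0)
    elev_at_snap = elev_min + slope * snapped

    # WGS84 coordinates: transect heading NE with small deterministic jitter
    lat0, lon0 = 39.0, 113.5
    m_per_deg = 111_000.0
    jitter = rng.normal(scale=20.0, size=(n_plots, 2))  # metres
    lat = lat0 + (distance * 0.8 + jitter[:, 0]) / m_per_deg
    lon = lon0 + (distance * 0.6 + jitter[:, 1]) / (m_per_deg * np.cos(np.radians(lat0)))

    funcs = _covariate_functions(elev_min, elev_max)
    cols = {name: f(elev_at_snap) for name, f in funcs.items()}
    # habitat diversity: integer 0..4, unimodal expectation over elevation
    hd_mean = 1.0 + 2.5 * np.exp(-(((elevation - elev_min) / (elev_max - elev_min) - 0.45) ** 2) / 0.12)
    cols["HD"] = np.clip(np.round(hd_mean + rng.normal(scale=0.5, size=n_plots)), 0, 4)

    width = len(str(n_plots))
    df = pd.DataFrame(
        {
            "lon": lon,
            "lat": lat,
            "elevation": elevation,
            "environment": _environment_class(elevation),
            **{name: cols[name] for name in PREDICTORS},
        },
        index=pd.Index([f"P{str(i + 1).zfill(width)}" for i in range(n_plots)], name="plot_id"),
    )
    return PlotTable(df)


# ---------------------------------------------------------------------------
# Truth construction helpers

def make_truth(
    c_fun: Callable[[np.ndarray], np.ndarray],
    z_fun: Callable[[np.ndarray], np.ndarray],
    n_species: int = 300,
    elev_min: float = 1960.0,
    elev_max: float = 3060.0,
    mean_range_frac: float = 0.6,
    seed: int = 0,
) -> SyntheticTruth:
    """Random species elevational ranges under the given SAR surfaces."""
    rng = np.random.default_rng(seed)
    span = elev_max - elev_min
    widths = np.clip(rng.beta(2.0, 2.0 / mean_range_frac - 2.0 + 1e-9, n_species) * span,
                     0.02 * span, span)
    mids = rng.uniform(elev_min, elev_max, n_species)
    lo = np.clip(mids - widths / 2, elev_min, elev_max)
    hi = np.clip(mids + widths / 2, elev_min, elev_max)
    return SyntheticTruth(c_fun, z_fun, np.column_stack([lo, hi]), seed=seed)


def default_truth(seed: int = 0, **kwargs) -> SyntheticTruth:
    """Mildly hump-shaped c, increasing z; a paper-like default surface."""
    def c_fun(e):
        t = (np.asarray(e, float) - 1960.0) / 1100.0
        return 3.0 + 9.0 * np.exp(-((t - 0.4) ** 2) / 0.09)

    def z_fun(e):
        t = (np.asarray(e, float) - 1960.0) / 1100.0
        return 0.08 + 0.10 * t

    return make_truth(c_fun, z_fun, seed=seed, **kwargs)


def hump_truth(peak: float = 2400.0, seed: int = 0, **kwargs) -> SyntheticTruth:
    """Richness hump at ``peak`` m at fine scales, saturating rise at 100 m².

    Expected richness at 1 m² equals c(e), a hump centred on ``peak``;
    z(e) is chosen so that expected richness at the full 100 m² plot,
    c(e)·100^z(e), follows an explicitly monotone saturating rise over the
    gradient — so the mid-elevation peak exists only at fine scales.
    """
    def c_fun(e):
        e = np.asarray(e, float)
        return 4.0 + 24.0 * np.exp(-(((e - peak) / 300.0) ** 2))

    def s100_target(e):
        t = (np.asarray(e, float) - 1960.0) / 1100.0
        return 15.0 + 45.0 * (1.0 - np.exp(-2.0 * np.clip(t, 0.0, 1.0)))

    def z_fun(e):
        return np.log(s100_target(e) / c_fun(e)) / np.log(100.0)

    return make_truth(c_fun, z_fun, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Community generation

def generate_community(
    plots: PlotTable, truth: SyntheticTruth
) -> dict[SubplotScale, OccurrenceMatrix]:
    """One strictly nested occurrence matrix per standard scale.

    A species is eligible in a plot iff the plot elevation falls inside its
    range. Eligible species occupy the largest (100 m²) plot with a per-plot
    probability chosen so the expected full-plot richness equals
    c(elev)·A_max^z(elev); occupancy at smaller areas is a nested thinning
    with retention (A/A_max)^z(elev), so expected richness at every area A
    equals c(elev)·A^z(elev) exactly. Nesting across scales holds by
    construction: retention is monotone in A and one latent uniform per
    plot × species decides presence at every scale at once.
    """
    scales = SubplotScale.standard()
    a_max = scales[-1].area
    elev = plots.elevation.to_numpy()
    z = np.clip(truth.z_fun(elev), 1e-6, 1.0 - 1e-6)
    ranges = truth.species_ranges
    if ranges[:, 0].min() < elev.min() - 1e-9 or ranges[:, 1].max() > elev.max() + 1e-9:
        raise ValueError("truth species ranges extend outside the plot elevation span")

    eligible = (elev[:, None] >= ranges[None, :, 0]) & (elev[:, None] <= ranges[None, :, 1])
    n_eligible = eligible.sum(axis=1)
    target_100 = truth.c_fun(elev) * a_max**z
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(n_eligible > 0, np.minimum(1.0, target_100 / n_eligible), 0.0)

    rng = np.random.default_rng(truth.seed)
    u_occ = rng.random(eligible.shape)
    occupied_100 = eligible & (u_occ < q[:, None])
    # latent uniform per plot×species: present at area A iff v <= (A/A_max)^z
    v = rng.random(eligible.shape)

    names = truth.species_names
    out: dict[SubplotScale, OccurrenceMatrix] = {}
    for scale in scales:
        retention = (scale.area / a_max) ** z[:, None]
        present = occupied_100 & (v <= retention)
        df = pd.DataFrame(
            present.astype(np.int8), index=plots.data.index.copy(), columns=names
        )
        out[scale] = OccurrenceMatrix(scale, df)
    return out
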