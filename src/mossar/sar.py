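"""Per-plot power-law species-area fits and environment comparisons.

The power model S = c·A^z is fit by untransformed nonlinear least squares
(Gaussian error) with standard errors from the asymptotic covariance; a
log-log ordinary-least-squares fit over positive points is the documented
fallback when NLS fails, recorded with ``converged=False``. 1/SE weights
accompany each estimate for use in downstream weighted models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mossar.data_io import OccurrenceMatrix, PlotTable, SubplotScale, richness_by_scale

__all__ = ["SARFit", "SARFitError", "fit_power_sar", "fit_all_plots", "compare_environments"]

log = logging.getLogger(__name__)


class SARFitError(ValueError):
    """Raised when a species-area curve cannot be fit."""


@dataclass
class SARFit:
    plot_id: str
    c: float
    z: float
    se_c: float
    se_z: float
    r2: float
    converged: bool

    @property
    def weight_c(self) -> float:
        return 1.0 / self.se_c if self.se_c > 0 else np.inf

    @property
    def weight_z(self) -> float:
        return 1.0 / self.se_z if self.se_z > 0 else np.inf

    @property
    def z_in_range(self) -> bool:
        """True when z falls inside the conventional [0, 1] band."""
        return 0.0 <= self.z <= 1.0


def _loglog_start(areas: np.ndarray, richness: np.ndarray) -> tuple[float, float]:
    """(c0, z0) from OLS of log S on log A over points with S > 0."""
    pos = richness > 0
    if pos.sum() < 2:
        raise SARFitError("fewer than 2 positive-richness points for log-log start")
    la, ls = np.log(areas[pos]), np.log(richness[pos].astype(float))
    slope, intercept = np.polyfit(la, ls, 1)
    return float(np.exp(intercept)), float(slope)


def fit_power_sar(areas, richness, plot_id: str = "") -> SARFit:
    """Fit S = c·A^z to one plot's nested richness vector.

    Requires at least three distinct areas and at least one positive
    richness value. Non-decreasing richness with area is expected for a
    nested design; violations are warned, not rejected.
    """
    areas = np.asarray(areas, float)
    richness = np.asarray(richness, float)
    if areas.shape != richness.shape:
        raise SARFitError("areas and richness must have equal length")
    if len(np.unique(areas)) < 3:
        raise SARFitError("need >= 3 distinct areas")
    if (richness < 0).any():
        raise SARFitError("negative richness")
    if not richness.any():
        raise SARFitError(f"all-zero richness{f' for plot {plot_id}' if plot_id else ''}")
    order = np.argsort(areas)
    if (np.diff(richness[order]) < 0).any():
        warnings.warn(
            f"richness not non-decreasing with area{f' for plot {plot_id}' if plot_id else ''}",
            stacklevel=2,
        )

    if np.ptp(richness) == 0:  # flat curve: exact solution, NLS covariance singular in z
        return SARFit(plot_id, float(richness[0]), 0.0, np.nan, np.nan, 1.0, True)

    c0, z0 = _loglog_start(areas, richness)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                lambda a, c, z: c * np.power(a, z),
                areas,
                richness,
                p0=(c0, z0),
                maxfev=10_000,
            )
        if not (np.isfinite(popt).all() and np.isfinite(pcov).all()):
            raise RuntimeError("non-finite NLS solution")
        c, z = float(popt[0]), float(popt[1])
        se_c, se_z = (float(x) for x in np.sqrt(np.diag(pcov)))
        converged = True
    except (RuntimeError, optimize.OptimizeWarning):
        # log-log OLS fallback over positive points, never silently mixed
        pos = richness > 0
        la, ls = np.log(areas[pos]), np.log(richness[pos])
        res = stats.linregress(la, ls)
        c, z = float(np.exp(res.intercept)), float(res.slope)
        se_c = float(c * res.intercept_stderr) if np.isfinite(res.intercept_stderr) else np.nan
        se_z = float(res.stderr) if np.isfinite(res.stderr) else np.nan
        converged = False

    pred = c * np.power(areas, z)
    ss_res = float(np.sum((richness - pred) ** 2))
    ss_tot = float(np.sum((richness - richness.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SARFit(plot_id, c, z, se_c, se_z, r2, converged)


def fit_all_plots(
    occ_by_scale: dict[SubplotScale, OccurrenceMatrix], plots: PlotTable
) -> pd.DataFrame:
    """One SAR fit per plot across all scales; failed fits become log entries.

    Returns a frame indexed by plot_id with columns c, se_c, z, se_z, r2,
    converged. Plots whose curve cannot be fit are omitted.
    """
    scales = sorted(occ_by_scale)
    areas = np.array([s.area for s in scales])
    richness = pd.DataFrame(
        {s.label(): richness_by_scale(occ_by_scale[s].align_to(plots)) for s in scales}
    )
    rows = []
    for pid in plots.plot_ids:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_power_sar(areas, richness.loc[pid].to_numpy(), plot_id=pid)
        except SARFitError as exc:
            log.warning("plot %s: SAR fit failed (%s); row omitted", pid, exc)
            continue
        rows.append(
            {"plot_id": fit.plot_id, "c": fit.c, "se_c": fit.se_c, "z": fit.z,
             "se_z": fit.se_z, "r2": fit.r2, "converged": fit.converged}
        )
    return pd.DataFrame(rows).set_index("plot_id")


def compare_environments(
    fits: pd.DataFrame, plots: PlotTable, parameters: tuple[str, ...] = ("c", "z")
) -> pd.DataFrame:
    """Welch two-sample t-tests of c and z between every environment pair.

    Groups with fewer than two members are excluded with a warning.
    Holm-adjusted p-values are reported alongside raw ones (adjusted within
    each parameter's family of pairwise tests).
    """
    env = plots.data.loc[fits.index, "environment"]
    groups = {g: idx for g, idx in env.groupby(env).groups.items()}
    usable = {}
    for g, idx in groups.items():
        if len(idx) < 2:
            warnings.warn(f"environment {g!r} has < 2 plots; excluded", stacklevel=2)
        else:
            usable[g] = idx
    if len(usable) < 2:
        raise ValueError("need >= 2 environments with >= 2 plots each")

    rows = []
    for param in parameters:
        pairs = list(combinations(sorted(usable), 2))
        raw = []
        for a, b in pairs:
            xa = fits.loc[fits.index.intersection(usable[a]), param].dropna()
            xb = fits.loc[fits.index.intersection(usable[b]), param].dropna()
            if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0 and xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
            raw.append((a, b, float(t), float(p), len(xa), len(xb)))
        p_holm = _holm([r[3] for r in raw])
        for (a, b, t, p, na, nb), ph in zip(raw, p_holm):
            rows.append(
                {"parameter": param, "group_a": a, "group_b": b, "t": t,
                 "p": p, "p_holm": ph, "n_a": na, "n_b": nb}
            )
    return pd.DataFrame(rows)


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjustment."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
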