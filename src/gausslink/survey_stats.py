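"""Population statistics over a table of per-domain entanglement profiles.

The survey works on a tidy DataFrame (one row per domain) with columns
``domain_id``, ``n_residues``, ``gn``, ``gc``, ``gmax`` and optional label
columns.  It produces:

* the signed-Gmax' histogram (the hallmark of the survey: peaks near
  |Gmax'| ~ 1 for single-winding motifs, shoulders at 0.2-0.3 for
  non-entangled structures, tails beyond 1.5 for double windings);
* the entanglement survival function - the fraction of domains whose
  indicator modulus exceeds a threshold;
* the four kind/chirality grouping fractions among survivors whose GN'
  and GC' share a sign;
* domain-level bootstrap percentile bands for any of these statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .entanglement_core import EntanglementProfile

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_N_BOOT = 10_000
DEFAULT_PERCENTILES = (5.0, 95.0)
DEFAULT_SEED = 20230524

GROUPS = (
    "N_positive",  # GN' > GC' > 0
    "C_positive",  # GC' > GN' > 0
    "N_negative",  # GN' < GC' < 0
    "C_negative",  # GC' < GN' < 0
)

__all__ = [
    "SurvivalCurve",
    "GroupingCurves",
    "profiles_to_table",
    "gmax_distribution",
    "survival_function",
    "grouping_fractions",
    "bootstrap_bands",
    "scatter_table",
    "length_distribution",
    "GROUPS",
]


@dataclass
class SurvivalCurve:
    thresholds: np.ndarray
    fraction: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"threshold": self.thresholds, "fraction": self.fraction}
        if self.lo is not None:
            d["lo"], d["hi"] = self.lo, self.hi
        return pd.DataFrame(d)


@dataclass
class GroupingCurves:
    thresholds: np.ndarray
    fractions: pd.DataFrame  # one column per group, NaN where no survivors
    lo: pd.DataFrame | None = None
    hi: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in GROUPS:
            for k, x in enumerate(self.thresholds):
                row = {"group": g, "threshold": x, "fraction": self.fractions[g].iloc[k]}
                if self.lo is not None:
                    row["lo"] = self.lo[g].iloc[k]
                    row["hi"] = self.hi[g].iloc[k]
                rows.append(row)
        return pd.DataFrame(rows)


def profiles_to_table(profiles: Sequence[EntanglementProfile]) -> pd.DataFrame:
    """Tidy per-domain results table; domain ids must be unique."""
    rows = []
    for p in profiles:
        row = {
            "domain_id": p.domain_id,
            "n_residues": p.n_residues,
            "gn": p.gn,
            "gc": p.gc,
            "gmax": p.gmax,
            "max_side": p.max_side,
            "no_loops": p.no_loops,
        }
        if p.labels:
            row.update(p.labels)
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table) and table["domain_id"].duplicated().any():
        raise ValueError("duplicate domain ids in survey table")
    return table


def _centered_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Bin edges aligned so that multiples of bin_width (0, +-1, ...) are centers."""
    lo = np.floor(values.min() / bin_width - 0.5)
    hi = np.ceil(values.max() / bin_width + 0.5)
    return (np.arange(lo, hi + 1) + 0.5) * bin_width


def gmax_distribution(
    table: pd.DataFrame, bin_width: float = DEFAULT_BIN_WIDTH
) -> pd.DataFrame:
    """Density-normalized histogram of signed Gmax' (columns center, density)."""
    if not len(table):
        raise ValueError("empty survey table")
    values = table["gmax"].to_numpy(dtype=float)
    edges = _centered_edges(values, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return pd.DataFrame({"center": centers, "density": density})


def length_distribution(table: pd.DataFrame, bin_width: float = 25.0) -> pd.DataFrame:
    """Histogram of domain lengths N (columns center, density)."""
    if not len(table):
        raise ValueError("empty survey table")
    values = table["n_residues"].to_numpy(dtype=float)
    edges = _centered_edges(values, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return pd.DataFrame({"center": centers, "density": density})


def _survival_values(gmax: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return (np.abs(gmax)[None, :] > grid[:, None]).mean(axis=1)


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be ascending and start at 0")
    return grid


def survival_function(table: pd.DataFrame, grid) -> SurvivalCurve:
    """Fraction of domains with |Gmax'| strictly above each threshold."""
    grid = _check_grid(grid)
    if not len(table):
        raise ValueError("empty survey table")
    gmax = table["gmax"].to_numpy(dtype=float)
    return SurvivalCurve(grid, _survival_values(gmax, grid))


def _group_masks(gn: np.ndarray, gc: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "N_positive": (gn > gc) & (gc > 0),
        "C_positive": (gc > gn) & (gn > 0),
        "N_negative": (gn < gc) & (gc < 0),
        "C_negative": (gc < gn) & (gn < 0),
    }


def _grouping_values(
    gn: np.ndarray, gc: np.ndarray, gmax: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """(len(grid), 4) group fractions among survivors; NaN where none survive."""
    masks = _group_masks(gn, gc)
    out = np.full((len(grid), len(GROUPS)), np.nan)
    surv = np.abs(gmax)[None, :] > grid[:, None]
    n_surv = surv.sum(axis=1)
    ok = n_surv > 0
    for g_idx, g in enumerate(GROUPS):
        counts = (surv & masks[g][None, :]).sum(axis=1)
        out[ok, g_idx] = counts[ok] / n_surv[ok]
    return out


def grouping_fractions(table: pd.DataFrame, grid) -> GroupingCurves:
    """Kind/chirality grouping fractions among survivors at each threshold.

    Only same-sign (diagonal-quadrant) domains belong to a group; domains
    whose GN' and GC' have opposite signs, or with a zero side, count in
    the survivor denominator but in no group.
    """
    grid = _check_grid(grid)
    if not len(table):
        raise ValueError("empty survey table")
    vals = _grouping_values(
        table["gn"].to_numpy(float),
        table["gc"].to_numpy(float),
        table["gmax"].to_numpy(float),
        grid,
    )
    return GroupingCurves(grid, pd.DataFrame(vals, columns=list(GROUPS)))


def bootstrap_bands(
    statistic: Callable[[pd.DataFrame], np.ndarray | float],
    table: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Domain-level bootstrap percentile bands of an arbitrary statistic.

    Resamples rows of the table with replacement ``n_boot`` times and
    returns the (lo, hi) percentile arrays of the statistic (NaN values in
    a replicate, e.g. empty survivor sets, are ignored per grid point).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(table)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps.append(np.atleast_1d(np.asarray(statistic(table.iloc[idx]), dtype=float)))
    stack = np.vstack(reps)
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(stack, percentiles[0], axis=0)
        hi = np.nanpercentile(stack, percentiles[1], axis=0)
    return lo, hi


def survival_with_bands(
    table: pd.DataFrame,
    grid,
    n_boot: int = DEFAULT_N_BOOT,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    seed: int = DEFAULT_SEED,
) -> SurvivalCurve:
    grid = _check_grid(grid)
    curve = survival_function(table, grid)
    lo, hi = bootstrap_bands(
        lambda t: _survival_values(t["gmax"].to_numpy(float), grid),
        table,
        n_boot=n_boot,
        percentiles=percentiles,
        seed=seed,
    )
    curve.lo, curve.hi = lo, hi
    return curve


def grouping_with_bands(
    table: pd.DataFrame,
    grid,
    n_boot: int = DEFAULT_N_BOOT,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
    seed: int = DEFAULT_SEED,
) -> GroupingCurves:
    grid = _check_grid(grid)
    curves = grouping_fractions(table, grid)

    def stat(t: pd.DataFrame) -> np.ndarray:
        return _grouping_values(
            t["gn"].to_numpy(float),
            t["gc"].to_numpy(float),
            t["gmax"].to_numpy(float),
            grid,
        ).ravel()

    lo, hi = bootstrap_bands(stat, table, n_boot=n_boot, percentiles=percentiles, seed=seed)
    shape = (len(grid), len(GROUPS))
    curves.lo = pd.DataFrame(lo.reshape(shape), columns=list(GROUPS))
    curves.hi = pd.DataFrame(hi.reshape(shape), columns=list(GROUPS))
    return curves


def scatter_table(table: pd.DataFrame) -> pd.DataFrame:
    """(GN', GC') pairs with diagonal / anti-diagonal quadrant classification.

    ``quadrant`` is "diagonal" when GN' and GC' share a strict sign,
    "anti-diagonal" when they have strictly opposite signs, and "boundary"
    when either is exactly zero.
    """
    gn = table["gn"].to_numpy(float)
    gc = table["gc"].to_numpy(float)
    quadrant = np.where(
        gn * gc > 0, "diagonal", np.where(gn * gc < 0, "anti-diagonal", "boundary")
    )
    return pd.DataFrame({"domain_id": table["domain_id"], "gn": gn, "gc": gc, "quadrant": quadrant})
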