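"""Cross-group statistics on bootstrapped network attributes.

Global attributes are evaluated on every bootstrap matrix over the sparsity
grid, summarized per bootstrap by the area under the attribute curve, and
compared across groups with a Kruskal-Wallis test followed by pairwise
rank-based post hoc comparisons (Bonferroni x number of pairs).  Nodal
normalized betweenness (NBC) is compared per region and grid point the same
way, with a region declared different only when the corrected test is
significant at >= 99% of the usable grid points; hubs are the regions whose
grand-mean NBC exceeds 1.5.

The bootstrap AUC values are treated as exchangeable samples; the resulting
p-values describe the separation of the bootstrap distributions, not
subject-level inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RegionAtlas
from .connectivity import BinaryGraph, ConnectivityMatrix, binarize
from .graph_metrics import DegenerateMetricError, compute_metric, largest_component, normalized_betweenness

METRICS = ("C", "L", "Eglob", "Eloc", "sigma")


@dataclass
class AttributeCurve:
    """A network attribute sampled over the sparsity grid, per bootstrap."""

    metric: str
    grid: np.ndarray
    values: np.ndarray  # (n_boot, n_grid); NaN marks an undefined point

    def auc(self, interpolate: bool = False) -> np.ndarray:
        return auc(self, interpolate=interpolate)


def attribute_curves(
    matrices: list[ConnectivityMatrix],
    grid: np.ndarray,
    metric: str,
    strict: bool = False,
    sigma_n_null: int = 20,
    sigma_seed: int = 0,
) -> AttributeCurve:
    """Evaluate a metric on the binarized graph of every (bootstrap, sparsity).

    A grid point where the metric is undefined (fragmented graph in strict
    mode) is recorded as NaN rather than dropped.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    grid = np.asarray(grid, dtype=float)
    values = np.empty((len(matrices), grid.size))
    kwargs = {}
    if metric == "sigma":
        kwargs = dict(n_null=sigma_n_null, seed=np.random.default_rng(sigma_seed))
    for b, C in enumerate(matrices):
        for s_idx, s in enumerate(grid):
            g = binarize(C, s)
            try:
                values[b, s_idx] = compute_metric(g, metric, strict=strict, **kwargs)
            except DegenerateMetricError:
                values[b, s_idx] = np.nan
    return AttributeCurve(metric=metric, grid=grid, values=values)


def auc(curve: AttributeCurve, interpolate: bool = False) -> np.ndarray:
    """Per-bootstrap trapezoidal area under the attribute curve."""
    if curve.grid.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    vals = curve.values
    if np.isnan(vals).any():
        if not interpolate:
            raise ValueError(
                "curve contains undefined points; pass interpolate=True to fill them"
            )
        vals = vals.copy()
        for row in vals:
            bad = np.isnan(row)
            if bad.all():
                raise ValueError("a bootstrap curve is undefined everywhere")
            row[bad] = np.interp(curve.grid[bad], curve.grid[~bad], row[~bad])
    return np.trapezoid(vals, curve.grid, axis=1)


@dataclass
class KWComparison:
    statistic: float
    p: float
    post_hoc: pd.DataFrame  # group_a, group_b, statistic, p, p_bonferroni, significant


def compare_auc(
    samples: dict[str, np.ndarray], alpha: float = 0.05
) -> KWComparison:
    """Kruskal-Wallis across groups' AUC samples plus pairwise post hoc.

    Post hoc pairs are tested with two-sided Mann-Whitney U and Bonferroni
    correction over the number of pairs.  Fully tied data short-circuits to
    p = 1 with no post hoc.
    """
    groups = list(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if a.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return KWComparison(statistic=0.0, p=1.0, post_hoc=pd.DataFrame())
    stat, p = stats.kruskal(*arrays)
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    for a, b in pairs:
        u, pp = stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        p_adj = min(1.0, pp * len(pairs))
        rows.append(
            dict(
                group_a=a,
                group_b=b,
                statistic=u,
                p=pp,
                p_bonferroni=p_adj,
                significant=p_adj <= alpha,
                median_a=float(np.median(samples[a])),
                median_b=float(np.median(samples[b])),
            )
        )
    return KWComparison(statistic=float(stat), p=float(p), post_hoc=pd.DataFrame(rows))


@dataclass
class NBCProfile:
    """Per-region NBC summary across bootstraps, groups and sparsity."""

    atlas: RegionAtlas
    grid_used: np.ndarray  # grid points up to the connectivity bound
    upper_bound: float
    mean_nbc: pd.DataFrame  # region x group grand means
    #: (region x grid) Bonferroni-corrected KW p-values
    p_corrected: np.ndarray
    significant_fraction: np.ndarray  # per region
    flagged: np.ndarray  # per region bool, fraction >= 0.99
    #: raw NBC samples, group -> array (n_boot, n_grid_used, N)
    samples: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def connectivity_upper_bound(
    matrices_by_group: dict[str, list[ConnectivityMatrix]], grid: np.ndarray
) -> float:
    """Largest grid sparsity at which every bootstrap graph stays connected.

    Edge sets are nested along the grid, so connectivity is monotone in
    sparsity and a single scan suffices.
    """
    grid = np.asarray(grid, dtype=float)
    bound = None
    for s in grid:  # ascending sparsity
        ok = True
        for mats in matrices_by_group.values():
            for C in mats:
                g = binarize(C, s)
                _, size = largest_component(g)
                if size < C.n:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            bound = s
        else:
            break
    if bound is None:
        raise ValueError(
            "no grid point yields fully connected graphs in every bootstrap; "
            "use a denser (lower-sparsity) grid"
        )
    return float(bound)


def nbc_profile(
    matrices_by_group: dict[str, list[ConnectivityMatrix]],
    grid: np.ndarray,
    atlas: RegionAtlas,
    alpha: float = 0.05,
    significance_fraction: float = 0.99,
) -> NBCProfile:
    """Nodal NBC computed on fully connected graphs, compared across groups.

    The sparsity range is capped at the largest grid value where every
    bootstrap graph of every group is connected, so all NBC values come
    from fully connected networks.  Per region and grid point a KW test
    across the groups' bootstrap NBC samples is Bonferroni-corrected over
    the N regions; a region is flagged different when corrected-significant
    at >= ``significance_fraction`` of the usable grid points.
    """
    grid = np.asarray(grid, dtype=float)
    bound = connectivity_upper_bound(matrices_by_group, grid)
    grid_used = grid[grid <= bound + 1e-12]
    N = atlas.n
    groups = list(matrices_by_group)
    samples: dict[str, np.ndarray] = {}
    for g in groups:
        mats = matrices_by_group[g]
        arr = np.empty((len(mats), grid_used.size, N))
        for b, C in enumerate(mats):
            for s_idx, s in enumerate(grid_used):
                arr[b, s_idx] = normalized_betweenness(binarize(C, s))
        samples[g] = arr

    p_corr = np.ones((N, grid_used.size))
    if len(groups) >= 2:
        for s_idx in range(grid_used.size):
            for j in range(N):
                data = [samples[g][:, s_idx, j] for g in groups]
                pooled = np.concatenate(data)
                if np.ptp(pooled) == 0:
                    p = 1.0
                else:
                    _, p = stats.kruskal(*data)
                p_corr[j, s_idx] = min(1.0, p * N)
    frac = (p_corr <= alpha).mean(axis=1)
    mean_nbc = pd.DataFrame(
        {g: samples[g].mean(axis=(0, 1)) for g in groups}, index=atlas.abbreviations
    )
    return NBCProfile(
        atlas=atlas,
        grid_used=grid_used,
        upper_bound=bound,
        mean_nbc=mean_nbc,
        p_corrected=p_corr,
        significant_fraction=frac,
        flagged=frac >= significance_fraction,
        samples=samples,
    )


def select_hubs(profile: NBCProfile, threshold: float = 1.5) -> pd.DataFrame:
    """Hub table: regions whose grand-mean NBC exceeds the threshold, per group."""
    rows = []
    for g in profile.mean_nbc.columns:
        for abbr, value in profile.mean_nbc[g].items():
            if value > threshold:
                region = profile.atlas.regions[profile.atlas.index_of(abbr)]
                rows.append(
                    dict(
                        group=g,
                        region=abbr,
                        mean_nbc=float(value),
                        lobe=region.lobe,
                        hemisphere=region.hemisphere,
                    )
                )
    return pd.DataFrame(rows, columns=["group", "region", "mean_nbc", "lobe", "hemisphere"])
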