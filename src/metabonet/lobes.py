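"""Spatial analyses of the strongest covariations.

Where the strongest absolute correlations live: counts of top-K edges
falling within each anatomical lobe, intra-/inter-lobe mean absolute
correlation, the bilateral central "Core" set (precentral, supplementary
motor, median cingulate, postcentral, paracentral) analyzed as a unit, and
the covariation among a hypometabolic region set — each per bootstrap and
compared across groups with Kruskal-Wallis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import NAMED_LOBES, RegionAtlas
from .connectivity import ConnectivityMatrix, _ranked_pairs
from .group_stats import KWComparison, compare_auc


def _maybe_kw(samples: dict[str, np.ndarray], alpha: float) -> KWComparison:
    """KW across groups, degrading to a no-test result when infeasible.

    A single group, or groups with a single bootstrap each, carry no
    between-group information; report statistic NaN / p NaN rather than
    refusing the whole analysis.
    """
    if len(samples) < 2 or any(np.asarray(s).size < 2 for s in samples.values()):
        import pandas as pd

        return KWComparison(statistic=float("nan"), p=float("nan"), post_hoc=pd.DataFrame())
    return compare_auc(samples, alpha=alpha)

#: The ten bilateral central-strip structures analyzed as a unit.
CORE_REGIONS = (
    "PreCG.R", "SMA.R", "DCG.R", "PoCG.R", "PCL.R",
    "PreCG.L", "SMA.L", "DCG.L", "PoCG.L", "PCL.L",
)


def top_k_edges(
    C: ConnectivityMatrix, k: int = 1000, signed: bool = False
) -> pd.DataFrame:
    """The k unordered pairs with largest |r| (or signed r), descending.

    Ties broken deterministically by atlas pair order.
    """
    total = C.n * (C.n - 1) // 2
    if not 1 <= k <= total:
        raise ValueError(f"k must be in [1, {total}] for N={C.n}")
    if signed:
        iu, ju = np.triu_indices(C.n, k=1)
        vals = C.r[iu, ju]
        order = np.argsort(-vals, kind="stable")
        ii, jj, vv = iu[order], ju[order], vals[order]
    else:
        ii, jj, vv = _ranked_pairs(C)
        vv = vv.copy()
    return pd.DataFrame(
        {
            "region_a_index": ii[:k],
            "region_b_index": jj[:k],
            "value": (C.r[ii[:k], jj[:k]] if not signed else vv[:k]),
            "rank": np.arange(1, k + 1),
        }
    )


def lobe_edge_counts(
    edges: pd.DataFrame, atlas: RegionAtlas, lobes: tuple[str, ...] = NAMED_LOBES
) -> dict[str, int]:
    """Count edges whose both endpoints share a lobe, per named lobe.

    Regions outside the requested lobes (central strip, subcortical
    nuclei) contribute only to cross-lobe edges and are not counted.
    """
    labels = atlas.lobe_labels
    a = labels[edges["region_a_index"].to_numpy()]
    b = labels[edges["region_b_index"].to_numpy()]
    return {lobe: int(((a == lobe) & (b == lobe)).sum()) for lobe in lobes}


def set_mean_abs_corr(
    C: ConnectivityMatrix | np.ndarray,
    set_a: np.ndarray,
    set_b: np.ndarray | None = None,
) -> float:
    """Mean |r| within a region set, or across two disjoint sets.

    With one set: mean over its C(|A|, 2) unordered pairs.  With two sets:
    mean over the |A| x |B| rectangle; the sets must be disjoint.
    """
    r = C.r if isinstance(C, ConnectivityMatrix) else np.asarray(C)
    a = np.asarray(set_a, dtype=int)
    if set_b is None:
        if a.size < 2:
            raise ValueError("need at least 2 regions for within-set covariation")
        sub = np.abs(r[np.ix_(a, a)])
        iu, ju = np.triu_indices(a.size, k=1)
        return float(sub[iu, ju].mean())
    b = np.asarray(set_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("sets must be disjoint for cross-set covariation")
    return float(np.abs(r[np.ix_(a, b)]).mean())


def bootstrap_set_covariation(
    matrices_by_group: dict[str, list[ConnectivityMatrix]],
    set_a: np.ndarray,
    set_b: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-bootstrap ``set_mean_abs_corr`` distributions for each group."""
    return {
        g: np.array([set_mean_abs_corr(C, set_a, set_b) for C in mats])
        for g, mats in matrices_by_group.items()
    }


def lobe_covariation_report(
    matrices_by_group: dict[str, list[ConnectivityMatrix]],
    atlas: RegionAtlas,
    top_k: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-lobe analyses of the strongest covariations, across groups.

    For every bootstrap matrix: the count of top-k edges falling inside
    each named lobe, and the intra-lobe mean |r|; each quantity is compared
    across groups with KW + post hoc.  Rows: (lobe, quantity) with the KW p
    and per-group means.
    """
    groups = list(matrices_by_group)
    counts = {
        g: pd.DataFrame(
            [lobe_edge_counts(top_k_edges(C, top_k), atlas) for C in mats]
        )
        for g, mats in matrices_by_group.items()
    }
    rows = []
    for lobe in NAMED_LOBES:
        idx = atlas.lobe_indices(lobe)
        cnt_samples = {g: counts[g][lobe].to_numpy(float) for g in groups}
        kw_counts = _maybe_kw(cnt_samples, alpha)
        mean_samples = bootstrap_set_covariation(matrices_by_group, idx)
        kw_mean = _maybe_kw(mean_samples, alpha)
        for quantity, kw, samp in [
            ("top_k_intra_count", kw_counts, cnt_samples),
            ("intra_lobe_mean_abs_r", kw_mean, mean_samples),
        ]:
            row = dict(lobe=lobe, quantity=quantity, kw_statistic=kw.statistic, kw_p=kw.p)
            for g in groups:
                row[f"mean_{g}"] = float(np.mean(samp[g]))
            rows.append(row)
    return pd.DataFrame(rows)


def core_analysis(
    matrices_by_group: dict[str, list[ConnectivityMatrix]],
    atlas: RegionAtlas,
    core: tuple[str, ...] = CORE_REGIONS,
    alpha: float = 0.05,
) -> dict[str, tuple[dict[str, np.ndarray], KWComparison]]:
    """Core-Core, Core-Frontal and Core-Limbic covariation across groups.

    Core members are removed from the frontal and limbic target sets before
    the cross-set contrasts.  Returns, per contrast, the per-bootstrap
    distributions by group and the KW comparison.
    """
    core_idx = atlas.indices_of(core)
    out = {}
    contrasts: dict[str, tuple[np.ndarray, np.ndarray | None]] = {
        "Core-Core": (core_idx, None)
    }
    for lobe in ("Frontal", "Limbic"):
        idx = np.setdiff1d(atlas.lobe_indices(lobe), core_idx)
        contrasts[f"Core-{lobe}"] = (core_idx, idx)
    for name, (a, b) in contrasts.items():
        samples = bootstrap_set_covariation(matrices_by_group, a, b)
        out[name] = (samples, _maybe_kw(samples, alpha))
    return out


def hypometabolic_set_covariation(
    matrices_by_group: dict[str, list[ConnectivityMatrix]],
    region_indices: np.ndarray,
    alpha: float = 0.05,
) -> tuple[dict[str, np.ndarray], KWComparison]:
    """Covariation among a hypometabolic region set, compared across groups."""
    region_indices = np.asarray(region_indices, dtype=int)
    if region_indices.size < 2:
        raise ValueError("hypometabolic set must contain at least 2 regions")
    samples = bootstrap_set_covariation(matrices_by_group, region_indices)
    return samples, _maybe_kw(samples, alpha)
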