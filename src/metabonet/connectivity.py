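"""Pearson connectivity matrices, bootstrapping, binarization, comparison.

An edge weight between two regions is the Pearson correlation of their
residual uptake computed across subjects.  Matrices are bootstrapped by
re-estimating the correlation on random subject subsets, binarized by
keeping the largest absolute correlations at a given sparsity degree, and
compared between groups edge-wise with the Fisher r-to-z Z statistic under
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import RegionAtlas


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Pearson matrix with zero diagonal."""

    r: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        r = self.r
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(r, r.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(r).max() > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")
        if np.any(np.diag(r) != 0):
            raise ValueError("diagonal must be exactly zero (self-connections excluded)")

    @property
    def n(self) -> int:
        return self.r.shape[0]

    def upper_values(self) -> np.ndarray:
        """Correlations of the unordered pairs, atlas pair order (i<j)."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.r[iu, ju]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap of the connectivity matrix over subject subsets.

    Each of ``n_boot`` samples re-estimates the matrix from a random subset
    holding ``fraction`` of the subjects.  Subsets are drawn without
    replacement within a sample and independently from sample to sample;
    ``replace=True`` switches to with-replacement draws.
    """

    n_boot: int = 300
    fraction: float = 0.8
    seed: int = 0
    replace: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass(frozen=True)
class BinaryGraph:
    """Adjacency retained at a sparsity degree.

    ``sparsity`` is the fraction of candidate pairs discarded; the K =
    floor((1 - sparsity) * N(N-1)/2) pairs of largest absolute correlation
    are kept and ``threshold`` records the smallest retained |r|.
    """

    adjacency: np.ndarray
    sparsity: float
    threshold: float
    k: int

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n, k=1)
        m = self.adjacency[iu, ju] > 0
        return list(zip(iu[m].tolist(), ju[m].tolist()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g


def pearson_matrix(residuals: np.ndarray, atlas: RegionAtlas | None = None) -> ConnectivityMatrix:
    """Pearson correlation across subjects for every region pair."""
    x = np.asarray(residuals, dtype=float)
    n, N = x.shape
    if n < 4:
        raise ValueError(f"need at least 4 subjects for a correlation matrix; have {n}")
    sd = x.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = (
            [atlas.regions[j].abbreviation for j in const] if atlas else const.tolist()
        )
        raise ValueError(f"constant residual column(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r=r, n_subjects=n)


def bootstrap_matrices(
    residuals: np.ndarray, config: BootstrapConfig, atlas: RegionAtlas | None = None
) -> list[ConnectivityMatrix]:
    """Bootstrap ensemble of connectivity matrices, reproducible under seed."""
    x = np.asarray(residuals, dtype=float)
    n = x.shape[0]
    m = int(round(config.fraction * n))
    if m < 4:
        raise ValueError(f"bootstrap subset size {m} < 4 (fraction {config.fraction}, n {n})")
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_boot):
        idx = rng.choice(n, size=m, replace=config.replace)
        out.append(pearson_matrix(x[idx], atlas))
    return out


def sparsity_grid(
    start: float = 0.5, stop: float = 0.9, step: float = 0.02
) -> np.ndarray:
    """Inclusive arithmetic grid of sparsity degrees (default 21 values)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0 < start <= stop < 1:
        raise ValueError("need 0 < start <= stop < 1")
    count = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(count)
    if grid[-1] > stop + 1e-12:
        grid = grid[:-1]
    return np.round(grid, 12)


def _ranked_pairs(C: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairs sorted by descending |r|; ties broken by atlas pair order."""
    iu, ju = np.triu_indices(C.n, k=1)
    vals = np.abs(C.r[iu, ju])
    order = np.argsort(-vals, kind="stable")  # stable: ties keep atlas pair order
    return iu[order], ju[order], vals[order]


def binarize(C: ConnectivityMatrix, sparsity: float) -> BinaryGraph:
    """Keep the K largest-|r| pairs at the given sparsity degree.

    K = floor((1 - sparsity) * N(N-1)/2); flooring guarantees the realized
    sparsity is never below nominal.  Nested by construction: the edge set
    at a higher sparsity is a subset of the edge set at a lower one.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must be in (0, 1)")
    n = C.n
    total = n * (n - 1) // 2
    k = int(np.floor((1.0 - sparsity) * total))
    if k == 0:
        raise ValueError(f"sparsity {sparsity} leaves no edges for N={n}")
    ii, jj, vals = _ranked_pairs(C)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[:k], jj[:k]] = 1
    adj[jj[:k], ii[:k]] = 1
    return BinaryGraph(adjacency=adj, sparsity=sparsity, threshold=float(vals[k - 1]), k=k)


def fisher_z(r):
    """Fisher r-to-z: z = arctanh(r) = 0.5 ln((1+r)/(1-r)); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compare_matrices(
    C1: ConnectivityMatrix,
    C2: ConnectivityMatrix,
    atlas: RegionAtlas,
    n1: int | None = None,
    n2: int | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise two-sample comparison of correlation matrices.

    Per unordered pair, Z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) with z the
    Fisher transform; two-sided normal p-values are controlled at FDR level
    ``q`` by Benjamini-Hochberg over all pairs.
    """
    n1 = C1.n_subjects if n1 is None else n1
    n2 = C2.n_subjects if n2 is None else n2
    if n1 <= 3 or n2 <= 3:
        raise ValueError("group sizes must exceed 3 (z variance is 1/(n-3))")
    if C1.n != C2.n:
        raise ValueError("matrices must share the region set")
    iu, ju = np.triu_indices(C1.n, k=1)
    r1 = C1.r[iu, ju]
    r2 = C2.r[iu, ju]
    z1 = fisher_z(r1)
    z2 = fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    Z = (z1 - z2) / se
    p = 2 * stats.norm.sf(np.abs(Z))
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    abbr = atlas.abbreviations
    return pd.DataFrame(
        {
            "region_a": [abbr[i] for i in iu],
            "region_b": [abbr[j] for j in ju],
            "r1": r1,
            "r2": r2,
            "z1": z1,
            "z2": z2,
            "Z": Z,
            "p": p,
            "significant": reject,
        }
    )


def edge_involvement_counts(comparison: pd.DataFrame, atlas: RegionAtlas) -> pd.Series:
    """Per-region count of significant edges from an edge comparison table."""
    sig = comparison[comparison["significant"]]
    counts = pd.Series(0, index=atlas.abbreviations, dtype=int)
    for col in ("region_a", "region_b"):
        vc = sig[col].value_counts()
        counts.loc[vc.index] += vc
    return counts
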