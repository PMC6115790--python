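"""Node- and neighborhood-level genetic summaries.

Neighborhood summaries pool individuals at all nodes within a Euclidean
radius (default 20 km) of the focal node: Ns (neighborhood census size,
the effective-population-size proxy), Ar (mean distinct alleles per
locus, unrarefied), Ho (observed heterozygosity) and He (expected
heterozygosity, 1 - sum p^2 averaged over loci).

Pairwise genetic similarity between nodes is Dps, the proportion of
shared alleles: for two individuals it is the per-locus multiset overlap
of their allele pairs divided by 2, averaged over loci; for two nodes it
is the mean over all cross-node individual pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .grids import Raster
from .landscape import NodeSet
from .simulate import Population

__all__ = [
    "DpsMatrix",
    "allele_counts",
    "neighborhood_summaries",
    "dps_matrix",
    "moving_window_surface",
    "mean_over_runs",
]


@dataclass
class DpsMatrix:
    """Symmetric node-by-node proportion of shared alleles in [0, 1]."""

    node_ids: np.ndarray
    dps: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.dps, index=self.node_ids, columns=self.node_ids).to_csv(path)


def allele_counts(pop: Population, n_nodes: int, n_alleles: int) -> np.ndarray:
    """Per-node allele count tensor of shape (n_nodes, n_loci, n_alleles)."""
    L = pop.n_loci
    counts = np.zeros((n_nodes, L, n_alleles), dtype=np.int64)
    li = np.broadcast_to(np.arange(L), (len(pop), L))
    for copy in range(2):
        np.add.at(counts, (pop.node[:, None], li, pop.genotype[:, :, copy]), 1)
    return counts


def neighborhood_summaries(
    pop: Population,
    nodes: NodeSet,
    n_alleles: int,
    radius: float = 20_000.0,
) -> pd.DataFrame:
    """Moving-neighborhood genetic summaries per node.

    Returns a DataFrame with columns node_id, n_s, a_r, h_o, h_e; nodes
    whose neighborhood holds no individuals get NaN summaries (flagged
    missing).
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    n_nodes = len(nodes)
    counts = allele_counts(pop, n_nodes, n_alleles)
    # per-node observed-heterozygote locus counts and individual counts
    het = (pop.genotype[:, :, 0] != pop.genotype[:, :, 1]).sum(axis=1)  # per individual
    het_sum = np.bincount(pop.node, weights=het, minlength=n_nodes)
    n_ind = np.bincount(pop.node, minlength=n_nodes)

    tree = cKDTree(nodes.coords)
    members = tree.query_ball_point(nodes.coords, r=radius)

    L = pop.n_loci
    out = {
        "node_id": nodes.node_id,
        "n_s": np.zeros(n_nodes),
        "a_r": np.full(n_nodes, np.nan),
        "h_o": np.full(n_nodes, np.nan),
        "h_e": np.full(n_nodes, np.nan),
    }
    for i, mem in enumerate(members):
        mem = np.asarray(mem)
        ns = int(n_ind[mem].sum())
        out["n_s"][i] = ns
        if ns == 0:
            continue
        c = counts[mem].sum(axis=0)  # (L, k)
        tot = c.sum(axis=1, keepdims=True).astype(float)  # 2*ns per locus
        p = c / tot
        out["h_e"][i] = float(np.mean(1.0 - (p**2).sum(axis=1)))
        out["a_r"][i] = float(np.mean((c > 0).sum(axis=1)))
        out["h_o"][i] = float(het_sum[mem].sum() / (ns * L))
    return pd.DataFrame(out)


def _individual_allele_matrix(pop: Population, n_alleles: int) -> np.ndarray:
    """(n, L*k) per-individual allele count matrix with entries in {0,1,2}."""
    n, L = len(pop), pop.n_loci
    C = np.zeros((n, L, n_alleles), dtype=np.int16)
    ii = np.broadcast_to(np.arange(n)[:, None], (n, L))
    li = np.broadcast_to(np.arange(L), (n, L))
    for copy in range(2):
        np.add.at(C, (ii, li, pop.genotype[:, :, copy]), 1)
    return C.reshape(n, L * n_alleles)


def dps_matrix(pop: Population, nodes: NodeSet, n_alleles: int) -> DpsMatrix:
    """Node-pair proportion of shared alleles.

    Individual-pair Dps counts shared alleles with multiplicity: AB vs AB
    -> 1, AA vs AB -> 0.5, AA vs BB -> 0 per locus, averaged over loci.
    The node pair value averages over all cross-node individual pairs;
    diagonal entries are 1 (self-similarity). Nodes without individuals
    are excluded.
    """
    occ = np.flatnonzero(np.bincount(pop.node, minlength=len(nodes)) > 0)
    if len(occ) == 0:
        raise ValueError("no occupied nodes")
    C = _individual_allele_matrix(pop, n_alleles)
    # shared allele count = sum_l sum_a min(ci, cj) = (4L - |ci - cj|_1) / 2,
    # so Dps = shared / (2L) = 1 - cityblock / (4L)
    L = pop.n_loci
    sim = 1.0 - squareform(pdist(C, metric="cityblock")) / (4.0 * L)
    members = [np.flatnonzero(pop.node == j) for j in occ]
    m = len(occ)
    dps = np.ones((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            val = sim[np.ix_(members[a], members[b])].mean()
            dps[a, b] = dps[b, a] = val
    return DpsMatrix(node_ids=nodes.node_id[occ], dps=dps)


def moving_window_surface(
    values: np.ndarray,
    nodes: NodeSet,
    geometry: Raster,
    radius: float = 20_000.0,
    min_n: int = 5,
    out_cell_size: float | None = None,
) -> Raster:
    """Smoothed continuous surface of a per-node index.

    Each output cell takes the mean of node values within ``radius`` of
    the cell center; cells with fewer than ``min_n`` contributing nodes
    (or only NaN values) are nodata (NaN). Output resolution defaults to
    4x the input cell size.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    values = np.asarray(values, dtype=float)
    cs = out_cell_size or 4.0 * geometry.cell_size
    xmin, ymin, xmax, ymax = geometry.extent
    n_cols = max(1, int(np.ceil((xmax - xmin) / cs)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / cs)))
    out = Raster(np.full((n_rows, n_cols), np.nan), cs, (xmin, ymin))
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    cx, cy = out.rowcol_to_xy(rows.ravel(), cols.ravel())
    tree = cKDTree(nodes.coords)
    hits = tree.query_ball_point(np.column_stack([cx, cy]), r=radius)
    flat = out.values.ravel()
    for i, mem in enumerate(hits):
        v = values[np.asarray(mem, dtype=int)] if mem else np.empty(0)
        v = v[~np.isnan(v)]
        if len(v) >= min_n:
            flat[i] = v.mean()
    out.values = flat.reshape(n_rows, n_cols)
    return out


def mean_over_runs(
    per_run: list[pd.DataFrame],
    extinct: list[bool] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-node arithmetic mean of summaries over Monte Carlo runs.

    Extinct runs are excluded; returns (means, number of runs used).
    """
    if extinct is not None:
        per_run = [df for df, e in zip(per_run, extinct) if not e]
    if not per_run:
        raise ValueError("all runs extinct: no summaries to average")
    stacked = pd.concat(per_run)
    return stacked.groupby("node_id", as_index=False).mean(), len(per_run)
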