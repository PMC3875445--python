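"""Heat-map numerics: Z-scaled abundance matrices and UPGMA dendrograms.

Profiles are standardized per row (genes) or per column (samples) and
clustered by unweighted pair-group average linkage on Euclidean
distances. The agglomeration is implemented here so that tie-breaking is
fully deterministic: among equal minimum average distances the pair with
the smallest (representative id, representative id) wins, where a
cluster's representative is its smallest original index; leaves are
ordered recursively smallest-id-first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform


def zscore(matrix: pd.DataFrame, axis: str = "rows", ddof: int = 1) -> pd.DataFrame:
    """Standardize to mean 0, sd 1 along rows or columns.

    Constant vectors map to all-zeros with a warning; a scaled axis of
    length 1 is an error (sample sd undefined).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    x = matrix.to_numpy(dtype=float)
    if axis == "rows":
        if x.shape[1] < 2:
            raise ValueError("cannot Z-scale rows of length 1")
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=ddof, keepdims=True)
    else:
        if x.shape[0] < 2:
            raise ValueError("cannot Z-scale columns of length 1")
        mean = x.mean(axis=0, keepdims=True)
        sd = x.std(axis=0, ddof=ddof, keepdims=True)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant vector(s) mapped to zeros")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z = np.where(np.broadcast_to(constant, z.shape), 0.0, z)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Agglomeration result: merges[i] = (node_a, node_b, height, size).

    Leaves are nodes 0..n-1 in input order; merge i creates node n+i.
    Heights are average inter-cluster Euclidean distances.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (a, b) for i, (a, b, _, _) in enumerate(self.merges)}

    def _min_leaf(self) -> dict[int, int]:
        n = self.n_leaves
        rep = {i: i for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.merges):
            rep[n + i] = min(rep[a], rep[b])
        return rep

    @property
    def leaf_order(self) -> list[int]:
        """Depth-first leaf permutation, smaller-representative child first."""
        children = self._children()
        rep = self._min_leaf()
        order: list[int] = []

        def visit(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
                return
            a, b = children[node]
            first, second = (a, b) if rep[a] <= rep[b] else (b, a)
            visit(first)
            visit(second)

        visit(self.n_leaves + len(self.merges) - 1)
        return order

    def to_newick(self) -> str:
        """Newick string with branch lengths height(parent) - height(child)."""
        children = self._children()
        rep = self._min_leaf()
        height = {i: 0.0 for i in range(self.n_leaves)}
        for i, (_, _, h, _) in enumerate(self.merges):
            height[self.n_leaves + i] = h

        def fmt(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < self.n_leaves:
                return f"{self.labels[node]}:{bl:.10g}"
            a, b = children[node]
            first, second = (a, b) if rep[a] <= rep[b] else (b, a)
            inner = f"({fmt(first, height[node])},{fmt(second, height[node])})"
            return f"{inner}:{bl:.10g}"

        root = self.n_leaves + len(self.merges) - 1
        a, b = children[root]
        first, second = (a, b) if rep[a] <= rep[b] else (b, a)
        return f"({fmt(first, height[root])},{fmt(second, height[root])});"

    def to_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def average_linkage(points: pd.DataFrame | np.ndarray, labels=None) -> Dendrogram:
    """UPGMA agglomeration of the rows of ``points`` on Euclidean distances.

    The Lance-Williams average-linkage update keeps every inter-cluster
    distance equal to the arithmetic mean over all cross-cluster point
    pairs, so heights equal the brute-force recomputation exactly (up to
    float associativity).
    """
    if isinstance(points, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in points.index]
        x = points.to_numpy(dtype=float)
    else:
        x = np.asarray(points, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in clustering input")

    d = squareform(pdist(x, metric="euclidean"))
    active: dict[int, dict] = {
        i: {"size": 1, "rep": i} for i in range(n)
    }
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    while len(active) > 1:
        # deterministic arg-min: smallest distance, ties by representative pair
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(active[kv[0][0]]["rep"], active[kv[0][1]]["rep"]),
                max(active[kv[0][0]]["rep"], active[kv[0][1]]["rep"]),
            ),
        )
        (a, b), h = best
        na, nb = active[a]["size"], active[b]["size"]
        new = {
            "size": na + nb,
            "rep": min(active[a]["rep"], active[b]["rep"]),
        }
        merges.append((a, b, h, na + nb))
        others = [k for k in active if k not in (a, b)]
        del active[a], active[b]
        for k in others:
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            dist[(min(next_node, k), max(next_node, k))] = (na * da + nb * db) / (na + nb)
        del dist[(a, b)]
        active[next_node] = new
        next_node += 1
    return Dendrogram(merges, [str(l) for l in labels])


def cluster_profiles(
    rpkm: pd.DataFrame, gene_axis: str = "rows"
) -> tuple[pd.DataFrame, Dendrogram, Dendrogram]:
    """Fig-2-style computation: gene dendrogram on row-scaled Z-scores,
    sample dendrogram on column-scaled Z-scores (independently).

    Returns (row-scaled matrix, gene dendrogram, sample dendrogram).
    """
    z_rows = zscore(rpkm, axis="rows")
    z_cols = zscore(rpkm, axis="columns")
    genes = average_linkage(z_rows, labels=list(rpkm.index))
    samples = average_linkage(z_cols.T, labels=list(rpkm.columns))
    return z_rows, genes, samples


def heatmap_figure(rpkm: pd.DataFrame, path: str | Path | None = None):
    """Optional rendering layer: clustered heat map of row-scaled values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z, genes, samples = cluster_profiles(rpkm)
    order_r = genes.leaf_order
    order_c = samples.leaf_order
    data = z.to_numpy()[np.ix_(order_r, order_c)]
    fig, ax = plt.subplots(figsize=(4, max(3, 0.12 * len(order_r))))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(order_c)))
    ax.set_xticklabels([z.columns[i] for i in order_c], rotation=90)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row Z-score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
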