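"""Two-way agglomerative clustering on Pearson-correlation distance.

Distance is ``d = 1 - r``; merging is agglomerative with configurable
linkage (average by default).  Merge ties are broken by the lexicographically
smallest member label so the tree is a pure function of the data, not of
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core import CountMatrix, Stage

Linkage = Literal["average", "complete", "single"]
Centering = Literal["none", "mean", "median"]


@dataclass
class ClusterTree:
    """Binary merge tree over named leaves.

    ``merges`` follows the scipy linkage convention: row t merges cluster
    ids ``a`` and ``b`` (leaves are 0..n-1, internal nodes n+t) at ``height``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    notes: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + t: (a, b) for t, (a, b, _) in enumerate(self.merges)}

    def _heights(self) -> dict[int, float]:
        n = self.n_leaves
        h = {i: 0.0 for i in range(n)}
        for t, (_, _, height) in enumerate(self.merges):
            h[n + t] = height
        return h

    def leaves_under(self, node: int) -> list[int]:
        children = self._children()
        out, stack = [], [node]
        while stack:
            k = stack.pop()
            if k < self.n_leaves:
                out.append(k)
            else:
                a, b = children[k]
                stack.extend((b, a))
        return out

    def leaf_order(self) -> list[str]:
        root = self.n_leaves + len(self.merges) - 1
        return [self.labels[i] for i in self.leaves_under(root)]

    def cut(self, k: int = 2) -> dict[str, int]:
        """Cluster label (0..k-1) per leaf, cutting the k-1 top merges."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"cannot cut {self.n_leaves}-leaf tree into {k}")
        n = self.n_leaves
        roots = [n + len(self.merges) - 1]
        children = self._children()
        heights = self._heights()
        while len(roots) < k:
            split = max((r for r in roots if r >= n), key=lambda r: heights[r])
            roots.remove(split)
            roots.extend(children[split])
        assignment = {}
        for c, r in enumerate(sorted(roots, key=lambda r: min(self.leaves_under(r)))):
            for leaf in self.leaves_under(r):
                assignment[self.labels[leaf]] = c
        return assignment

    def to_linkage(self) -> np.ndarray:
        """scipy-compatible (n-1, 4) linkage matrix."""
        sizes = {i: 1 for i in range(self.n_leaves)}
        rows = []
        for t, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[self.n_leaves + t] = size
            rows.append([a, b, h, size])
        return np.array(rows, dtype=float)

    def to_newick(self) -> str:
        children = self._children()
        heights = self._heights()

        def render(node: int, parent_h: float) -> str:
            length = max(parent_h - heights[node], 0.0) / 2.0
            if node < self.n_leaves:
                return f"{self.labels[node]}:{length:.6g}"
            a, b = children[node]
            return f"({render(a, heights[node])},{render(b, heights[node])}):{length:.6g}"

        root = self.n_leaves + len(self.merges) - 1
        return render(root, heights[root]) + ";" if self.merges else \
            f"{self.labels[0]}:0;"


@dataclass
class ClusterReport:
    sample_tree: ClusterTree
    gene_tree: ClusterTree
    sample_order: list[str]
    gene_order: list[str]
    k_cut_assignments: dict[str, int]
    within_cluster_correlation: dict[int, float]
    label_crosstab: pd.DataFrame


def correlation_distance(data: np.ndarray, labels: list[str],
                         notes: list[str] | None = None) -> np.ndarray:
    """1 - Pearson r between rows; constant rows get distance 1 to all."""
    data = np.asarray(data, dtype=float)
    sd = data.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    d = 1.0 - r
    for i in np.flatnonzero(constant):
        d[i, :] = 1.0
        d[:, i] = 1.0
        if notes is not None:
            notes.append(f"constant profile {labels[i]!r}: correlation "
                         "undefined, distance set to 1")
    np.fill_diagonal(d, 0.0)
    return d


def agglomerate(dist: np.ndarray, labels: list[str],
                linkage: Linkage = "average") -> ClusterTree:
    """Deterministic bottom-up merging of a full distance matrix."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    d = dist.astype(float).copy()
    tree = ClusterTree(labels=list(labels), merges=[])
    rows = {i: i for i in range(n)}  # cluster id -> row in d
    sizes = {i: 1 for i in range(n)}
    keys = {i: labels[i] for i in range(n)}
    ids = sorted(rows)
    next_id = n
    while len(ids) > 1:
        # vectorized min over active pairs; exact ties resolved by the
        # lexicographically smallest (key_a, key_b) member labels
        rlist = [rows[i] for i in ids]
        sub = d[np.ix_(rlist, rlist)]
        iu = np.triu_indices(len(ids), k=1)
        dmin = sub[iu].min()
        hits = np.argwhere(np.triu(sub == dmin, k=1))
        best = None
        for ii, jj in hits:
            a, b = ids[ii], ids[jj]
            ka, kb = sorted((keys[a], keys[b]))
            if best is None or (ka, kb) < best[:2]:
                best = (ka, kb, a, b)
        a, b = best[2], best[3]
        dd = dmin
        tree.merges.append((a, b, float(dd)))
        ra, rb = rows[a], rows[b]
        na, nb = sizes[a], sizes[b]
        if linkage == "average":
            new_row = (na * d[ra, :] + nb * d[rb, :]) / (na + nb)
        elif linkage == "complete":
            new_row = np.maximum(d[ra, :], d[rb, :])
        elif linkage == "single":
            new_row = np.minimum(d[ra, :], d[rb, :])
        else:
            raise ValueError(f"unknown linkage {linkage!r}")
        d[ra, :] = new_row
        d[:, ra] = new_row
        d[ra, ra] = 0.0
        rows[next_id] = ra
        sizes[next_id] = na + nb
        keys[next_id] = min(keys[a], keys[b])
        for k in (a, b):
            del rows[k], sizes[k], keys[k]
        ids = sorted(rows)
        next_id += 1
    return tree


def _expression(m: CountMatrix, centering: Centering,
                log2: bool = True) -> pd.DataFrame:
    expr = m.endogenous_frame()
    if log2:
        expr = np.log2(expr + 1.0)
    if centering == "mean":
        expr = expr.sub(expr.mean(axis=1), axis=0)
    elif centering == "median":
        expr = expr.sub(expr.median(axis=1), axis=0)
    elif centering != "none":
        raise ValueError(f"unknown centering {centering!r}")
    return expr


def hca(m: CountMatrix, axis: Literal["genes", "samples"], *,
        linkage: Linkage = "average",
        centering: Centering = "mean", log2: bool = True) -> ClusterTree:
    """Cluster genes or samples of a normalized matrix on 1 - Pearson r.

    Expression enters on the log2(count+1) scale by default (same scale the
    classifier uses); set ``log2=False`` for raw normalized counts.
    """
    if m.stage != Stage.BIO_NORMALIZED:
        raise ValueError(f"clustering expects normalized counts, got {m.stage.value}")
    expr = _expression(m, centering, log2)
    if axis == "genes":
        data, labels = expr.to_numpy(), list(expr.index)
    elif axis == "samples":
        data, labels = expr.to_numpy().T, list(expr.columns)
    else:
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    notes: list[str] = []
    d = correlation_distance(data, labels, notes)
    tree = agglomerate(d, labels, linkage=linkage)
    tree.notes = notes
    return tree


def mean_pairwise_correlation(data: np.ndarray) -> float:
    """Mean off-diagonal Pearson r between rows (1.0 for a single row)."""
    if data.shape[0] < 2:
        return 1.0
    sd = data.std(axis=1)
    if np.any(sd == 0):
        data = data[sd > 0]
        if data.shape[0] < 2:
            return 0.0
    r = np.corrcoef(data)
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def cut_two(m: CountMatrix, *, linkage: Linkage = "average",
            centering: Centering = "mean", log2: bool = True) -> ClusterReport:
    """Full two-way report with a 2-cluster cut of the sample tree."""
    if len(m.samples) < 2:
        raise ValueError("need at least 2 samples")
    sample_tree = hca(m, "samples", linkage=linkage, centering=centering,
                      log2=log2)
    gene_tree = hca(m, "genes", linkage=linkage, centering=centering,
                    log2=log2)
    assignment = sample_tree.cut(2)

    expr = _expression(m, centering, log2)
    within = {}
    for c in sorted(set(assignment.values())):
        members = [s for s, cc in assignment.items() if cc == c]
        within[c] = mean_pairwise_correlation(expr[members].to_numpy().T)

    labels = {s.sample_id: s.label for s in m.samples}
    crosstab = pd.crosstab(
        pd.Series({sid: f"cluster{c}" for sid, c in assignment.items()}),
        pd.Series(labels),
    )
    return ClusterReport(
        sample_tree=sample_tree,
        gene_tree=gene_tree,
        sample_order=sample_tree.leaf_order(),
        gene_order=gene_tree.leaf_order(),
        k_cut_assignments=assignment,
        within_cluster_correlation=within,
        label_crosstab=crosstab,
    )
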