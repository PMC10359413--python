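"""Correlated FA group identification.

The measured FA variables fall into a small number of groups whose mol-%
profiles move together across samples.  This module computes the
variable-variable Pearson correlation matrix, clusters variables (or
samples) hierarchically with correlation distance d = 1 - r and the Ward
criterion applied to the *unsquared* distances (the ``ward.D`` variant,
as used by ClustVis/hclust, which scipy does not provide), and turns the
dendrogram into a group assignment — either by cutting at K groups or by
a manually curated mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "CorrMatrix",
    "Dendrogram",
    "correlation_matrix",
    "ward_linkage",
    "cluster",
    "assign_groups",
]


class GroupingError(ValueError):
    pass


@dataclass
class CorrMatrix:
    """Pairwise Pearson r and two-sided p (t on n-2 df) between variables."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int


def correlation_matrix(z) -> CorrMatrix:
    """All-pairs Pearson correlation across samples.

    ``z`` is any object with a samples x variables ``values`` DataFrame
    (ZMatrix or ProfileMatrix; Pearson r is location/scale invariant so
    either gives identical r).
    """
    x = z.values.to_numpy(float)
    n, p = x.shape
    if n < 3:
        raise GroupingError("correlation requires at least 3 samples")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    # two-sided p from t = r * sqrt((n-2)/(1-r^2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval[np.isinf(t) | np.isnan(t)] = 0.0  # |r| == 1
    np.fill_diagonal(pval, 0.0)
    cols = z.values.columns
    return CorrMatrix(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(pval, index=cols, columns=cols),
        n=n,
    )


@dataclass
class Dendrogram:
    """Agglomeration tree in scipy linkage format plus item labels."""

    linkage: np.ndarray  # (n-1, 4): left, right, height, size
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.dendrogram(self.linkage, no_plot=True)["leaves"]
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Partition into k clusters; cluster ids renumbered 1..k in
        order of first appearance along the label list."""
        if not 1 <= k <= len(self.labels):
            raise GroupingError(f"k={k} outside [1, {len(self.labels)}]")
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        remap: dict[int, int] = {}
        ids = []
        for c in flat:
            if c not in remap:
                remap[c] = len(remap) + 1
            ids.append(remap[c])
        return pd.Series(ids, index=self.labels, name="group")


def ward_linkage(dist: np.ndarray, labels: list[str]) -> np.ndarray:
    """Ward agglomeration on an arbitrary (unsquared) distance matrix.

    Implements the Lance-Williams recurrence for the classical Ward
    criterion applied directly to the supplied distances (R's
    ``hclust(method="ward.D")``):

        d(k, i+j) = ((n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)) / N

    with N = n_i + n_j + n_k.  Ties are broken by merging the pair whose
    (lexicographically smallest member label, then second-smallest) sorts
    first, so the tree is deterministic across platforms.
    """
    d = np.asarray(dist, dtype=float).copy()
    m = d.shape[0]
    if d.shape != (m, m) or m != len(labels):
        raise GroupingError("distance matrix / labels mismatch")
    if m < 2:
        raise GroupingError("need at least 2 items to cluster")
    # active cluster bookkeeping
    sizes = {i: 1 for i in range(m)}
    reps = {i: labels[i] for i in range(m)}  # smallest member label per cluster
    node_id = {i: i for i in range(m)}  # scipy node ids
    active = list(range(m))
    Z = np.zeros((m - 1, 4))
    next_id = m
    for step in range(m - 1):
        # find minimum-distance active pair, ties by representative labels
        best = None
        best_key = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                rep = tuple(sorted((reps[i], reps[j])))
                key = (d[i, j], rep)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        h = d[i, j]
        ni, nj = sizes[i], sizes[j]
        Z[step] = [node_id[i], node_id[j], h, ni + nj]
        # Lance-Williams update onto slot i
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            nn = ni + nj + nk
            dk = ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * h) / nn
            d[i, k] = d[k, i] = dk
        sizes[i] = ni + nj
        reps[i] = min(reps[i], reps[j])
        node_id[i] = next_id
        next_id += 1
        active.remove(j)
    return Z


def cluster(z, axis: str = "variables") -> Dendrogram:
    """Hierarchically cluster variables (or samples) of a Z-score matrix.

    Distance is 1 - Pearson r between items; linkage is Ward on the
    unsquared distances (:func:`ward_linkage`).
    """
    if axis not in ("variables", "samples"):
        raise GroupingError("axis must be 'variables' or 'samples'")
    x = z.values.to_numpy(float)
    labels = list(z.values.columns if axis == "variables" else z.values.index)
    if axis == "samples":
        x = x.T
    if x.shape[1] < 2:
        raise GroupingError("need at least 2 items to cluster")
    sd = x.std(axis=0)
    dead = [labels[i] for i in np.nonzero(sd == 0)[0]]
    if dead:
        raise GroupingError(
            f"zero-variance items have undefined correlation distance: {dead}"
        )
    r = np.clip(np.corrcoef(x, rowvar=False), -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return Dendrogram(ward_linkage(d, labels), labels)


def assign_groups(
    dendrogram: Dendrogram | None,
    k: int = 5,
    manual: pd.Series | dict | None = None,
    variables: list[str] | None = None,
) -> pd.Series:
    """Variable -> group id mapping (GroupAssignment).

    A manual mapping (e.g. a curated table) overrides the dendrogram
    cut; it must cover exactly the clustered variables.
    """
    if manual is not None:
        mapping = pd.Series(manual, name="group")
        expected = variables if variables is not None else (
            dendrogram.labels if dendrogram is not None else None
        )
        if expected is not None:
            missing = set(expected) - set(mapping.index)
            unknown = set(mapping.index) - set(expected)
            if missing or unknown:
                raise GroupingError(
                    f"manual mapping mismatch; missing={sorted(missing)}, "
                    f"unknown={sorted(unknown)}"
                )
            mapping = mapping.loc[list(expected)]
        return mapping.astype(int)
    if dendrogram is None:
        raise GroupingError("need a dendrogram or a manual mapping")
    return dendrogram.cut(k)
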