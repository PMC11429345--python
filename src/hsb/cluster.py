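"""Phi correlation of binary marker flags and complete-linkage clustering.

The phi coefficient is the Pearson correlation specialised to two binary
variables, computed from the 2×2 contingency table:

    phi = (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0)

Markers are clustered on the distance d = 1 - phi with complete linkage
(inter-cluster distance = maximum cross-pair distance).  Negative phi
gives d > 1, which complete linkage handles without modification, so the
weak negative between-group correlations seen in real marker data are
preserved rather than truncated.

Determinism contracts
---------------------
* Tie rule: when several cluster pairs attain the minimal distance, the
  pair with the lexicographically smallest (id_a, id_b) merges first
  (leaves are 0..n-1 in input order; merged clusters get ids n, n+1, ...).
* Leaf order: at each merge the subtree containing the smaller minimum
  original index goes left.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .ascertain import MarkerFlags

__all__ = [
    "phi",
    "PhiMatrix",
    "phi_matrix",
    "Dendrogram",
    "complete_linkage",
    "cut_clusters",
    "grouping_agreement",
]

logger = logging.getLogger(__name__)


def phi(x, y) -> tuple[float | None, dict[str, int]]:
    """Phi coefficient of two equal-length 0/1 vectors, with 2×2 counts.

    Returns ``(phi, counts)`` where counts has keys n11, n10, n01, n00.
    If either vector is constant the coefficient is undefined and None is
    returned (never an exception).
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("phi needs two equal-length 1-d vectors of length >= 2")
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    counts = {"n11": n11, "n10": n10, "n01": n01, "n00": n00}
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return None, counts
    return (n11 * n00 - n10 * n01) / math.sqrt(denom), counts


@dataclass
class PhiMatrix:
    """Symmetric marker × marker phi matrix with per-pair 2×2 counts.

    ``dropped`` lists zero-variance markers excluded from the matrix
    (phi is undefined for them).
    """

    matrix: pd.DataFrame
    counts: dict[tuple[str, str], dict[str, int]]
    dropped: list[str] = field(default_factory=list)
    n: int = 0

    @property
    def markers(self) -> list[str]:
        return list(self.matrix.columns)

    def distance(self) -> pd.DataFrame:
        """d = 1 - phi (0 on the diagonal, up to 2 for phi = -1)."""
        d = 1.0 - self.matrix
        np.fill_diagonal(d.values, 0.0)
        return d


def phi_matrix(flags: MarkerFlags | pd.DataFrame, subset=None) -> PhiMatrix:
    """All pairwise phi coefficients on one patient subset.

    ``subset`` is an optional boolean mask or patient-id indexer applied
    to the flag matrix rows (e.g. one sex).  Zero-variance markers on the
    subset are excluded with a warning.
    """
    df = flags.flags if isinstance(flags, MarkerFlags) else flags
    if subset is not None:
        df = df.loc[subset]
    n = len(df)
    if n < 2:
        raise ValueError("phi matrix needs at least 2 patients")
    variances = df.std(ddof=0)
    dropped = [m for m in df.columns if variances[m] == 0]
    if dropped:
        logger.warning("excluding zero-variance markers from phi matrix: %s", dropped)
    kept = [m for m in df.columns if m not in dropped]
    if len(kept) < 2:
        raise ValueError("fewer than 2 markers with variance; phi matrix undefined")
    x = df[kept].to_numpy(dtype=np.int64)
    ones = x.T @ x  # pairwise n11
    col = x.sum(axis=0)
    n11 = ones
    n10 = col[:, None] - ones
    n01 = col[None, :] - ones
    n00 = n - n11 - n10 - n01
    num = n11 * n00 - n10 * n01
    denom = np.sqrt(
        (n11 + n10).astype(float) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = num / denom
    np.fill_diagonal(mat, 1.0)
    matrix = pd.DataFrame(mat, index=kept, columns=kept)
    counts = {}
    for i, a in enumerate(kept):
        for j, b in enumerate(kept):
            if i < j:
                counts[(a, b)] = {
                    "n11": int(n11[i, j]), "n10": int(n10[i, j]),
                    "n01": int(n01[i, j]), "n00": int(n00[i, j]),
                }
    return PhiMatrix(matrix, counts, dropped, n)


@dataclass
class Dendrogram:
    """Merge tree from agglomerative clustering.

    ``merges`` lists (id_a, id_b, height, new_id) in merge order; leaves
    are 0..n-1 in the order of ``labels``; merged clusters get ids n,
    n+1, ....  ``leaf_order`` is the deterministic display order.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[str]

    @property
    def n(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height", "new_id"])


def complete_linkage(dist: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix.

    D(A, B) = max over cross-pairs of d; ties resolved by the
    lexicographic cluster-id rule documented in the module docstring.
    Complete linkage is monotone, so merge heights are non-decreasing.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    labels = list(dist.columns) if isinstance(dist, pd.DataFrame) else [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    # active clusters: id -> (member leaf indices, min original index)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    # current inter-cluster distances, keyed by (id_a, id_b), id_a < id_b
    cd: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    trees: dict[int, tuple] = {i: (i,) for i in range(n)}  # leaf-order trees
    next_id = n
    for _ in range(n - 1):
        best = min(cd.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        new = next_id
        next_id += 1
        members[new] = members.pop(a) + members.pop(b)
        active = [c for c in active if c not in (a, b)]
        for c in active:
            da = cd.pop((min(a, c), max(a, c)))
            db = cd.pop((min(b, c), max(b, c)))
            cd[(min(new, c), max(new, c))] = max(da, db)
        cd.pop((a, b))
        # smaller minimum original index goes left
        ta, tb = trees.pop(a), trees.pop(b)
        if min(_tree_leaves(tb)) < min(_tree_leaves(ta)):
            ta, tb = tb, ta
        trees[new] = (ta, tb)
        active.append(new)
        merges.append((a, b, float(h), new))
    root = trees[next_id - 1] if n > 1 else trees[0]
    leaf_order = [labels[i] for i in _tree_leaves(root)]
    return Dendrogram(labels, merges, leaf_order)


def _tree_leaves(t) -> list[int]:
    if isinstance(t, tuple) and len(t) == 1:
        return [t[0]]
    out = []
    for child in t:
        if isinstance(child, tuple):
            out.extend(_tree_leaves(child))
        else:
            out.append(child)
    return out


def cut_clusters(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition from undoing the last k-1 merges (k clusters).

    Returns marker -> cluster label; labels are 0..k-1 in order of each
    cluster's smallest original leaf index.
    """
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b, _, new in dend.merges[: n - k]:
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    clusters = sorted(roots.values(), key=min)
    out: dict[str, int] = {}
    for label, leaves in enumerate(clusters):
        for leaf in leaves:
            out[dend.labels[leaf]] = label
    return out


def grouping_agreement(partition: dict[str, int], grouping: dict[str, str]) -> float:
    """Adjusted Rand index between a data-driven partition and a
    theoretical grouping of the same markers.

    1.0 iff the partitions coincide up to relabelling; ~0 for chance-level
    agreement.
    """
    if set(partition) != set(grouping):
        raise ValueError("partition and grouping must cover the same markers")
    keys = sorted(partition)
    a = [partition[k] for k in keys]
    b = [grouping[k] for k in keys]
    return float(adjusted_rand_score(a, b))
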