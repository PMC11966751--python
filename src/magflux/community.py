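"""Beta-diversity statistics implemented from their definitions.

Bray–Curtis dissimilarity between compositional samples, principal
coordinates analysis by Gower double-centering, the rank-based ANOSIM
permutation test, and average-linkage (UPGMA) hierarchical clustering
with Newick export.  These are written out from the textbook
definitions so each step is inspectable; the test suite cross-checks
them against independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .iodata import ProfileMatrix

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "AnosimResult",
    "MergeTree",
    "bray_curtis",
    "pcoa",
    "anosim",
    "hclust_average",
]

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=_SYM_TOL):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < -_SYM_TOL):
            raise ValueError("negative dissimilarity")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        labels = [str(i) for i in self.ids]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample", lineterminator="\n")


def bray_curtis(profiles: ProfileMatrix | pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between sample columns.

    d(u, v) = 1 − 2·Σᵢ min(uᵢ, vᵢ) / (Σᵢ uᵢ + Σᵢ vᵢ): 0 for identical
    samples, 1 for samples sharing no taxa.
    """
    df = profiles.data if isinstance(profiles, ProfileMatrix) else profiles
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    x = df.to_numpy(dtype=float)
    sums = x.sum(axis=0)
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = sums[i] + sums[j]
            if denom == 0:
                raise ValueError(
                    f"Bray-Curtis undefined for all-zero samples "
                    f"{df.columns[i]} / {df.columns[j]}"
                )
            shared = np.minimum(x[:, i], x[:, j]).sum()
            d[i, j] = d[j, i] = 1.0 - 2.0 * shared / denom
    return DistanceMatrix(list(df.columns), d)


@dataclass
class PcoaResult:
    """Metric embedding of a dissimilarity matrix.

    ``coordinates`` holds one column per retained (positive-eigenvalue)
    axis, ordered by decreasing eigenvalue and scaled by √λ, so
    Euclidean distances between rows reproduce the input distances when
    the matrix is Euclidean-embeddable.  ``eigenvalues`` keeps the full
    spectrum, negative eigenvalues included (no correction is applied);
    ``proportion_explained`` is over the positive eigenvalues only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering."""
    n = len(d)
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    labels = [str(i) for i in d.ids]
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PC{i+1}" for i in range(pos.sum())]
    )
    pos_sum = eigvals[pos].sum()
    explained = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return PcoaResult(frame, eigvals, explained)


@dataclass
class AnosimResult:
    """ANOSIM R statistic with its permutation p-value."""

    r: float
    p_value: float
    n_permutations: int
    seed: int


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray, n: int) -> float:
    r_between = ranks[~same_group].mean()
    r_within = ranks[same_group].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(
    d: DistanceMatrix,
    groups: list,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on ranked dissimilarities.

    R = (mean between-group rank − mean within-group rank) / (n(n−1)/4),
    in [−1, 1]; R near 1 means between-group dissimilarities dominate.
    The p-value counts label permutations with R at least as large as
    observed, with the add-one convention so p is never 0.
    """
    n = len(d)
    if len(groups) != n:
        raise ValueError("one group label per sample required")
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two samples")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.values[iu])
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p, n) >= r_obs - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(float(r_obs), float(p), n_permutations, seed)


@dataclass
class _Node:
    label: str
    height: float
    members: tuple
    children: tuple = ()

    def newick(self, parent_height: float | None = None) -> str:
        if self.children:
            inner = ",".join(c.newick(self.height) for c in self.children)
            s = f"({inner})"
        else:
            s = self.label
        if parent_height is None:
            return s
        # ultrametric layout: tips sit at height 0, a node at h/2 from the root axis
        return f"{s}:{(parent_height - self.height) / 2:.10g}"


@dataclass
class MergeTree:
    """UPGMA merge sequence.

    ``merges`` lists (height, left label, right label, new label) in
    merge order, where height is the average-linkage distance at which
    the two clusters fuse (the cophenetic distance of their members).
    """

    root: _Node
    merges: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def to_newick(self) -> str:
        return self.root.newick() + ";"

    def cophenetic(self) -> DistanceMatrix:
        n = len(self.labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        out = np.zeros((n, n))

        def walk(node: _Node) -> None:
            for child in node.children:
                walk(child)
            if len(node.children) == 2:
                left, right = node.children
                for a in left.members:
                    for b in right.members:
                        i, j = index[a], index[b]
                        out[i, j] = out[j, i] = node.height

        walk(self.root)
        return DistanceMatrix(self.labels, out)


def hclust_average(d: DistanceMatrix) -> MergeTree:
    """Average-linkage (UPGMA) clustering of a dissimilarity matrix.

    At each step the pair of clusters at minimum average dissimilarity
    is merged; ties break toward the lexicographically smallest pair of
    cluster labels (a cluster is labeled by its smallest member).
    """
    labels = [str(i) for i in d.ids]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    nodes = {
        lab: _Node(label=lab, height=0.0, members=(lab,)) for lab in labels
    }
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            key = (min(a, b), max(a, b))
            dist[key] = float(d.values[i, j])
    active = set(labels)
    merges = []
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        new_label = min(a, b)
        na, nb = len(nodes[a].members), len(nodes[b].members)
        merged = _Node(
            label=new_label,
            height=h,
            members=tuple(sorted(nodes[a].members + nodes[b].members)),
            children=(nodes[a], nodes[b]),
        )
        merges.append((h, a, b, new_label))
        for other in list(active):
            if other in (a, b):
                continue
            ka = (min(a, other), max(a, other))
            kb = (min(b, other), max(b, other))
            new_d = (na * dist[ka] + nb * dist[kb]) / (na + nb)
            del dist[ka], dist[kb]
            dist[(min(new_label, other), max(new_label, other))] = new_d
        del dist[(min(a, b), max(a, b))]
        active.discard(a)
        active.discard(b)
        active.add(new_label)
        nodes.pop(a, None)
        nodes.pop(b, None)
        nodes[new_label] = merged
    root = nodes[next(iter(active))]
    return MergeTree(root=root, merges=merges, labels=labels)
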