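"""Isotopic source grouping: Ward clustering, cuts, and merge/omit rules.

Primary producers and consumers are sorted into isotopically distinct groups
by Ward's minimum-variance hierarchical clustering on a Euclidean distance
matrix of their ‰ signatures.  Groups whose signatures are statistically
indistinguishable on the isotopes in use (means closer than one pooled SD on
every axis) are merged, mirroring how sources such as macroalgae and
eelgrass must be combined before a mixing model can separate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .isotopes import GroupSummary, SampleRecord

__all__ = [
    "Dendrogram",
    "GroupingResult",
    "isotope_distance_matrix",
    "ward_cluster",
    "cut_to_groups",
    "merge_indistinguishable",
    "pool_summaries",
    "group_samples",
]


@dataclass(frozen=True)
class Dendrogram:
    """Ward merge tree over named leaves.

    ``linkage`` is a scipy-format (n−1, 4) matrix; heights are Ward linkage
    distances in ‰ units.
    """

    linkage: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 2) and self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows for n leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        """The merge sequence as (cluster A, cluster B, height) triples."""
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    @property
    def heights(self) -> np.ndarray:
        return np.asarray(self.linkage[:, 2], dtype=float)

    def to_newick(self) -> str:
        """Serialize as Newick with branch lengths spanning merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


@dataclass
class GroupingResult:
    """Labels, per-group summaries, and a provenance log of merges/omissions."""

    labels: dict[str, str]
    summaries: list[GroupSummary]
    provenance: list[str] = field(default_factory=list)
    omitted: list[str] = field(default_factory=list)


def _sample_matrix(samples: Sequence[SampleRecord],
                   isotopes: Sequence[str]) -> np.ndarray:
    X = np.empty((len(samples), len(isotopes)))
    for i, s in enumerate(samples):
        for j, iso in enumerate(isotopes):
            v = s.measurement.isotope(iso)
            if v is None:
                raise ValueError(
                    f"sample {s.sample_id!r} has no {iso} value")
            X[i, j] = v
    return X


def isotope_distance_matrix(samples: Sequence[SampleRecord],
                            isotopes: Sequence[str],
                            standardize: bool = False) -> np.ndarray:
    """Pairwise Euclidean distances (‰) on the requested isotope axes.

    Axes are left on their raw ‰ scales by default; ``standardize`` z-scores
    each axis first (off by default because the distance matrix the analysis
    is defined on is unscaled).
    """
    X = _sample_matrix(samples, isotopes)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


def ward_cluster(dist: np.ndarray,
                 leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """Ward minimum-variance linkage from a distance matrix.

    Uses the Lance–Williams recurrence; deterministic for a given input
    (ties resolved by scipy's nearest-neighbour chain order).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("clustering requires at least 2 samples")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if leaf_ids is None:
        leaf_ids = tuple(str(i) for i in range(n))
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return Dendrogram(linkage=Z, leaf_ids=tuple(leaf_ids))


def cut_to_groups(dend: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into the k clusters left by removing the k−1 highest merges."""
    n = len(dend.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    return {leaf: int(lbl) for leaf, lbl in zip(dend.leaf_ids, labels)}


def pool_summaries(members: Sequence[GroupSummary], group_id: str,
                   label: str, isotopes: Sequence[str]) -> GroupSummary:
    """Pool member groups into one summary (exact moment pooling).

    The pooled mean is the N-weighted mean; the pooled variance combines
    within-member variance and between-member spread, so it equals the
    variance of the concatenated member samples.
    """
    n_tot = sum(m.n for m in members)
    means: dict[str, float] = {}
    sds: dict[str, float | None] = {}
    for iso in isotopes:
        mu = sum(m.n * m.means[iso] for m in members) / n_tot
        if n_tot > 1:
            ss = sum((m.n - 1) * m.sd(iso) ** 2 + m.n * (m.means[iso] - mu) ** 2
                     for m in members)
            sds[iso] = float(np.sqrt(ss / (n_tot - 1)))
        else:
            sds[iso] = None
        means[iso] = float(mu)
    return GroupSummary(group_id=group_id, label=label, n=n_tot,
                        means=means, sds=sds)


def _pooled_sd(a: GroupSummary, b: GroupSummary, iso: str) -> float:
    na, nb = a.n, b.n
    if na + nb <= 2:
        return float(np.sqrt((a.sd(iso) ** 2 + b.sd(iso) ** 2) / 2.0))
    return float(np.sqrt(((na - 1) * a.sd(iso) ** 2 + (nb - 1) * b.sd(iso) ** 2)
                         / (na + nb - 2)))


def merge_indistinguishable(
        groups: Sequence[GroupSummary],
        isotopes: Sequence[str]) -> tuple[list[GroupSummary], list[str]]:
    """Merge groups that cannot be told apart on the requested isotopes.

    Two groups merge when their means differ by less than one pooled SD on
    *every* requested isotope; merging repeats to a fixed point.  When more
    than one pair qualifies, the pair with the smallest maximum standardized
    mean difference merges first (closest-pair-first tie-break).  Returns
    the merged summaries and a log describing each merge.
    """
    for g in groups:
        for iso in isotopes:
            if iso not in g.means:
                raise ValueError(f"group {g.group_id!r} lacks isotope {iso!r}")
    current = list(groups)
    log: list[str] = []
    while True:
        best: tuple[float, int, int] | None = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                a, b = current[i], current[j]
                zs = []
                for iso in isotopes:
                    sd = _pooled_sd(a, b, iso)
                    diff = abs(a.means[iso] - b.means[iso])
                    if sd == 0:
                        zs.append(0.0 if diff == 0 else np.inf)
                    else:
                        zs.append(diff / sd)
                zmax = max(zs)
                if zmax < 1.0 and (best is None or zmax < best[0]):
                    best = (zmax, i, j)
        if best is None:
            return current, log
        _, i, j = best
        a, b = current[i], current[j]
        merged = pool_summaries(
            [a, b], group_id=f"{a.group_id}+{b.group_id}",
            label=f"{a.label} + {b.label}", isotopes=list(a.means))
        log.append(
            f"merged {a.group_id!r} and {b.group_id!r} "
            f"(max standardized mean difference {best[0]:.3f} < 1 on "
            f"{'/'.join(isotopes)})")
        current = [g for idx, g in enumerate(current) if idx not in (i, j)]
        current.append(merged)


def group_samples(samples: Sequence[SampleRecord],
                  labels: Mapping[str, str],
                  isotopes: Sequence[str]) -> list[GroupSummary]:
    """Summarize samples into GroupSummary rows given a sample_id -> group map."""
    frame = pd.DataFrame({
        "group": [labels[s.sample_id] for s in samples],
        **{iso: [s.measurement.isotope(iso) for s in samples]
           for iso in isotopes},
    })
    out = []
    for gid, sub in frame.groupby("group", sort=True):
        n = len(sub)
        means = {iso: float(sub[iso].mean()) for iso in isotopes}
        sds = {iso: (float(sub[iso].std(ddof=1)) if n > 1 else None)
               for iso in isotopes}
        out.append(GroupSummary(group_id=str(gid), label=str(gid), n=n,
                                means=means, sds=sds))
    return out
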