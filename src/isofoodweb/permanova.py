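"""Permutational MANOVA on a Euclidean isotope distance matrix.

The pseudo-F statistic uses the distance-based partition of Anderson (2001):
total sum of squares from all pairwise squared distances, within-group sums
from within-group pairs, and F = (SS_between/(g−1)) / (SS_within/(n−g)).
Significance comes from free permutation of whole-sample labels; the p-value
counts the observed statistic in both numerator and denominator, so it is
never zero.  Pairwise contrasts are available either as 2-group PERMANOVAs
or via Pillai's trace from the 2-group MANOVA eigenproblem, both with
permutation p-values and no multiplicity correction (raw p is reported).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermanovaResult",
    "permanova_global",
    "pairwise_tests",
    "pillai_trace",
    "pseudo_f",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p_value: float
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.pseudo_F < 0:
            raise ValueError("pseudo_F must be >= 0")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def _check_dist(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    return dist


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    arr = np.asarray(labels)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes, list(uniq)


def pseudo_f(d2: np.ndarray, codes: np.ndarray, g: int) -> float:
    """Anderson's distance-based pseudo-F from squared distances and label codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    onehot = np.zeros((n, g))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)
    # within-group sum of squared pairwise distances, per group
    within_pairs = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / 2.0
    ss_within = float((within_pairs / counts).sum())
    ss_between = ss_total - ss_within
    if ss_total < _EPS or ss_within < _EPS:
        # no variance at all -> F defined as 0; perfect separation -> large F
        if ss_between < _EPS:
            return 0.0
        return np.inf
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova_global(dist: np.ndarray, labels, n_perm: int = 1000,
                     seed: int | None = None,
                     exhaustive: bool = False) -> PermanovaResult:
    """Global PERMANOVA on a distance matrix.

    ``exhaustive=True`` enumerates every ordering of the labels instead of
    sampling ``n_perm`` random permutations (feasible for small n only);
    the exhaustive p-value is the exact proportion of orderings whose
    pseudo-F reaches the observed one.
    """
    dist = _check_dist(dist)
    n = dist.shape[0]
    codes, uniq = _encode_labels(labels)
    g = len(uniq)
    if len(codes) != n:
        raise ValueError("number of labels must match the matrix order")
    if g < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    d2 = dist ** 2
    f_obs = pseudo_f(d2, codes, g)

    if np.isnan(f_obs):  # pragma: no cover - defensive
        raise ValueError("pseudo-F is undefined for this input")

    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_p = pseudo_f(d2, codes[list(perm)], g)
            count += f_p >= f_obs - _EPS
            total += 1
        p = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            f_p = pseudo_f(d2, rng.permutation(codes), g)
            count += f_p >= f_obs - _EPS
        p = (1 + count) / (1 + n_perm)
        n_used = n_perm

    if not np.isfinite(f_obs):
        # perfect separation: report a large finite statistic
        f_obs = np.finfo(float).max
    return PermanovaResult(pseudo_F=float(f_obs), df_between=g - 1,
                           df_within=n - g, p_value=float(p),
                           n_permutations=n_used, seed=seed)


def pillai_trace(X: np.ndarray, codes: np.ndarray) -> float:
    """Pillai's trace V = tr(B (B + W)^-1) from raw data and label codes.

    B and W are the between- and within-group cross-product matrices of the
    column-centred data.  For the 2-group case V lies in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    grand = X.mean(axis=0)
    B = np.zeros((X.shape[1], X.shape[1]))
    W = np.zeros_like(B)
    for gcode in np.unique(codes):
        sub = X[codes == gcode]
        mu = sub.mean(axis=0)
        diff = (mu - grand)[:, None]
        B += len(sub) * diff @ diff.T
        centred = sub - mu
        W += centred.T @ centred
    T = B + W
    if np.linalg.norm(T) < _EPS:
        return 0.0
    return float(np.trace(B @ np.linalg.pinv(T)))


def _pair_pvalue(stat_obs: float, null_stats: np.ndarray, n_perm: int) -> float:
    return float((1 + (null_stats >= stat_obs - _EPS).sum()) / (1 + n_perm))


def pairwise_tests(X: np.ndarray, labels, method: str = "permanova",
                   n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """All unordered 2-group contrasts with permutation p-values.

    ``X`` is the (n, d) matrix of raw isotope values (‰).  ``method`` is
    ``"permanova"`` (2-group pseudo-F on Euclidean distances) or
    ``"pillai"`` (Pillai's trace).  Pairs in which either group has a single
    member are flagged untestable rather than raising.  Returns a tidy frame
    with columns group_a, group_b, statistic, p_value, testable.
    """
    if method not in {"permanova", "pillai"}:
        raise ValueError(f"unknown method {method!r}")
    X = np.asarray(X, dtype=float)
    codes, uniq = _encode_labels(labels)
    if len(uniq) < 2:
        raise ValueError("pairwise tests require at least 2 groups")
    rng = np.random.default_rng(seed)
    rows = []
    for ia, ib in itertools.combinations(range(len(uniq)), 2):
        mask = (codes == ia) | (codes == ib)
        sub = X[mask]
        sub_codes = (codes[mask] == ib).astype(int)
        na, nb = (sub_codes == 0).sum(), (sub_codes == 1).sum()
        if na < 2 or nb < 2:
            rows.append({"group_a": uniq[ia], "group_b": uniq[ib],
                         "statistic": np.nan, "p_value": np.nan,
                         "testable": False})
            continue
        if method == "permanova":
            diff = sub[:, None, :] - sub[None, :, :]
            d2 = (diff ** 2).sum(axis=-1)
            stat = pseudo_f(d2, sub_codes, 2)
            null = np.array([pseudo_f(d2, rng.permutation(sub_codes), 2)
                             for _ in range(n_perm)])
        else:
            stat = pillai_trace(sub, sub_codes)
            null = np.array([pillai_trace(sub, rng.permutation(sub_codes))
                             for _ in range(n_perm)])
        rows.append({"group_a": uniq[ia], "group_b": uniq[ib],
                     "statistic": float(min(stat, np.finfo(float).max)),
                     "p_value": _pair_pvalue(stat, null, n_perm),
                     "testable": True})
    return pd.DataFrame(rows)
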