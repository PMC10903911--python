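"""Two-stage propagation of diet posteriors into allochthony fractions.

The invertebrate-diet posteriors (proportions over primary-producer sources)
are collapsed per draw into an allochthonous fraction a = sum of proportions
of terrestrially derived sources (riverine plants, marsh C3 and C4 plants);
everything aquatic (POM, diatoms, macroalgae/eelgrass) is autochthonous.
The fish-diet posterior (proportions over consolidated invertebrate prey
groups) is then chained through those fractions: per Monte-Carlo draw,

    A = sum_j p_j * a~_j,   a~_j = sum_m w_m * a_m

where the member fractions a_m are resampled independently (seeded) from
each member group's a-draws; fish and invertebrate posteriors were fit
separately and are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mixing import PosteriorDraws

__all__ = [
    "ALLOCHTHONOUS",
    "AUTOCHTHONOUS",
    "AllochthonyClassification",
    "ConsolidationMap",
    "AllochthonyPosterior",
    "default_classification",
    "default_consolidation",
    "invert_allochthony",
    "fish_allochthony",
    "terrestrial_prey_fraction",
    "TERRESTRIAL_PREY_GROUPS",
]

ALLOCHTHONOUS = "allochthonous"
AUTOCHTHONOUS = "autochthonous"

#: Consolidated prey groups flagged terrestrial (riverine and marsh insects
#: and dipterans) for the terrestrial-prey fraction of fish diets.
TERRESTRIAL_PREY_GROUPS = ("T1", "T2", "T345", "T6", "T7")


@dataclass(frozen=True)
class AllochthonyClassification:
    """Map of each primary source group to allochthonous/autochthonous."""

    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.classes.items()
               if c not in (ALLOCHTHONOUS, AUTOCHTHONOUS)}
        if bad:
            raise ValueError(f"invalid classes: {bad}")

    def allochthonous_sources(self) -> set[str]:
        return {g for g, c in self.classes.items() if c == ALLOCHTHONOUS}

    @classmethod
    def from_csv(cls, path) -> "AllochthonyClassification":
        df = pd.read_csv(path)
        return cls(dict(zip(df["source"].astype(str), df["class"].astype(str))))


@dataclass(frozen=True)
class ConsolidationMap:
    """Map of fish-prey group -> [(invertebrate SIMM group, weight)].

    Weights are normalized to sum to one per prey group at construction.
    Member weights default to Table-style sample counts (the only printed
    size information), supplied unnormalized in the CSV.
    """

    members: Mapping[str, tuple[tuple[str, float], ...]]
    labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        normed = {}
        for prey, mws in self.members.items():
            if not mws:
                raise ValueError(f"prey group {prey!r} has no members")
            total = sum(w for _, w in mws)
            if total <= 0 or any(w < 0 for _, w in mws):
                raise ValueError(
                    f"prey group {prey!r} weights must be >= 0, summing > 0")
            normed[prey] = tuple((m, w / total) for m, w in mws)
        object.__setattr__(self, "members", normed)

    @property
    def prey_groups(self) -> tuple[str, ...]:
        return tuple(self.members)

    @classmethod
    def from_csv(cls, path) -> "ConsolidationMap":
        df = pd.read_csv(path)
        members: dict[str, list[tuple[str, float]]] = {}
        labels: dict[str, str] = {}
        for row in df.itertuples(index=False):
            members.setdefault(str(row.prey_group), []).append(
                (str(row.member), float(row.weight)))
            if hasattr(row, "label"):
                labels[str(row.prey_group)] = str(row.label)
        return cls({k: tuple(v) for k, v in members.items()}, labels or None)


@dataclass(frozen=True)
class AllochthonyPosterior:
    """Posterior draws of the allochthonous organic-matter fraction A in [0, 1]."""

    draws: np.ndarray
    mean: float
    sd: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_draws(cls, draws: np.ndarray,
                   level: float = 0.95) -> "AllochthonyPosterior":
        draws = np.asarray(draws, dtype=float)
        if np.any((draws < -1e-12) | (draws > 1 + 1e-12)):
            raise ValueError("allochthony draws must lie in [0, 1]")
        lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
        return cls(draws=draws, mean=float(draws.mean()),
                   sd=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
                   ci_low=float(lo), ci_high=float(hi))

    @property
    def autochthonous_mean(self) -> float:
        return 1.0 - self.mean


def _data_path(name: str):
    return resources.files("isofoodweb.data").joinpath(name)


def default_classification() -> AllochthonyClassification:
    """Packaged default classes: vascular terrestrial plants allochthonous,
    POM/diatoms/delta plants autochthonous (marsh POM counted autochthonous
    even though its C:N hints at some detritus; the classification is an
    editable input)."""
    with resources.as_file(_data_path("allochthony_classes.csv")) as p:
        return AllochthonyClassification.from_csv(p)


def default_consolidation(fold_mysids: bool = True) -> ConsolidationMap:
    """Packaged prey consolidation for the fish model.

    ``fold_mysids=True`` (default) folds the riverine and marsh mysid groups
    (A3, A4) into "delta mysids and shrimp"; ``False`` keeps them as their
    own prey groups.
    """
    with resources.as_file(_data_path("fish_prey_consolidation.csv")) as p:
        cons = ConsolidationMap.from_csv(p)
    if fold_mysids:
        return cons
    members = dict(cons.members)
    a56 = [(m, w) for m, w in members["A56"] if m in ("A5", "A6")]
    members["A56"] = tuple(a56)
    members["A3"] = (("A3", 1.0),)
    members["A4"] = (("A4", 1.0),)
    labels = dict(cons.labels or {})
    labels["A3"] = "Riverine Mysids"
    labels["A4"] = "Marsh Mysids"
    return ConsolidationMap(members, labels)


def _alloch_draws(draws: PosteriorDraws, alloch: set[str],
                  classes: Mapping[str, str]) -> np.ndarray:
    unclassified = [s for s in draws.sources if s not in classes]
    if unclassified:
        raise ValueError(
            f"sources without allochthony class: {unclassified}")
    mask = np.array([s in alloch for s in draws.sources])
    return draws.p[:, mask].sum(axis=1)


def invert_allochthony(
        invert_results: Mapping[str, PosteriorDraws],
        cls: AllochthonyClassification) -> dict[str, np.ndarray]:
    """Per-draw allochthonous fraction for each invertebrate group.

    Each retained diet draw p over classified primary sources collapses to
    a = sum of the allochthonous proportions; the autochthonous fraction is
    its complement, so the two sum to one per draw by construction.
    """
    alloch = cls.allochthonous_sources()
    return {group: _alloch_draws(draws, alloch, cls.classes)
            for group, draws in invert_results.items()}


def fish_allochthony(fish_result: PosteriorDraws,
                     prey_alloch: Mapping[str, np.ndarray],
                     cons: ConsolidationMap,
                     seed: int | None = None,
                     level: float = 0.95) -> AllochthonyPosterior:
    """Chain a fish-diet posterior through invertebrate allochthony draws.

    For each fish draw, every consolidated prey group's allochthonous
    fraction is the member-weighted mean of fractions resampled (seeded)
    from the member groups' a-draws.
    """
    rng = np.random.default_rng(seed)
    n = fish_result.n_draws
    a_tilde = np.zeros((n, len(fish_result.sources)))
    for j, prey in enumerate(fish_result.sources):
        if prey not in cons.members:
            raise ValueError(f"prey group {prey!r} is not in the consolidation map")
        for member, w in cons.members[prey]:
            if member not in prey_alloch:
                raise ValueError(
                    f"prey group {prey!r}: no allochthony draws for member "
                    f"{member!r}")
            a_m = np.asarray(prey_alloch[member], dtype=float)
            idx = rng.integers(0, a_m.size, size=n)
            a_tilde[:, j] += w * a_m[idx]
    A = (fish_result.p * a_tilde).sum(axis=1)
    return AllochthonyPosterior.from_draws(A, level=level)


def terrestrial_prey_fraction(
        fish_result: PosteriorDraws,
        terrestrial_groups: Sequence[str] = TERRESTRIAL_PREY_GROUPS,
        strict: bool = True) -> np.ndarray:
    """Per-draw summed proportion of terrestrially sourced prey groups.

    With ``strict`` (default) every flagged group must appear among the
    fish posterior's prey groups.
    """
    missing = [g for g in terrestrial_groups if g not in fish_result.sources]
    if strict and missing:
        raise ValueError(f"unknown terrestrial prey groups: {missing}")
    mask = np.array([s in set(terrestrial_groups) for s in fish_result.sources])
    return fish_result.p[:, mask].sum(axis=1)
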