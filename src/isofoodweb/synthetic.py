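"""Synthetic per-sample isotope data from printed group moments.

The study's raw per-sample values are released separately; everything this
package computes can instead be exercised on synthetic data regenerated from
the published group means, SDs, and sample counts.  Samples are drawn as
independent normals per isotope (no printed covariances exist to honour;
an optional correlation parameter supports sensitivity runs), which matches
the mixing model's own likelihood assumptions.  A second generator draws
consumers from an arbitrary known source mixture for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .isotopes import ISOTOPES, GroupSummary, IsotopeMeasurement, SampleRecord
from .mixing import MeasurementError, SourceSet, TrophicEnrichment

__all__ = [
    "FixtureTable",
    "load_fixture",
    "generate_group_samples",
    "generate_consumer_from_mixture",
    "source_set_from_summaries",
]

_GROUP_HABITAT = "EEM"  # placeholder habitat for group-level synthetic records


@dataclass(frozen=True)
class FixtureTable:
    """The packaged primary-source and consumer group tables.

    ``sources`` / ``consumers`` hold the group-level rows (the italicized
    headers of the published tables); ``source_members`` / ``consumer_members``
    the constituent taxon rows.  Frames keep the printed moments verbatim.
    """

    sources: tuple[GroupSummary, ...]
    source_members: pd.DataFrame
    consumers: tuple[GroupSummary, ...]
    consumer_members: pd.DataFrame
    consumer_strata: dict[str, str]

    def source(self, group_id: str) -> GroupSummary:
        return _find(self.sources, group_id)

    def consumer(self, group_id: str) -> GroupSummary:
        return _find(self.consumers, group_id)

    @property
    def invertebrate_groups(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.consumers
                     if self.consumer_strata[g.group_id] != "fish")

    @property
    def fish_groups(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.consumers
                     if self.consumer_strata[g.group_id] == "fish")


def _find(groups: Sequence[GroupSummary], group_id: str) -> GroupSummary:
    for g in groups:
        if g.group_id == group_id:
            return g
    raise KeyError(f"no group {group_id!r} in fixture")


def _summaries_from_frame(df: pd.DataFrame) -> list[GroupSummary]:
    out = []
    for row in df.itertuples(index=False):
        means, sds = {}, {}
        for iso in ISOTOPES:
            mean = getattr(row, f"{iso}_mean")
            if pd.isna(mean):
                continue
            means[iso] = float(mean)
            sd = getattr(row, f"{iso}_sd")
            sds[iso] = None if pd.isna(sd) else float(sd)
        out.append(GroupSummary(group_id=str(row.group_id),
                                label=str(row.label), n=int(row.n),
                                means=means, sds=sds))
    return out


def load_fixture() -> FixtureTable:
    """Load the packaged group-moment tables (primary sources and consumers)."""
    pkg = resources.files("isofoodweb.data")
    with resources.as_file(pkg.joinpath("primary_sources.csv")) as p:
        src = pd.read_csv(p)
    with resources.as_file(pkg.joinpath("consumers.csv")) as p:
        con = pd.read_csv(p)
    for df, name in ((src, "primary_sources"), (con, "consumers")):
        if df.isnull().all(axis=1).any():  # pragma: no cover
            raise ValueError(f"corrupted fixture table {name!r}")
    src_groups = src[src["member"].isna()]
    con_groups = con[con["member"].isna()]
    # spot integrity checks on well-known rows
    dpom = src_groups[src_groups.group_id == "S3"].iloc[0]
    if not (dpom.d13C_mean == -21.21 and dpom.d13C_sd == 1.42 and dpom.n == 16):
        raise ValueError("fixture integrity check failed for Delta POM")
    sculpin = con_groups[con_groups.group_id == "F7"].iloc[0]
    if not (sculpin.d15N_mean == 12.44 and sculpin.d15N_sd == 0.43
            and sculpin.n == 15):
        raise ValueError("fixture integrity check failed for Marsh Sculpin")
    strata = dict(zip(con_groups["group_id"], con_groups["stratum"]))
    return FixtureTable(
        sources=tuple(_summaries_from_frame(src_groups)),
        source_members=src[src["member"].notna()].reset_index(drop=True),
        consumers=tuple(_summaries_from_frame(con_groups)),
        consumer_members=con[con["member"].notna()].reset_index(drop=True),
        consumer_strata=strata,
    )


def generate_group_samples(summary: GroupSummary, seed: int | None,
                           isotopes: Sequence[str] | None = None,
                           stratum: str = "source",
                           habitat: str = _GROUP_HABITAT,
                           correlation: float = 0.0) -> list[SampleRecord]:
    """Draw n synthetic samples for a group from Normal(mean, sd) per isotope.

    Isotopes are independent by default; ``correlation`` applies a common
    equicorrelation across the group's isotopes for sensitivity runs.
    Groups with a single sample (sd unavailable) regenerate as the printed
    value.  Reproducible given ``seed``.
    """
    iso = list(isotopes) if isotopes is not None else list(summary.isotopes)
    missing = [i for i in iso if i not in summary.means]
    if missing:
        raise ValueError(
            f"group {summary.group_id!r} lacks isotopes {missing}")
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    mu = np.array([summary.means[i] for i in iso])
    sd = np.array([summary.sd(i, default=0.0) for i in iso])
    J = len(iso)
    if correlation != 0.0 and J > 1:
        corr = np.full((J, J), correlation)
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(sd, sd)
        X = rng.multivariate_normal(mu, cov, size=summary.n)
    else:
        X = mu + sd * rng.standard_normal((summary.n, J))
    records = []
    for i in range(summary.n):
        vals = dict(zip(iso, X[i]))
        records.append(SampleRecord(
            sample_id=f"{summary.group_id}_{i:03d}",
            taxon=summary.label, habitat=habitat, stratum=stratum,
            measurement=IsotopeMeasurement(
                delta13C=float(vals.get("d13C", 0.0)),
                delta15N=float(vals.get("d15N", 0.0)),
                delta34S=(float(vals["d34S"]) if "d34S" in vals else None))))
    return records


def generate_consumer_from_mixture(sources: SourceSet, p_true,
                                   tef: TrophicEnrichment,
                                   meas: MeasurementError, n: int,
                                   seed: int | None) -> np.ndarray:
    """Draw n consumer isotope vectors implied by a known diet mixture.

    Each isotope j is Normal(sum_k p_k (mu_kj + Delta_j),
    sqrt(sum_k p_k^2 (sigma_kj^2 + sigma_Dj^2) + sigma_meas_j^2)) — exactly
    the mixing model's likelihood, so fits to this output are pure
    parameter-recovery tests.  Returns an (n, J) array.
    """
    p = np.asarray(p_true, dtype=float)
    if p.shape != (sources.n_sources,):
        raise ValueError("p_true must have one entry per source")
    if np.any(p < -1e-8) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p_true must lie on the simplex")
    if n < 1:
        raise ValueError("n must be >= 1")
    m = p @ sources.mu + tef.delta
    v = (p ** 2) @ (sources.sigma ** 2 + tef.sd ** 2) + meas.sd ** 2
    rng = np.random.default_rng(seed)
    return m + np.sqrt(v) * rng.standard_normal((n, len(sources.isotopes)))


def source_set_from_summaries(summaries: Sequence[GroupSummary],
                              isotopes: Sequence[str]) -> SourceSet:
    """Assemble a SourceSet from group summaries on a shared isotope set."""
    iso = tuple(isotopes)
    mu = np.empty((len(summaries), len(iso)))
    sigma = np.empty_like(mu)
    for k, g in enumerate(summaries):
        for j, i in enumerate(iso):
            if i not in g.means:
                raise ValueError(f"group {g.group_id!r} lacks isotope {i!r}")
            mu[k, j] = g.means[i]
            sigma[k, j] = g.sd(i, default=0.0)
    return SourceSet(names=tuple(g.group_id for g in summaries),
                     isotopes=iso, mu=mu, sigma=sigma)
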