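"""Core isotope data types and closed-form computations.

Stable isotope values are expressed in delta notation (per mil, ‰) relative
to an international standard (PDB for carbon, atmospheric N2 for nitrogen,
Vienna-CDT for sulfur).  This module holds the sample/group containers used
throughout the package plus the small closed-form operations: delta
notation, lipid normalization of consumer δ13C, trophic-level calculation
from δ15N, and C:N-based classification of particulate organic matter (POM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "HABITATS",
    "STRATA",
    "ISOTOPES",
    "IsotopeRatio",
    "IsotopeMeasurement",
    "SampleRecord",
    "GroupSummary",
    "TrophicContext",
    "PomClass",
    "delta_value",
    "ratio_from_delta",
    "lipid_correct",
    "trophic_level",
    "trophic_band",
    "classify_pom",
    "read_samples_csv",
    "write_samples_csv",
]

#: Habitat codes: freshwater forested, tidally influenced forested,
#: transitional emergent marsh, estuarine emergent salt marsh, delta mudflat,
#: eelgrass, Madrone Slough (restoring marsh), Red Salmon Slough (relict marsh).
HABITATS = frozenset({"FW", "FOR", "EFT", "EEM", "DMF", "EEL", "MAD", "RSS"})

#: Environmental strata (plus "source" for primary producers).
STRATA = frozenset({"terrestrial", "aquatic", "benthic", "fish", "source"})

#: Isotope column names used across the package.
ISOTOPES = ("d13C", "d15N", "d34S")

#: C:N threshold above which consumer δ13C is lipid-normalized.
LIPID_CN_THRESHOLD = 3.5


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class IsotopeRatio:
    """Heavy/light isotope abundance ratios for a sample and its standard."""

    ratio_sample: float
    ratio_standard: float

    def __post_init__(self) -> None:
        for name in ("ratio_sample", "ratio_standard"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One specimen's isotope values (‰) and optional ancillary chemistry.

    ``c_to_n`` is the molar carbon:nitrogen ratio; ``chlorophyll_a`` and
    ``pheophytin`` are water-column pigment concentrations in μg/L (POM only).
    Absent values are ``None`` and are never imputed.
    """

    delta13C: float
    delta15N: float
    delta34S: float | None = None
    c_to_n: float | None = None
    chlorophyll_a: float | None = None
    pheophytin: float | None = None

    def __post_init__(self) -> None:
        _require_finite("delta13C", self.delta13C)
        _require_finite("delta15N", self.delta15N)
        if self.delta34S is not None:
            _require_finite("delta34S", self.delta34S)
        if self.c_to_n is not None:
            _require_finite("c_to_n", self.c_to_n)
            if self.c_to_n <= 0:
                raise ValueError(f"c_to_n must be > 0, got {self.c_to_n}")
        for name in ("chlorophyll_a", "pheophytin"):
            v = getattr(self, name)
            if v is not None:
                _require_finite(name, v)
                if v < 0:
                    raise ValueError(f"{name} must be >= 0, got {v}")

    def isotope(self, name: str) -> float | None:
        """Return the value of isotope ``name`` ('d13C', 'd15N' or 'd34S')."""
        try:
            return {"d13C": self.delta13C, "d15N": self.delta15N,
                    "d34S": self.delta34S}[name]
        except KeyError:
            raise KeyError(f"unknown isotope {name!r}") from None


@dataclass(frozen=True)
class SampleRecord:
    """One specimen or composite sample with its isotope measurement."""

    sample_id: str
    taxon: str
    habitat: str
    stratum: str
    measurement: IsotopeMeasurement
    date: str | None = None

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(
                f"habitat {self.habitat!r} not in {sorted(HABITATS)}")
        if self.stratum not in STRATA:
            raise ValueError(
                f"stratum {self.stratum!r} not in {sorted(STRATA)}")


@dataclass(frozen=True)
class GroupSummary:
    """Per-isotope mean/SD and sample count for a named group.

    ``means`` maps isotope name -> mean (‰); the keys of ``means`` define the
    group's isotope set.  ``sds`` may omit an isotope (``None``) when n = 1.
    """

    group_id: str
    label: str
    n: int
    means: Mapping[str, float] = field(default_factory=dict)
    sds: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for iso, sd in self.sds.items():
            if sd is not None and sd < 0:
                raise ValueError(f"sd[{iso}] must be >= 0, got {sd}")

    @property
    def isotopes(self) -> tuple[str, ...]:
        return tuple(self.means)

    def sd(self, iso: str, default: float = 0.0) -> float:
        v = self.sds.get(iso)
        return default if v is None else v


@dataclass(frozen=True)
class TrophicContext:
    """Baseline and enrichment parameters for the trophic-level formula.

    ``baseline_d15N`` is the mean δ15N of the consumers at the base of the
    food web (herbivorous terrestrial insects here, at baseline level
    ``lam`` = 2); ``tef_d15N`` is the per-step δ15N trophic enrichment.
    """

    baseline_d15N: float
    tef_d15N: float
    lam: float = 2.0

    def __post_init__(self) -> None:
        _require_finite("baseline_d15N", self.baseline_d15N)
        _require_finite("tef_d15N", self.tef_d15N)
        if self.tef_d15N <= 0:
            raise ValueError(f"tef_d15N must be > 0, got {self.tef_d15N}")


class PomClass(NamedTuple):
    """POM-composition label with a flag for C:N below the phytoplankton band."""

    label: str
    below_phytoplankton_band: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def delta_value(r: IsotopeRatio) -> float:
    """Delta notation (‰): (R_sample / R_standard − 1) × 1000."""
    return (r.ratio_sample / r.ratio_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, ratio_standard: float) -> IsotopeRatio:
    """Invert delta notation: recover the sample ratio from a ‰ value."""
    if ratio_standard <= 0 or not math.isfinite(ratio_standard):
        raise ValueError("ratio_standard must be positive and finite")
    return IsotopeRatio(ratio_standard * (1.0 + delta / 1000.0), ratio_standard)


def lipid_correct(delta13C: float, c_to_n: float) -> float:
    """Lipid-normalize a consumer δ13C value when its C:N ratio exceeds 3.5.

    Applies the linear aquatic-animal normalization
    δ13C' = δ13C − 3.32 + 0.99 × C:N; tissues with C:N ≤ 3.5 are returned
    unchanged (lipid-poor tissue needs no correction).
    """
    if not math.isfinite(c_to_n) or c_to_n <= 0:
        raise ValueError(f"c_to_n must be > 0 and finite, got {c_to_n}")
    _require_finite("delta13C", delta13C)
    if c_to_n <= LIPID_CN_THRESHOLD:
        return delta13C
    return delta13C - 3.32 + 0.99 * c_to_n


def trophic_level(d15N_consumer: float, ctx: TrophicContext) -> float:
    """Trophic level from δ15N: (δ15N_consumer − δ15N_baseline)/TEF + λ."""
    _require_finite("d15N_consumer", d15N_consumer)
    return (d15N_consumer - ctx.baseline_d15N) / ctx.tef_d15N + ctx.lam


def trophic_band(tl: float) -> int:
    """Display band for a trophic level: the half-open interval [k−0.5, k+0.5)."""
    return int(math.floor(tl + 0.5))


def classify_pom(c_to_n: float, delta13C: float | None = None) -> PomClass:
    """Classify POM composition from its molar C:N ratio.

    C:N in [5, 9] indicates phytoplankton-dominant material, C:N >= 15
    terrestrial detritus, and intermediate values a phytoplankton/detritus
    mix.  Values below 5 are labelled phytoplankton_dominant with
    ``below_phytoplankton_band`` set, since the detrital signal strengthens
    with increasing C:N.  ``delta13C`` is accepted for reporting alongside
    the ratio but does not alter the label.
    """
    if not math.isfinite(c_to_n) or c_to_n <= 0:
        raise ValueError(f"c_to_n must be > 0 and finite, got {c_to_n}")
    if c_to_n < 5.0:
        return PomClass("phytoplankton_dominant", True)
    if c_to_n <= 9.0:
        return PomClass("phytoplankton_dominant")
    if c_to_n < 15.0:
        return PomClass("mixed")
    return PomClass("detrital")


# ---------------------------------------------------------------------------
# Sample CSV I/O
#
# Schema (one row per sample, UTF-8, header required):
#   sample_id, taxon, habitat, stratum, date, d13C, d15N, d34S, c_to_n,
#   chl_a, pheophytin
# Empty cells mean "absent".

_CSV_COLUMNS = ["sample_id", "taxon", "habitat", "stratum", "date",
                "d13C", "d15N", "d34S", "c_to_n", "chl_a", "pheophytin"]


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_samples_csv(path) -> list[SampleRecord]:
    """Read sample records from the package's CSV schema."""
    df = pd.read_csv(path, dtype={"sample_id": str, "taxon": str,
                                  "habitat": str, "stratum": str, "date": str})
    missing = [c for c in ("sample_id", "taxon", "habitat", "stratum",
                           "d13C", "d15N") if c not in df.columns]
    if missing:
        raise ValueError(f"sample CSV missing required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        m = IsotopeMeasurement(
            delta13C=float(row.d13C),
            delta15N=float(row.d15N),
            delta34S=_opt(getattr(row, "d34S", None)),
            c_to_n=_opt(getattr(row, "c_to_n", None)),
            chlorophyll_a=_opt(getattr(row, "chl_a", None)),
            pheophytin=_opt(getattr(row, "pheophytin", None)),
        )
        date = getattr(row, "date", None)
        records.append(SampleRecord(
            sample_id=str(row.sample_id), taxon=str(row.taxon),
            habitat=str(row.habitat), stratum=str(row.stratum),
            measurement=m, date=None if pd.isna(date) else str(date)))
    return records


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabulate sample records using the CSV schema's column order."""
    rows = []
    for s in samples:
        m = s.measurement
        rows.append({
            "sample_id": s.sample_id, "taxon": s.taxon, "habitat": s.habitat,
            "stratum": s.stratum, "date": s.date, "d13C": m.delta13C,
            "d15N": m.delta15N, "d34S": m.delta34S, "c_to_n": m.c_to_n,
            "chl_a": m.chlorophyll_a, "pheophytin": m.pheophytin,
        })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_samples_csv(samples: Sequence[SampleRecord], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)
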