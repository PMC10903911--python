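"""Config-driven end-to-end driver for the estuarine food-web analysis.

Workflow: regenerate per-sample data from the packaged group moments →
Ward clustering of primary-producer taxa → PERMANOVA contrasts per
environmental stratum → invertebrate-diet mixing model (δ13C, δ15N over the
nine primary sources) → fish-diet mixing model (δ13C, δ15N, δ34S over the
consolidated invertebrate prey groups) → chained allochthony posteriors →
manifest.  Every stage writes its artifacts to the run directory so stages
can be rerun in isolation; all randomness flows from one master seed via
named substreams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grouping import cut_to_groups, pool_summaries, ward_cluster
from .isotopes import GroupSummary
from .mixing import (MeasurementError, MixingModelConfig, PosteriorDraws,
                     SimmResult, TrophicEnrichment, fit_simm)
from .permanova import pairwise_tests, permanova_global
from .propagation import (AllochthonyClassification, AllochthonyPosterior,
                          ConsolidationMap, default_classification,
                          default_consolidation, fish_allochthony,
                          invert_allochthony, terrestrial_prey_fraction)
from .synthetic import (FixtureTable, generate_group_samples, load_fixture,
                        source_set_from_summaries)

__all__ = [
    "RunConfig",
    "Pipeline",
    "run_pipeline",
    "stage_seed",
    "INVERTEBRATE_TEF",
    "FISH_TEF",
    "MEASUREMENT_ERROR",
]

#: Literature TEF for aquatic invertebrate consumers (δ13C, δ15N; ‰).
INVERTEBRATE_TEF = TrophicEnrichment(
    ("d13C", "d15N"), np.array([0.42, 2.22]), np.array([0.18, 0.28]))

#: TEF for juvenile Chinook salmon / fish consumers (δ13C, δ15N, δ34S; ‰).
FISH_TEF = TrophicEnrichment(
    ("d13C", "d15N", "d34S"), np.array([-0.21, 2.91, -0.20]),
    np.array([0.20, 0.38, 0.29]))

#: Analytical measurement error of the isotope lab's standards (‰).
MEASUREMENT_ERROR = MeasurementError(
    ("d13C", "d15N", "d34S"), np.array([0.04, 0.07, 0.12]))


def stage_seed(master: int, name: str) -> int:
    """Derive a named, reproducible substream seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Everything a full run needs; loadable from YAML/JSON.

    The desk-scaled MCMC schedule (3 chains × 50,000 with 25,000 burn-in)
    is the default; ``paper_scale`` switches to 3 × 300,000 / 150,000.
    """

    seed: int
    outdir: str = "run"
    invert_isotopes: tuple[str, ...] = ("d13C", "d15N")
    fish_isotopes: tuple[str, ...] = ("d13C", "d15N", "d34S")
    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 25_000
    thinning: int = 25
    paper_scale: bool = False
    alpha: float = 1.0
    residual_error_invertebrates: bool = False
    residual_error_fish: bool = True
    fold_mysids: bool = True
    n_permutations: int = 1000
    pairwise_method: str = "permanova"
    cluster_k: int = 9
    fish_groups: tuple[str, ...] | None = None
    classification_path: str | None = None
    consolidation_path: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        if self.paper_scale:
            self.iterations, self.burn_in = 300_000, 150_000
        for iso in self.fish_isotopes:
            if iso not in ("d13C", "d15N", "d34S"):
                raise ValueError(f"fish stage: unknown isotope {iso!r}")
        if "d34S" not in self.fish_isotopes:
            raise ValueError(
                "fish stage requires d34S in its isotope set")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        for key in ("invert_isotopes", "fish_isotopes", "fish_groups"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def mcmc(self, isotopes: tuple[str, ...], residual: bool,
             seed: int) -> MixingModelConfig:
        return MixingModelConfig(
            isotopes=isotopes, alpha=self.alpha, chains=self.chains,
            iterations=self.iterations, burn_in=self.burn_in,
            thinning=self.thinning, residual_error=residual, seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class Pipeline:
    """Stage runner; artifacts live under ``config.outdir``."""

    config: RunConfig
    fixture: FixtureTable = field(default_factory=load_fixture)

    def __post_init__(self) -> None:
        self.outdir = Path(self.config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._manifest: dict = {
            "package_version": __version__,
            "seed": self.config.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "stages": {},
            "warnings": [],
        }
        if self.config.fold_mysids:
            self._manifest["warnings"].append(
                "riverine/marsh mysid groups (A3, A4) folded into the delta "
                "mysids-and-shrimp prey group (assumption; set "
                "fold_mysids=false to keep them separate)")

    # -- inputs -----------------------------------------------------------
    def classification(self) -> AllochthonyClassification:
        if self.config.classification_path:
            return AllochthonyClassification.from_csv(
                self.config.classification_path)
        return default_classification()

    def consolidation(self) -> ConsolidationMap:
        if self.config.consolidation_path:
            return ConsolidationMap.from_csv(self.config.consolidation_path)
        return default_consolidation(fold_mysids=self.config.fold_mysids)

    # -- stages -----------------------------------------------------------
    def simulate(self) -> dict[str, np.ndarray]:
        """Regenerate per-group sample matrices; persist them as CSV."""
        t0 = time.time()
        samples: dict[str, np.ndarray] = {}
        rows = []
        for group in (*self.fixture.sources, *self.fixture.consumers):
            iso = list(group.isotopes)
            seed = stage_seed(self.config.seed, f"simulate:{group.group_id}")
            recs = generate_group_samples(group, seed=seed, isotopes=iso)
            X = np.array([[r.measurement.isotope(i) for i in iso]
                          for r in recs])
            samples[group.group_id] = X
            for r in recs:
                m = r.measurement
                rows.append({"group_id": group.group_id,
                             "sample_id": r.sample_id, "label": group.label,
                             "d13C": m.delta13C, "d15N": m.delta15N,
                             "d34S": m.delta34S})
        frame = pd.DataFrame(rows)
        path = self.outdir / "samples.csv"
        frame.to_csv(path, index=False)
        self._manifest["stages"]["simulate"] = {
            "status": "ok", "n_samples": len(frame),
            "artifact": str(path), "sha256": _sha256(path),
            "seconds": round(time.time() - t0, 2)}
        return samples

    def _load_samples(self) -> dict[str, np.ndarray]:
        path = self.outdir / "samples.csv"
        if not path.exists():
            return self.simulate()
        frame = pd.read_csv(path)
        out = {}
        for gid, sub in frame.groupby("group_id", sort=False):
            cols = [c for c in ("d13C", "d15N", "d34S")
                    if sub[c].notna().all()]
            out[str(gid)] = sub[cols].to_numpy()
        return out

    def cluster(self) -> None:
        """Ward-cluster primary-producer taxa on δ13C/δ15N means; write Newick."""
        t0 = time.time()
        members = self.fixture.source_members
        leaves = [f"{r.group_id}:{r.member}:{r.habitat}"
                  for r in members.itertuples(index=False)]
        X = members[["d13C_mean", "d15N_mean"]].to_numpy()
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        dend = ward_cluster(dist, leaf_ids=leaves)
        k = min(self.config.cluster_k, len(leaves))
        labels = cut_to_groups(dend, k)
        (self.outdir / "source_dendrogram.nwk").write_text(dend.to_newick())
        pd.DataFrame({"leaf": list(labels), "cluster": list(labels.values())}
                     ).to_csv(self.outdir / "source_clusters.csv", index=False)
        self._manifest["stages"]["cluster"] = {
            "status": "ok", "k": k, "n_leaves": len(leaves),
            "seconds": round(time.time() - t0, 2)}

    def permanova(self, samples: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
        """Global + pairwise contrasts of consumer signatures per stratum."""
        t0 = time.time()
        samples = samples if samples is not None else self._load_samples()
        rows = []
        pair_frames = []
        for stratum in ("terrestrial", "aquatic", "benthic"):
            gids = [g for g in self.fixture.invertebrate_groups
                    if self.fixture.consumer_strata[g] == stratum]
            X = np.vstack([samples[g] for g in gids])
            labels = np.concatenate(
                [[g] * samples[g].shape[0] for g in gids])
            diff = X[:, None, :] - X[None, :, :]
            dist = np.sqrt((diff ** 2).sum(axis=-1))
            res = permanova_global(
                dist, labels, n_perm=self.config.n_permutations,
                seed=stage_seed(self.config.seed, f"permanova:{stratum}"))
            rows.append({"stratum": stratum, "pseudo_F": res.pseudo_F,
                         "df_between": res.df_between,
                         "df_within": res.df_within, "p_value": res.p_value})
            pw = pairwise_tests(
                X, labels, method=self.config.pairwise_method,
                n_perm=self.config.n_permutations,
                seed=stage_seed(self.config.seed, f"pairwise:{stratum}"))
            pw.insert(0, "stratum", stratum)
            pair_frames.append(pw)
        global_df = pd.DataFrame(rows)
        global_df.to_csv(self.outdir / "permanova_global.csv", index=False)
        pd.concat(pair_frames).to_csv(
            self.outdir / "permanova_pairwise.csv", index=False)
        self._manifest["stages"]["permanova"] = {
            "status": "ok",
            "global": global_df.to_dict(orient="records"),
            "seconds": round(time.time() - t0, 2)}
        return global_df

    def fit_invertebrates(
            self, samples: dict[str, np.ndarray] | None = None
    ) -> dict[str, SimmResult]:
        """Fit the two-isotope invertebrate SIMM for every invertebrate group.

        Sulfur is excluded automatically: the primary sources (POM, diatoms)
        lack δ34S, so the model runs on δ13C and δ15N.
        """
        t0 = time.time()
        samples = samples if samples is not None else self._load_samples()
        iso = tuple(self.config.invert_isotopes)
        sources = source_set_from_summaries(self.fixture.sources, iso)
        iso_index = {"d13C": 0, "d15N": 1, "d34S": 2}
        results: dict[str, SimmResult] = {}
        draws_dir = self.outdir / "invert_draws"
        draws_dir.mkdir(exist_ok=True)
        summary_rows = []
        for gid in self.fixture.invertebrate_groups:
            X = samples[gid][:, [iso_index[i] for i in iso]]
            cfg = self.config.mcmc(
                iso, self.config.residual_error_invertebrates,
                stage_seed(self.config.seed, f"simm:invert:{gid}"))
            res = fit_simm(X, sources, INVERTEBRATE_TEF.subset_isotopes(iso),
                           MEASUREMENT_ERROR.subset_isotopes(iso), cfg)
            results[gid] = res
            res.draws.to_frame().to_csv(draws_dir / f"{gid}.csv", index=False)
            for src, row in res.summary.iterrows():
                summary_rows.append({"consumer": gid, "source": src,
                                     **row.to_dict(),
                                     "rhat": res.rhat[src]})
        pd.DataFrame(summary_rows).to_csv(
            self.outdir / "invert_simm_summary.csv", index=False)
        non_conv = [g for g, r in results.items() if not r.converged]
        if non_conv:
            self._manifest["warnings"].append(
                f"invertebrate SIMM non-converged (R-hat > 1.1): {non_conv}")
        self._manifest["stages"]["fit_invertebrates"] = {
            "status": "ok", "n_fits": len(results),
            "schedule": {"chains": self.config.chains,
                         "iterations": self.config.iterations,
                         "burn_in": self.config.burn_in,
                         "thinning": self.config.thinning},
            "non_converged": non_conv,
            "seconds": round(time.time() - t0, 2)}
        return results

    def prey_source_set(self):
        """Pooled moments for the consolidated fish-prey groups."""
        cons = self.consolidation()
        iso = tuple(self.config.fish_isotopes)
        pooled: list[GroupSummary] = []
        for prey in cons.prey_groups:
            members = [self.fixture.consumer(m) for m, _ in cons.members[prey]]
            label = (cons.labels or {}).get(prey, prey)
            pooled.append(pool_summaries(members, group_id=prey, label=label,
                                         isotopes=iso))
        return source_set_from_summaries(pooled, iso), cons

    def fit_fish(self, samples: dict[str, np.ndarray] | None = None
                 ) -> dict[str, SimmResult]:
        """Fit the three-isotope fish SIMM over the consolidated prey groups."""
        t0 = time.time()
        samples = samples if samples is not None else self._load_samples()
        iso = tuple(self.config.fish_isotopes)
        prey_sources, _ = self.prey_source_set()
        fish_groups = (self.config.fish_groups
                       or self.fixture.fish_groups)
        iso_index = {"d13C": 0, "d15N": 1, "d34S": 2}
        results: dict[str, SimmResult] = {}
        draws_dir = self.outdir / "fish_draws"
        draws_dir.mkdir(exist_ok=True)
        summary_rows = []
        for gid in fish_groups:
            if samples[gid].shape[1] < len(iso):
                raise ValueError(
                    f"fish stage: group {gid!r} lacks values for isotopes "
                    f"{iso}")
            X = samples[gid][:, [iso_index[i] for i in iso]]
            cfg = self.config.mcmc(
                iso, self.config.residual_error_fish,
                stage_seed(self.config.seed, f"simm:fish:{gid}"))
            res = fit_simm(X, prey_sources, FISH_TEF.subset_isotopes(iso),
                           MEASUREMENT_ERROR.subset_isotopes(iso), cfg)
            results[gid] = res
            res.draws.to_frame().to_csv(draws_dir / f"{gid}.csv", index=False)
            for src, row in res.summary.iterrows():
                summary_rows.append({"consumer": gid, "source": src,
                                     **row.to_dict(), "rhat": res.rhat[src]})
        pd.DataFrame(summary_rows).to_csv(
            self.outdir / "fish_simm_summary.csv", index=False)
        non_conv = [g for g, r in results.items() if not r.converged]
        if non_conv:
            self._manifest["warnings"].append(
                f"fish SIMM non-converged (R-hat > 1.1): {non_conv}")
        self._manifest["stages"]["fit_fish"] = {
            "status": "ok", "n_fits": len(results),
            "non_converged": non_conv,
            "seconds": round(time.time() - t0, 2)}
        return results

    def _load_draws(self, subdir: str) -> dict[str, PosteriorDraws]:
        out = {}
        for path in sorted((self.outdir / subdir).glob("*.csv")):
            df = pd.read_csv(path)
            sources = [c for c in df.columns
                       if c not in ("chain", "iteration")]
            out[path.stem] = PosteriorDraws(
                sources=tuple(sources), p=df[sources].to_numpy(),
                chain=df["chain"].to_numpy())
        return out

    def allochthony(self,
                    invert_results: dict[str, SimmResult] | None = None,
                    fish_results: dict[str, SimmResult] | None = None
                    ) -> dict[str, AllochthonyPosterior]:
        """Chain diet posteriors into allochthonous-fraction posteriors per fish."""
        t0 = time.time()
        if invert_results is not None:
            invert_draws = {g: r.draws for g, r in invert_results.items()}
        else:
            invert_draws = self._load_draws("invert_draws")
        if fish_results is not None:
            fish_draws = {g: r.draws for g, r in fish_results.items()}
        else:
            fish_draws = self._load_draws("fish_draws")
        cls = self.classification()
        cons = self.consolidation()
        prey_a = invert_allochthony(invert_draws, cls)
        posteriors: dict[str, AllochthonyPosterior] = {}
        rows = []
        draws_frames = {}
        for gid, fdraws in fish_draws.items():
            post = fish_allochthony(
                fdraws, prey_a, cons,
                seed=stage_seed(self.config.seed, f"alloch:{gid}"))
            posteriors[gid] = post
            terr = terrestrial_prey_fraction(fdraws)
            rows.append({
                "fish_group": gid,
                "allochthonous_mean": post.mean,
                "allochthonous_sd": post.sd,
                "allochthonous_ci_low": post.ci_low,
                "allochthonous_ci_high": post.ci_high,
                "autochthonous_mean": post.autochthonous_mean,
                "terrestrial_prey_mean": float(terr.mean()),
            })
            draws_frames[gid] = post.draws
        summary = pd.DataFrame(rows)
        summary.to_csv(self.outdir / "allochthony_summary.csv", index=False)
        pd.DataFrame(draws_frames).to_csv(
            self.outdir / "allochthony_draws.csv", index=False)
        self._manifest["stages"]["allochthony"] = {
            "status": "ok",
            "fish_posteriors": summary.to_dict(orient="records"),
            "seconds": round(time.time() - t0, 2)}
        return posteriors

    def report(self) -> dict:
        """Write the run manifest (inputs, seed, schedule, statuses) as JSON."""
        self._manifest["mcmc_schedule"] = {
            "chains": self.config.chains,
            "iterations": self.config.iterations,
            "burn_in": self.config.burn_in,
            "thinning": self.config.thinning,
        }
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self._manifest, indent=2, sort_keys=True))
        return self._manifest


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    pipe = Pipeline(config)
    samples = pipe.simulate()
    pipe.cluster()
    pipe.permanova(samples)
    invert = pipe.fit_invertebrates(samples)
    fish = pipe.fit_fish(samples)
    pipe.allochthony(invert, fish)
    return pipe.report()
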