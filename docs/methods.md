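# Methods

`isofoodweb` reconstructs the trophic pathways of an estuarine habitat
mosaic from carbon, nitrogen, and sulfur stable isotope signatures. The
pipeline mirrors a complete field-study analysis: isotopically coherent
source groups are formed by hierarchical clustering, group contrasts are
tested by permutational MANOVA, diet composition is inferred with Bayesian
stable isotope mixing models (SIMMs) at two trophic levels, and the two
diet posteriors are chained to estimate how much of each fish group's
energy ultimately derives from terrestrial (allochthonous) versus aquatic
(autochthonous) primary production.

## Delta notation and closed-form quantities

Isotope values are per-mil deviations of a sample's heavy:light abundance
ratio from an international standard, δ = (R_sample/R_standard − 1) × 1000.
Consumer δ13C values whose molar C:N ratio exceeds 3.5 are lipid-normalized
with the linear aquatic-animal correction δ13C′ = δ13C − 3.32 + 0.99·C:N;
lipid-poor tissue (C:N ≤ 3.5) is left unchanged. Trophic level is computed
from δ15N relative to a baseline consumer as
TL = (δ15N_consumer − δ15N_baseline)/TEF + λ, with herbivorous terrestrial
insects as the baseline (λ = 2) and a δ15N trophic enrichment factor (TEF)
of 2.91 ± 0.38‰ for juvenile Chinook salmon.

Particulate organic matter (POM) is a mixture of live phytoplankton and
detritus; its composition is classified from the molar C:N ratio:
[5, 9] phytoplankton-dominant, (9, 15) mixed, ≥ 15 terrestrial detritus.
Ratios below 5 are labelled phytoplankton-dominant but flagged, since the
detrital signal strengthens monotonically with C:N; δ13C is reported
alongside but never alters the label.

## Source grouping

Clustering uses Ward's minimum-variance linkage on a Euclidean distance
matrix of raw ‰ signatures (δ13C, δ15N, and δ34S where available). Axes
are deliberately not standardized — the analysis is defined on raw per-mil
distances — though a z-score switch exists for sensitivity checks. The
number of groups k is user-supplied; the packaged default (9 primary
sources) matches the published grouping. Linkage heights satisfy
h² = 2·ΔESS and are verified in the test suite against an independent
brute-force Ward oracle on all small instances. Ties are resolved by
scipy's deterministic nearest-neighbour-chain order.

Mixing models cannot separate sources that overlap isotopically, so groups
whose means differ by less than one pooled SD on *every* isotope in use are
merged (closest pair first, repeated to a fixed point), with each merge
logged. This operationalizes decisions such as combining ulvoid macroalgae
with eelgrass into a single "delta plants" source when only δ13C and δ15N
are available. Pooled moments are exact: the merged variance includes the
between-member spread, so it equals the variance of the concatenated
samples.

## PERMANOVA

Group contrasts use the distance-based pseudo-F partition
(SS_total = Σ_{i<j} d²_ij / n, within-group sums from within-group pairs,
F = (SS_between/(g−1))/(SS_within/(n−g))) with free whole-sample label
permutation; the default is 1,000 permutations and the p-value counts the
observed statistic in numerator and denominator, so p ≥ 1/(n_perm+1).
Exhaustive enumeration of all label orderings is available for small n.
Pairwise contrasts are reported either as two-group PERMANOVAs (default)
or as Pillai's trace V = tr(B(B+W)⁻¹) from the two-group MANOVA
cross-product matrices, both with raw (uncorrected) permutation p-values.
Degenerate inputs are defined explicitly: all-identical points give F = 0,
p = 1; perfect separation gives the largest representable statistic.

## The mixing model

For a consumer group with isotope vectors x_i over isotopes j, sources k
with fixed moments (μ_kj, σ_kj), TEF shifts Δ_j ± σ_Δj, and analytical
measurement error σ_meas,j:

    x_ij ~ Normal(m_j, v_j)
    m_j  = Σ_k p_k (μ_kj + Δ_j)
    v_j  = Σ_k p_k² (σ_kj² + σ_Δj²) + σ²_meas,j + σ²_res,j

with diet proportions p ~ Dirichlet(α), α = 1 (uninformative). Source
moments enter as known constants because only group means and SDs are
observed; no concentration dependence is modelled (elemental concentrations
are not reported for these sources). The optional residual SD σ_res,j has
a weak half-normal prior (scale 5‰): it is on by default for fish, which
integrate diet over time and space beyond what the source spread captures,
and off for invertebrate composites, which sit close to their mixture.
Note the variance structure is informative about diet evenness: without a
residual term, a diffuse mixture shrinks Σp_k² and cannot reproduce an
overdispersed consumer, so sparse diets are favoured; with the residual
term enabled this penalty is absorbed and posteriors are correspondingly
flatter.

Parameters used throughout (all ‰): invertebrate model TEF
δ13C = 0.42 ± 0.18, δ15N = 2.22 ± 0.28; fish model TEF δ13C = −0.21 ± 0.20,
δ15N = 2.91 ± 0.38, δ34S = −0.20 ± 0.29; measurement error 0.04 (δ13C),
0.07 (δ15N), 0.12 (δ34S). Sulfur is excluded automatically from any model
whose sources lack δ34S — in practice the invertebrate model, because POM
and diatom samples have no sulfur values.

### Sampling

The posterior is explored by Metropolis sampling on the additive log-ratio
transform z = alr(p) (the Dirichlet prior contributes Σ_k α log p_k after
the Jacobian). Three chains run vectorized; per-chain proposal scales are
adapted during burn-in toward a 0.2–0.4 acceptance rate and frozen
afterwards. Ill-separated sources produce multimodal posteriors with modes
at simplex vertices, which a pure random walk cannot traverse; 15% of
iterations therefore use a symmetric component-swap move (an involution in
alr space with unit Jacobian) that exchanges two coordinates of p and jumps
directly between modes. The default desk schedule is 3 chains × 50,000
iterations with 25,000 burn-in and thinning 25 (3,000 retained draws); the
full published schedule (3 × 300,000 / 150,000) is available via
`--paper-scale`. Convergence is monitored with split-R-hat; any value
above 1.1 flags the fit non-converged (returned with a warning, never
silently dropped). With the swap moves, all 26 group fits in the default
pipeline converge.

The likelihood is evaluated through per-isotope sufficient statistics
(sample mean and centred sum of squares), so each MCMC iteration costs
O(KJ) regardless of the number of consumer samples.

## Allochthony propagation

Each primary source group is classified once: riverine plants and marsh C3
and C4 vascular plants are allochthonous; riverine/marsh/delta POM, marsh
and delta diatoms, and delta plants (macroalgae + eelgrass) are
autochthonous. Marsh POM is counted autochthonous by convention even though
its C:N ratio (> 9) suggests partial terrestrial detritus; the
classification is a plain CSV input, so this assumption is user-editable,
and treating marsh POM as partly allochthonous would raise every
allochthony estimate.

Per retained draw, an invertebrate group's allochthonous fraction is
a = Σ_{k allochthonous} p_k; the autochthonous fraction is its exact
complement. Fish diets are expressed over coarser consolidated prey groups
(e.g. "riverine/marsh shoreflies and shorebugs" pooling three terrestrial
groups); member weights are proportional to the members' sample counts,
the only size information available. The fish-level allochthonous fraction
is the Monte-Carlo chain A = Σ_j p_j ã_j with ã_j = Σ_m w_m a_m, where the
member fractions a_m are resampled independently (seeded) from each
member's a-draws — the two SIMMs were fit separately, so their posteriors
are treated as independent. Riverine and marsh mysids, absent from the
published consolidation list, are folded into the "delta mysids and
shrimp" group by default (switchable); the fold is noted in the run
manifest. Terrestrial prey fractions sum the flagged insect/dipteran prey
groups per draw.

## Synthetic data

The raw per-sample observations are released as a separate data product and
are not required: the generator regenerates per-sample values from the
packaged group moments (9 primary source groups, 19 invertebrate groups,
7 fish groups, with the printed means, SDs, and sample counts) as
independent normals per isotope. Independence across isotopes is a fidelity
limit — no covariances are printed — and an equicorrelation parameter is
exposed for sensitivity runs. Marginals are normal to match the mixing
model's own likelihood; no truncation is applied. Groups observed once
regenerate as the single printed value. A second generator draws consumers
from a known diet p* under exactly the SIMM likelihood, making fits to its
output pure parameter-recovery experiments. Passing tests on these data
demonstrate the statistical machinery under the model's assumptions; they
cannot validate assumptions the generator shares with the model (normality,
isotope independence, composite samples treated as independent).

## Problem sizes and reproducibility

The default pipeline regenerates 595 samples across 35 groups, runs 19
invertebrate and up to 7 fish SIMM fits at the desk schedule (roughly a
minute total on one CPU), and derives every random stream from one master
seed via named SHA-256 substreams, so any stage can be rerun in isolation
bit-for-bit. Parameter-recovery checks use 50 replicates of a 3-source,
2-isotope design with 20 consumers; PERMANOVA calibration uses 500 null
simulations of 30 samples in 3 groups with a shared non-spherical
covariance.

## Known limitations

- The published diet estimates come from a hierarchical model whose full
  internals are not stated; this package implements the standard
  fixed-source-moment SIMM those published inputs parameterize. Posterior
  *means* can therefore differ systematically (flatter diet posteriors,
  especially with the fish residual term on) even when published values sit
  comfortably inside the posterior credible intervals, which is the
  agreement the reproduction checks assert.
- Source-grouping uncertainty is not propagated into the chained
  posterior.
- No individual-level random effects, isotope covariance estimation, or
  informative priors.
- PERMDISP-style dispersion tests and stratified permutation designs are
  out of scope.
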