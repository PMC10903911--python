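"""Bayesian stable isotope mixing model (SIMM).

A consumer's isotope values are modelled as a convex combination of source
signatures shifted by a trophic enrichment factor (TEF), with variance from
source spread, TEF uncertainty, analytical measurement error, and an
optional residual term:

    x_ij ~ Normal(m_j, v_j)
    m_j  = sum_k p_k (mu_kj + Delta_j)
    v_j  = sum_k p_k^2 (sigma_kj^2 + sigma_Dj^2) + sigma_meas_j^2 + sigma_res_j^2

with diet proportions p ~ Dirichlet(alpha) on the K-simplex and, when the
residual term is enabled, sigma_res_j given a weak half-normal prior
(scale 5‰).  Source moments enter as fixed known values (only group means
and SDs are observed); no concentration dependence is modelled.

Posterior sampling is adaptive random-walk Metropolis on the additive
log-ratio (alr) transform of p, run as several independent chains that are
vectorized together for speed.  Because poorly separated sources produce
multimodal posteriors with modes at simplex vertices, the random walk is
mixed with symmetric component-swap moves (an involution in alr space with
unit Jacobian) that let chains jump directly between modes.  Convergence is
assessed by split-R-hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SourceSet",
    "TrophicEnrichment",
    "MeasurementError",
    "MixingModelConfig",
    "PosteriorDraws",
    "SimmResult",
    "fit_simm",
    "gelman_rubin",
    "effective_sample_size",
    "posterior_summary",
]

#: Half-normal prior scale (‰) for the residual SD.
RESIDUAL_PRIOR_SCALE = 5.0


@dataclass(frozen=True)
class SourceSet:
    """K candidate diet sources with per-isotope mean and SD (‰)."""

    names: tuple[str, ...]
    isotopes: tuple[str, ...]
    mu: np.ndarray      # (K, J)
    sigma: np.ndarray   # (K, J), >= 0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        K, J = len(self.names), len(self.isotopes)
        if mu.shape != (K, J) or sigma.shape != (K, J):
            raise ValueError("mu and sigma must be (K sources, J isotopes)")
        if np.any(sigma < 0):
            raise ValueError("source sds must be >= 0")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def n_sources(self) -> int:
        return len(self.names)

    def subset_isotopes(self, isotopes: Sequence[str]) -> "SourceSet":
        idx = [self.isotopes.index(i) for i in isotopes]
        return SourceSet(self.names, tuple(isotopes),
                         self.mu[:, idx], self.sigma[:, idx])


@dataclass(frozen=True)
class TrophicEnrichment:
    """Per-isotope trophic discrimination shift (mean ± SD, ‰)."""

    isotopes: tuple[str, ...]
    delta: np.ndarray   # (J,)
    sd: np.ndarray      # (J,), >= 0

    def __post_init__(self) -> None:
        delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if delta.shape != (len(self.isotopes),) or sd.shape != delta.shape:
            raise ValueError("delta and sd must have one entry per isotope")
        if np.any(sd < 0):
            raise ValueError("TEF sds must be >= 0")
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "sd", sd)

    def subset_isotopes(self, isotopes: Sequence[str]) -> "TrophicEnrichment":
        idx = [self.isotopes.index(i) for i in isotopes]
        return TrophicEnrichment(tuple(isotopes), self.delta[idx], self.sd[idx])


@dataclass(frozen=True)
class MeasurementError:
    """Per-isotope analytical measurement SD (‰)."""

    isotopes: tuple[str, ...]
    sd: np.ndarray

    def __post_init__(self) -> None:
        sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if sd.shape != (len(self.isotopes),):
            raise ValueError("sd must have one entry per isotope")
        if np.any(sd < 0):
            raise ValueError("measurement sds must be >= 0")
        object.__setattr__(self, "sd", sd)

    def subset_isotopes(self, isotopes: Sequence[str]) -> "MeasurementError":
        idx = [self.isotopes.index(i) for i in isotopes]
        return MeasurementError(tuple(isotopes), self.sd[idx])


@dataclass(frozen=True)
class MixingModelConfig:
    """Prior, error structure, and MCMC schedule for a SIMM fit.

    ``alpha`` is the common Dirichlet concentration (1 = the uninformative
    prior).  ``iterations`` counts total iterations per chain including
    ``burn_in``; every ``thinning``-th post-burn-in state is retained.
    """

    isotopes: tuple[str, ...]
    alpha: float = 1.0
    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 25_000
    thinning: int = 25
    residual_error: bool = False
    proposal_scale: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be > 0")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws of diet proportions (and residual SDs if present)."""

    sources: tuple[str, ...]
    p: np.ndarray                     # (n_draws, K), rows on the simplex
    chain: np.ndarray                 # (n_draws,) chain index
    resid_sd: np.ndarray | None = None  # (n_draws, J) when residual error on

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.sources):
            raise ValueError("p must be (n_draws, K)")
        if np.any(p < -1e-12):
            raise ValueError("proportions must be non-negative")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each draw must sum to 1 on the simplex")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "chain",
                           np.asarray(self.chain, dtype=int))

    @property
    def n_draws(self) -> int:
        return self.p.shape[0]

    def by_chain(self) -> np.ndarray:
        """Reshape to (chains, draws_per_chain, K); chains must be equal length."""
        chains = np.unique(self.chain)
        stacks = [self.p[self.chain == c] for c in chains]
        lengths = {s.shape[0] for s in stacks}
        if len(lengths) != 1:
            raise ValueError("chains have unequal retained lengths")
        return np.stack(stacks)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p, columns=list(self.sources))
        df.insert(0, "chain", self.chain)
        df.insert(1, "iteration", np.arange(len(df)))
        return df


@dataclass(frozen=True)
class SimmResult:
    """Posterior summaries and diagnostics for one SIMM fit."""

    draws: PosteriorDraws
    summary: pd.DataFrame           # per source: mean, sd, ci_low, ci_high
    rhat: dict[str, float]
    ess: dict[str, float]
    config: MixingModelConfig
    converged: bool
    acceptance_rate: float

    @property
    def means(self) -> pd.Series:
        return self.summary["mean"]


# ---------------------------------------------------------------------------
# Log-posterior pieces (vectorized over chains)

def _softmax_aug(z: np.ndarray) -> np.ndarray:
    """alr^-1: map (C, K-1) to simplex points (C, K); last component is reference."""
    aug = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
    aug -= aug.max(axis=1, keepdims=True)
    e = np.exp(aug)
    return e / e.sum(axis=1, keepdims=True)


def _log_posterior(z: np.ndarray, eta: np.ndarray | None,
                   alpha: float, n: int, xbar: np.ndarray, ss: np.ndarray,
                   mu: np.ndarray, tau2: np.ndarray, delta: np.ndarray,
                   meas2: np.ndarray, prior_only: bool) -> np.ndarray:
    """Unnormalized log posterior density in alr space, one value per chain.

    ``tau2`` is sigma_kj^2 + sigma_Dj^2 (K, J); ``xbar``/``ss`` are the
    per-isotope sample mean and centred sum of squares of the consumer data.
    The Dirichlet prior combined with the alr Jacobian contributes
    sum_k alpha * log p_k.
    """
    p = _softmax_aug(z)
    logp = alpha * np.sum(np.log(np.maximum(p, 1e-300)), axis=1)
    res2 = 0.0
    if eta is not None:
        sig = np.exp(eta)
        # half-normal prior on sigma_res plus log-Jacobian of the log transform
        logp += np.sum(-sig ** 2 / (2.0 * RESIDUAL_PRIOR_SCALE ** 2) + eta,
                       axis=1)
        res2 = sig ** 2
    if prior_only:
        return logp
    m = p @ mu + delta                      # (C, J)
    v = (p ** 2) @ tau2 + meas2 + res2      # (C, J)
    ll = -0.5 * n * np.log(2.0 * np.pi * v) \
        - (ss + n * (xbar - m) ** 2) / (2.0 * v)
    return logp + ll.sum(axis=1)


def _as_matrix(consumer_samples, J: int) -> np.ndarray:
    X = np.asarray(consumer_samples, dtype=float)
    if X.ndim == 1:
        X = X[:, None] if J == 1 else X[None, :]
    if X.ndim != 2 or X.shape[1] != J:
        raise ValueError(
            f"consumer samples must be (n, {J}) for the model's isotope set")
    if not np.all(np.isfinite(X)):
        raise ValueError("consumer samples must be finite")
    return X


def fit_simm(consumer_samples, sources: SourceSet, tef: TrophicEnrichment,
             meas: MeasurementError, config: MixingModelConfig,
             prior_only: bool = False, ci_level: float = 0.95) -> SimmResult:
    """Sample the posterior of diet proportions for one consumer group.

    ``consumer_samples`` is an (n, J) array of per-sample isotope values on
    the isotope set of ``config`` (and of ``sources``/``tef``/``meas``).
    ``prior_only`` disables the likelihood, so the draws recover the
    Dirichlet prior (a sampler validity check).  Any split-R-hat above 1.1
    flags the result non-converged (returned with a warning).
    """
    iso = tuple(config.isotopes)
    if sources.n_sources == 0:
        raise ValueError("at least one source is required")
    for obj, what in ((sources, "sources"), (tef, "TEF"), (meas, "measurement")):
        if tuple(obj.isotopes) != iso:
            raise ValueError(
                f"{what} isotope set {obj.isotopes} does not match model "
                f"isotopes {iso}")
    J = len(iso)
    K = sources.n_sources
    X = _as_matrix(consumer_samples, J)
    n = X.shape[0]

    if K == 1:
        # simplex of dimension 0: the posterior is degenerate at p = 1
        n_keep = config.chains * max(
            (config.iterations - config.burn_in) // config.thinning, 1)
        draws = PosteriorDraws(
            sources=tuple(sources.names), p=np.ones((n_keep, 1)),
            chain=np.repeat(np.arange(config.chains), n_keep // config.chains))
        summary = pd.DataFrame({"mean": [1.0], "sd": [0.0],
                                "ci_low": [1.0], "ci_high": [1.0]},
                               index=list(sources.names))
        return SimmResult(draws=draws, summary=summary,
                          rhat={sources.names[0]: 1.0},
                          ess={sources.names[0]: float(n_keep)},
                          config=config, converged=True, acceptance_rate=1.0)

    xbar = X.mean(axis=0)
    ss = ((X - xbar) ** 2).sum(axis=0)
    tau2 = sources.sigma ** 2 + tef.sd[None, :] ** 2
    meas2 = meas.sd ** 2

    C = config.chains
    rng = np.random.default_rng(config.seed)
    z = rng.normal(scale=0.5, size=(C, K - 1))
    eta = np.log(np.full((C, J), 1.0)) if config.residual_error else None
    scale = np.full(C, config.proposal_scale)

    logpost = _log_posterior(z, eta, config.alpha, n, xbar, ss, sources.mu,
                             tau2, tef.delta, meas2, prior_only)

    adapt_window = 100
    accepted_window = np.zeros(C)
    walk_window = 0
    accepted_total = 0
    walk_total = 0
    swap_prob = 0.15 if K > 2 else 0.0
    kept_p: list[np.ndarray] = []
    kept_eta: list[np.ndarray] = []
    kept_chain: list[np.ndarray] = []

    for it in range(1, config.iterations + 1):
        swap_move = swap_prob > 0.0 and rng.random() < swap_prob
        if swap_move:
            # involution swapping components i and j of p (unit Jacobian in
            # alr space): jumps directly between vertex modes
            i, j = rng.choice(K, size=2, replace=False)
            z_prop = z.copy()
            if i == K - 1:
                i, j = j, i
            if j == K - 1:
                z_prop -= z[:, i][:, None]
                z_prop[:, i] = -z[:, i]
            else:
                z_prop[:, i], z_prop[:, j] = z[:, j], z[:, i]
            eta_prop = eta
        else:
            z_prop = z + scale[:, None] * rng.standard_normal((C, K - 1))
            if eta is not None:
                eta_prop = eta + 0.3 * scale[:, None] \
                    * rng.standard_normal((C, J))
            else:
                eta_prop = None
        lp_prop = _log_posterior(z_prop, eta_prop, config.alpha, n, xbar, ss,
                                 sources.mu, tau2, tef.delta, meas2,
                                 prior_only)
        accept = np.log(rng.random(C)) < lp_prop - logpost
        z[accept] = z_prop[accept]
        if eta is not None and eta_prop is not None and not swap_move:
            eta[accept] = eta_prop[accept]
        logpost[accept] = lp_prop[accept]
        if not swap_move:
            accepted_window += accept
            walk_window += 1

        if it <= config.burn_in:
            if walk_window >= adapt_window:
                rate = accepted_window / walk_window
                scale *= np.where(rate < 0.2, 0.8,
                                  np.where(rate > 0.4, 1.25, 1.0))
                accepted_window[:] = 0.0
                walk_window = 0
        else:
            if not swap_move:
                accepted_total += int(accept.sum())
                walk_total += C
            if (it - config.burn_in) % config.thinning == 0:
                kept_p.append(_softmax_aug(z).copy())
                if eta is not None:
                    kept_eta.append(np.exp(eta).copy())
                kept_chain.append(np.arange(C))

    per_chain = len(kept_p)
    p_draws = np.concatenate(
        [np.stack(kept_p)[:, c, :] for c in range(C)], axis=0)
    chain_ix = np.repeat(np.arange(C), per_chain)
    resid = None
    if kept_eta:
        resid = np.concatenate(
            [np.stack(kept_eta)[:, c, :] for c in range(C)], axis=0)
    draws = PosteriorDraws(sources=tuple(sources.names), p=p_draws,
                           chain=chain_ix, resid_sd=resid)

    by_chain = np.stack([p_draws[chain_ix == c] for c in range(C)])
    rhat_vals = gelman_rubin(by_chain)
    ess_vals = effective_sample_size(by_chain)
    rhat = {name: float(r) for name, r in zip(sources.names, rhat_vals)}
    ess = {name: float(e) for name, e in zip(sources.names, ess_vals)}
    converged = all(r <= 1.1 for r in rhat.values())
    if not converged:
        warnings.warn(
            f"SIMM did not converge: max R-hat = {max(rhat.values()):.3f}",
            RuntimeWarning, stacklevel=2)

    summary = posterior_summary(draws, level=ci_level)
    acc_rate = accepted_total / max(walk_total, 1)
    return SimmResult(draws=draws, summary=summary, rhat=rhat, ess=ess,
                      config=config, converged=converged,
                      acceptance_rate=float(acc_rate))


def gelman_rubin(chain_draws: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter from (chains, draws, params) arrays.

    Each chain is split in half, giving 2C sequences; R-hat compares the
    between- and within-sequence variances.  Sequences with zero total
    variance return 1 by convention.
    """
    arr = np.asarray(chain_draws, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    C, T, P = arr.shape
    half = T // 2
    if half < 2:
        raise ValueError("chains too short for split-R-hat")
    seqs = np.concatenate([arr[:, :half, :], arr[:, half:2 * half, :]], axis=0)
    m, t = seqs.shape[0], seqs.shape[1]
    means = seqs.mean(axis=1)                      # (m, P)
    variances = seqs.var(axis=1, ddof=1)           # (m, P)
    W = variances.mean(axis=0)
    B = t * means.var(axis=0, ddof=1)
    out = np.ones(P)
    nz = W > 1e-300
    var_plus = (t - 1) / t * W[nz] + B[nz] / t
    out[nz] = np.sqrt(var_plus / W[nz])
    return out


def effective_sample_size(chain_draws: np.ndarray,
                          max_lag: int = 200) -> np.ndarray:
    """Crude autocorrelation-based ESS per parameter (Geyer initial-positive)."""
    arr = np.asarray(chain_draws, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    C, T, P = arr.shape
    out = np.empty(P)
    for p in range(P):
        rho_sum = 0.0
        var = arr[:, :, p].var(axis=1, ddof=0).mean()
        if var <= 1e-300:
            out[p] = C * T
            continue
        for lag in range(1, min(max_lag, T - 1)):
            acov = np.mean([
                np.mean((arr[c, :-lag, p] - arr[c, :, p].mean())
                        * (arr[c, lag:, p] - arr[c, :, p].mean()))
                for c in range(C)])
            rho = acov / var
            if rho <= 0.0:
                break
            rho_sum += rho
        out[p] = C * T / (1.0 + 2.0 * rho_sum)
    return out


def posterior_summary(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Per-source posterior mean, SD, and equal-tailed credible interval."""
    if not 0 < level < 1:
        raise ValueError(f"credible level must be in (0, 1), got {level}")
    if draws.n_draws == 0:
        raise ValueError("no draws to summarize")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    q = np.quantile(draws.p, [lo, hi], axis=0)
    return pd.DataFrame({
        "mean": draws.p.mean(axis=0),
        "sd": draws.p.std(axis=0, ddof=1) if draws.n_draws > 1
        else np.zeros(draws.p.shape[1]),
        "ci_low": q[0],
        "ci_high": q[1],
    }, index=list(draws.sources))
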