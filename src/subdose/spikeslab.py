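"""Spike-and-slab variable selection for the four-parameter logistic model.

The subgroup coefficients ``b2`` (intercept shift) and ``b3`` (slope shift)
carry Dirac-spike / normal-slab mixture priors

    b_j | gamma_j  ~  gamma_j N(m_j, s_j^2) + (1 - gamma_j) delta_0,
    P(gamma_j = 1) = w_j,

with independent Bernoulli priors on the latent inclusion indicators.  The
posterior inclusion probabilities ``w2_hat``, ``w3_hat`` (fraction of retained
MCMC draws with the term in the model) drive a choose-model step: a term
enters the escalation model when its inclusion probability exceeds a
prespecified bound.

Sampling is Metropolis-within-Gibbs: random-walk updates of the active
coefficients (step sizes adapted during burn-in only, so the retained chain
is a valid Markov chain) combined with birth/death moves on each indicator.
Birth proposals are drawn from the slab itself, which makes the prior and
proposal densities cancel, leaving the exact likelihood-times-prior-odds
acceptance ratio.  Fractional binomial weights enter the likelihood directly.
The numerical kernel is JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .model import DoseGrid, ModelSpec, ToxicityDataset, standardise_dose
from .prior import SlabPrior

__all__ = ["SpikeSlabConfig", "SpikeSlabPosterior", "run_chain", "choose_model"]


@dataclass(frozen=True)
class SpikeSlabConfig:
    """MCMC settings for the variable-selection step.

    Defaults are the full profile (20 000 iterations, 5 000 burn-in); the
    fast profile halves per-cohort cost for large simulation studies.
    """

    n_iterations: int = 20_000
    burn_in: int = 5_000
    prior_inclusion: tuple[float, float] = (0.5, 0.5)
    inclusion_bound: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if any(not (0.0 <= w <= 1.0) for w in self.prior_inclusion):
            raise ValueError("prior inclusion probabilities must lie in [0, 1]")
        if not (0.0 < self.inclusion_bound < 1.0):
            raise ValueError("inclusion bound must lie in (0, 1)")

    @classmethod
    def fast(cls, **kwargs) -> "SpikeSlabConfig":
        """Reduced-length profile (5 000 iterations, 1 000 burn-in)."""
        kwargs.setdefault("n_iterations", 5_000)
        kwargs.setdefault("burn_in", 1_000)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "SpikeSlabConfig":
        return SpikeSlabConfig(
            self.n_iterations, self.burn_in, self.prior_inclusion,
            self.inclusion_bound, int(seed),
        )


@dataclass(frozen=True)
class SpikeSlabPosterior:
    """Retained draws of coefficients and inclusion indicators."""

    beta_draws: np.ndarray    # (n_keep, 4)
    gamma_draws: np.ndarray   # (n_keep, 2) for (gamma2, gamma3)
    accept_rates: np.ndarray  # per-coordinate RW acceptance after burn-in

    @property
    def w2(self) -> float:
        return float(self.gamma_draws[:, 0].mean())

    @property
    def w3(self) -> float:
        return float(self.gamma_draws[:, 1].mean())

    @property
    def inclusion_probabilities(self) -> tuple[float, float, float, float]:
        return (1.0, 1.0, self.w2, self.w3)

    def summary(self) -> dict:
        mean = self.beta_draws.mean(axis=0)
        sd = self.beta_draws.std(axis=0)
        return {
            "w2": self.w2,
            "w3": self.w3,
            "beta_mean": mean.tolist(),
            "beta_sd": sd.tolist(),
            "n_draws": int(self.beta_draws.shape[0]),
            "accept_rates": self.accept_rates.tolist(),
        }


@njit(cache=True)
def _loglik(z, g, y1, y0, b0, b1, b2, b3):
    s = 0.0
    for i in range(z.shape[0]):
        eta = b0 + b1 * z[i] + g[i] * (b2 + b3 * z[i])
        if eta > 0.0:
            lse = eta + np.log1p(np.exp(-eta))
        else:
            lse = np.log1p(np.exp(eta))
        s += y1[i] * eta - (y1[i] + y0[i]) * lse
    return s


@njit(cache=True)
def _chain_kernel(z, g, y1, y0, mean, sd, w2, w3, n_iter, burn_in, seed):
    np.random.seed(seed)
    beta = mean.copy()
    gamma2 = 1
    gamma3 = 1
    if w2 <= 0.0:
        gamma2 = 0
        beta[2] = 0.0
    if w3 <= 0.0:
        gamma3 = 0
        beta[3] = 0.0

    log_step = np.log(np.maximum(sd, 1e-3))
    ll = _loglik(z, g, y1, y0, beta[0], beta[1], beta[2], beta[3])

    n_keep = n_iter - burn_in
    betas = np.zeros((n_keep, 4))
    gammas = np.zeros((n_keep, 2), dtype=np.int64)
    acc = np.zeros(4)
    n_prop = np.zeros(4)

    lw2 = np.log(w2) if w2 > 0.0 else -np.inf
    l1w2 = np.log(1.0 - w2) if w2 < 1.0 else -np.inf
    lw3 = np.log(w3) if w3 > 0.0 else -np.inf
    l1w3 = np.log(1.0 - w3) if w3 < 1.0 else -np.inf

    for it in range(n_iter):
        # random-walk updates of the active coefficients
        for k in range(4):
            if k == 2 and gamma2 == 0:
                continue
            if k == 3 and gamma3 == 0:
                continue
            old = beta[k]
            prop = old + np.exp(log_step[k]) * np.random.normal()
            beta[k] = prop
            ll_new = _loglik(z, g, y1, y0, beta[0], beta[1], beta[2], beta[3])
            dprior = (
                (old - mean[k]) ** 2 - (prop - mean[k]) ** 2
            ) / (2.0 * sd[k] * sd[k])
            log_alpha = ll_new - ll + dprior
            accepted = np.log(np.random.random()) < log_alpha
            if accepted:
                ll = ll_new
            else:
                beta[k] = old
            if it < burn_in:
                rate = 2.0 / np.sqrt(it + 1.0)
                if rate > 0.1:
                    rate = 0.1
                log_step[k] += rate * ((1.0 if accepted else 0.0) - 0.44)
            else:
                n_prop[k] += 1.0
                if accepted:
                    acc[k] += 1.0

        # birth/death moves on the inclusion indicators
        for j in range(2, 4):
            if j == 2:
                wj, lwj, l1wj, gam = w2, lw2, l1w2, gamma2
            else:
                wj, lwj, l1wj, gam = w3, lw3, l1w3, gamma3
            if wj <= 0.0 or wj >= 1.0:
                continue
            if gam == 1:
                old = beta[j]
                beta[j] = 0.0
                ll0 = _loglik(z, g, y1, y0, beta[0], beta[1], beta[2], beta[3])
                log_alpha = ll0 - ll + l1wj - lwj
                if np.log(np.random.random()) < log_alpha:
                    ll = ll0
                    if j == 2:
                        gamma2 = 0
                    else:
                        gamma3 = 0
                else:
                    beta[j] = old
            else:
                prop = mean[j] + sd[j] * np.random.normal()
                beta[j] = prop
                ll1 = _loglik(z, g, y1, y0, beta[0], beta[1], beta[2], beta[3])
                log_alpha = ll1 - ll + lwj - l1wj
                if np.log(np.random.random()) < log_alpha:
                    ll = ll1
                    if j == 2:
                        gamma2 = 1
                    else:
                        gamma3 = 1
                else:
                    beta[j] = 0.0

        if it >= burn_in:
            keep = it - burn_in
            betas[keep, 0] = beta[0]
            betas[keep, 1] = beta[1]
            betas[keep, 2] = beta[2]
            betas[keep, 3] = beta[3]
            gammas[keep, 0] = gamma2
            gammas[keep, 1] = gamma3

    for k in range(4):
        if n_prop[k] > 0.0:
            acc[k] /= n_prop[k]
    return betas, gammas, acc


def run_chain(
    data: ToxicityDataset,
    slab: SlabPrior,
    grid: DoseGrid,
    config: SpikeSlabConfig,
) -> SpikeSlabPosterior:
    """Sample the spike-and-slab posterior for the given dataset.

    The dataset normally contains the pseudo-data plus any observed patients;
    an empty dataset yields draws from the prior.  A fixed seed gives
    bit-identical output.
    """
    sd = slab.sd
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise ValueError("degenerate slab covariance")
    dose, g, y1, y0 = data.arrays()
    z = (
        np.atleast_1d(standardise_dose(dose, grid))
        if dose.size
        else np.empty(0)
    )
    w2, w3 = config.prior_inclusion
    betas, gammas, acc = _chain_kernel(
        np.ascontiguousarray(z, dtype=np.float64),
        np.ascontiguousarray(g, dtype=np.float64),
        np.ascontiguousarray(y1, dtype=np.float64),
        np.ascontiguousarray(y0, dtype=np.float64),
        np.ascontiguousarray(slab.mean, dtype=np.float64),
        np.ascontiguousarray(sd, dtype=np.float64),
        float(w2),
        float(w3),
        int(config.n_iterations),
        int(config.burn_in),
        int(config.seed) % (2**31),
    )
    return SpikeSlabPosterior(betas, gammas, acc)


def choose_model(
    posterior: SpikeSlabPosterior, config: SpikeSlabConfig
) -> ModelSpec:
    """Terms with posterior inclusion probability strictly above the bound
    enter the escalation model; b0 and b1 are always included."""
    return ModelSpec(
        include_beta2=posterior.w2 > config.inclusion_bound,
        include_beta3=posterior.w3 > config.inclusion_bound,
    )
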