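"""Single-source contamination model for SNP-probe beta-values.

When a sample is contaminated with DNA from one foreign source, SNP-probe
beta-values shift from their genotype cluster toward the contaminating
genotype, the same way heterozygous beta-values scatter around 0.5. The
generative model for sample n and SNP probe j is

    beta_nj ~ Normal((1 - gamma_n) * mu_k(n,j) + gamma_n * c_j,
                     (1 - gamma_n) * sigma_k(n,j))

with k(n,j) in {AA, AB, BB} the host genotype, mu_k / sigma_k the cluster
location and spread, c_j the methylation level of probe j in the foreign
DNA, and gamma_n in [0, 1) the per-sample degree of contamination. The
spread shrinks with gamma because a mixed signal averages over many beads.

Posteriors are sampled with a Metropolis-within-Gibbs scheme: random-walk
proposals (reflected at the bounds) for gamma_n, c_j, mu_k and sigma_k, and
discrete Gibbs updates for the genotype assignments. Priors are uniform on
[0, 0.99] for gamma_n and [0, 1] for c_j, flat order-constrained on mu, and
half-normal(0.1) on sigma. The whole cohort is fitted jointly, and every
draw is reproducible from one integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .exceptions import FitError, ValidationError
from .genotyping import GenotypePosteriors
from .preprocess import BetaMatrix

_GAMMA_MAX = 0.99
_SIGMA_MIN = 1e-4
_SIGMA_PRIOR_SCALE = 0.1
_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


@dataclass
class ContaminationFit:
    """Posterior summaries of the contamination model.

    ``gamma`` are per-sample posterior-mean contamination degrees with
    2.5/97.5-percentile bounds in ``gamma_ci``; ``genotypes`` holds the
    modal genotype index (0=AA, 1=AB, 2=BB) per (sample, probe); ``chain``
    retains thinned post-burn-in gamma draws for diagnostics.
    """

    gamma: pd.Series
    gamma_ci: pd.DataFrame
    c: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    genotypes: np.ndarray
    chain: np.ndarray  # (n_kept, n_samples) gamma draws
    acceptance_rate: Dict[str, float] = field(default_factory=dict)


def contamination_loglik(
    beta_snp: np.ndarray,
    gamma: np.ndarray,
    c: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    genotypes: np.ndarray,
) -> float:
    """Total log-likelihood; missing beta entries are skipped."""
    gamma = np.asarray(gamma, dtype=float)
    c = np.asarray(c, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if ((gamma < 0) | (gamma > _GAMMA_MAX)).any():
        raise ValidationError(f"gamma must lie in [0, {_GAMMA_MAX}]")
    if ((c < 0) | (c > 1)).any():
        raise ValidationError("c must lie in [0, 1]")
    if (sigma <= 0).any():
        raise ValidationError("sigma must be positive")
    cells = _cell_loglik(np.asarray(beta_snp, dtype=float), gamma, c, mu, sigma,
                         np.asarray(genotypes))
    return float(np.nansum(cells))


def _cell_loglik(beta, gamma, c, mu, sigma, genotypes):
    """(N, J) log normal densities; NaN where beta missing."""
    one_m = (1.0 - gamma)[:, None]
    mean = one_m * mu[genotypes] + gamma[:, None] * c[None, :]
    sd = one_m * sigma[genotypes]
    z = (beta - mean) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    period = 2.0 * (hi - lo)
    y = np.mod(x - lo, period)
    y = np.where(y > (hi - lo), period - y, y)
    return y + lo


def fit_contamination(
    beta_snp: BetaMatrix,
    init: Optional[GenotypePosteriors] = None,
    n_iter: int = 10_000,
    burn_in: int = 5_000,
    seed: int = 0,
    thin: int = 10,
) -> ContaminationFit:
    """Joint Metropolis-within-Gibbs fit of the contamination model.

    ``init`` (genotype posteriors from the mixture model) seeds the genotype
    assignments and cluster locations; without it, hard thresholds at 0.25
    and 0.75 are used. Proposal scales adapt during burn-in toward ~0.3
    acceptance. Point estimates are posterior means over the retained
    (thinned) post-burn-in draws; genotype estimates are posterior modes.
    """
    beta = beta_snp.beta.to_numpy(dtype=float).T  # samples x probes
    n, j = beta.shape
    if n < 10:
        raise ValidationError("contamination fit requires >= 10 samples")
    mask = np.isfinite(beta)
    if (mask.sum(axis=0) > 0).sum() < 20:
        raise ValidationError("contamination fit requires >= 20 SNP probes with data")
    if burn_in >= n_iter:
        raise ValidationError("burn_in must be smaller than n_iter")
    rng = np.random.default_rng(seed)
    beta_f = np.where(mask, beta, 0.5)  # placeholder; masked out of all sums

    # --- initialization ----------------------------------------------------
    if init is not None:
        k = init.hard_calls()
        k[k < 0] = 1
    else:
        k = np.where(beta_f < 0.25, 0, np.where(beta_f > 0.75, 2, 1))
    mu = np.empty(3)
    sigma = np.empty(3)
    for comp, default_mu in zip(range(3), (0.05, 0.5, 0.95)):
        sel = (k == comp) & mask
        if sel.sum() >= 10:
            mu[comp] = beta_f[sel].mean()
            sigma[comp] = max(beta_f[sel].std(), 0.01)
        else:
            mu[comp] = default_mu
            sigma[comp] = 0.05
    mu = np.sort(mu)
    gamma = np.full(n, 0.01)
    c = np.full(j, 0.5)

    cur = _cell_loglik(beta_f, gamma, c, mu, sigma, k)
    cur[~mask] = 0.0

    # --- sampler state -----------------------------------------------------
    scales = {"gamma": 0.02, "c": 0.05, "mu": 0.01, "sigma": 0.01}
    accepted = {key: 0.0 for key in scales}
    proposed = {key: 0.0 for key in scales}
    adapt_window = 50

    n_kept = (n_iter - burn_in + thin - 1) // thin
    chain = np.empty((n_kept, n))
    kept = 0
    gamma_sum = np.zeros(n)
    c_sum = np.zeros(j)
    mu_sum = np.zeros(3)
    sigma_sum = np.zeros(3)
    k_counts = np.zeros((n, j, 3))

    for it in range(n_iter):
        # gamma_n: independent random walks, vectorized over samples
        prop = _reflect(gamma + rng.normal(0, scales["gamma"], n), 0.0, _GAMMA_MAX)
        new = _cell_loglik(beta_f, prop, c, mu, sigma, k)
        new[~mask] = 0.0
        delta = new.sum(axis=1) - cur.sum(axis=1)
        acc = np.log(rng.uniform(size=n)) < delta
        gamma = np.where(acc, prop, gamma)
        cur[acc] = new[acc]
        accepted["gamma"] += acc.mean()
        proposed["gamma"] += 1.0

        # c_j: vectorized over probes
        prop = _reflect(c + rng.normal(0, scales["c"], j), 0.0, 1.0)
        new = _cell_loglik(beta_f, gamma, prop, mu, sigma, k)
        new[~mask] = 0.0
        delta = new.sum(axis=0) - cur.sum(axis=0)
        acc = np.log(rng.uniform(size=j)) < delta
        c = np.where(acc, prop, c)
        cur[:, acc] = new[:, acc]
        accepted["c"] += acc.mean()
        proposed["c"] += 1.0

        # mu_k and sigma_k: scalar random walks per component
        for comp in range(3):
            step = rng.normal(0, scales["mu"])
            prop_mu = mu.copy()
            prop_mu[comp] = _reflect(np.array([mu[comp] + step]), 0.0, 1.0)[0]
            proposed["mu"] += 1.0
            if prop_mu[0] < prop_mu[1] < prop_mu[2]:  # flat ordered prior
                sel = (k == comp) & mask
                new_cells = _cell_loglik(beta_f, gamma, c, prop_mu, sigma, k)
                delta = new_cells[sel].sum() - cur[sel].sum()
                if np.log(rng.uniform()) < delta:
                    mu = prop_mu
                    cur[sel] = new_cells[sel]
                    accepted["mu"] += 1.0

            step = rng.normal(0, scales["sigma"])
            prop_sigma = sigma.copy()
            prop_sigma[comp] = _reflect(np.array([sigma[comp] + step]),
                                        _SIGMA_MIN, 1.0)[0]
            proposed["sigma"] += 1.0
            sel = (k == comp) & mask
            new_cells = _cell_loglik(beta_f, gamma, c, mu, prop_sigma, k)
            prior = (sigma[comp] ** 2 - prop_sigma[comp] ** 2) / (2 * _SIGMA_PRIOR_SCALE ** 2)
            delta = new_cells[sel].sum() - cur[sel].sum() + prior
            if np.log(rng.uniform()) < delta:
                sigma = prop_sigma
                cur[sel] = new_cells[sel]
                accepted["sigma"] += 1.0

        # genotype assignments: discrete Gibbs, proportional to likelihoods
        logp = np.stack([
            _cell_loglik(beta_f, gamma, c, mu, sigma,
                         np.full((n, j), comp, dtype=int))
            for comp in range(3)
        ], axis=-1)
        logp -= logp.max(axis=-1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=-1, keepdims=True)
        u = rng.uniform(size=(n, j, 1))
        k = (u > np.cumsum(p, axis=-1)).sum(axis=-1)
        cur = _cell_loglik(beta_f, gamma, c, mu, sigma, k)
        cur[~mask] = 0.0

        if not np.isfinite(cur[mask]).all():
            raise FitError("non-finite log-likelihood in contamination chain")

        # adapt proposal scales toward ~0.3 acceptance during burn-in
        if it < burn_in and (it + 1) % adapt_window == 0:
            for key in scales:
                rate = accepted[key] / max(proposed[key], 1.0)
                scales[key] = float(np.clip(
                    scales[key] * np.exp(1.5 * (rate - 0.3)), 1e-5, 0.5))
                accepted[key] = proposed[key] = 0.0

        if it >= burn_in:
            gamma_sum += gamma
            c_sum += c
            mu_sum += mu
            sigma_sum += sigma
            rows = np.repeat(np.arange(n), j)
            k_counts[rows, np.tile(np.arange(j), n), k.ravel()] += 1
            if (it - burn_in) % thin == 0:
                chain[kept] = gamma
                kept += 1

    n_post = n_iter - burn_in
    rates = {key: accepted[key] / max(proposed[key], 1.0) for key in scales}
    for key, rate in rates.items():
        if not 0.05 <= rate <= 0.95:
            warnings.warn(
                f"contamination sampler: acceptance rate for {key} is {rate:.2f}, "
                "outside [0.05, 0.95]; inspect the chain", stacklevel=2)

    chain = chain[:kept]
    sample_ids = beta_snp.beta.columns
    gamma_hat = pd.Series(gamma_sum / n_post, index=sample_ids, name="gamma_hat")
    ci = pd.DataFrame({
        "gamma_ci_low": np.percentile(chain, 2.5, axis=0),
        "gamma_ci_high": np.percentile(chain, 97.5, axis=0),
    }, index=sample_ids)
    return ContaminationFit(
        gamma=gamma_hat,
        gamma_ci=ci,
        c=c_sum / n_post,
        mu=mu_sum / n_post,
        sigma=sigma_sum / n_post,
        genotypes=np.argmax(k_counts, axis=2),
        chain=chain,
        acceptance_rate=rates,
    )


def write_contamination_report(fit: ContaminationFit, path) -> None:
    out = pd.concat([fit.gamma, fit.gamma_ci], axis=1).reset_index(names="sample_id")
    out.to_csv(path, sep="\t", index=False, na_rep="")
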