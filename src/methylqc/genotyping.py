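"""SNP-probe genotype calling and sample fingerprinting.

The arrays carry a set of probes querying high-frequency SNPs (identifiers
starting with "rs"; 65 on the 450K design, 59 on EPIC). Their beta-values
fall into three clusters around 0, 0.5 and 1, corresponding to the
homozygous and heterozygous genotypes AA / AB / BB. Pooling beta-values of
all SNP probes across samples, a four-component mixture is fitted by EM:
three Beta distributions, one per genotype, plus a uniform density on
[0, 1] absorbing outliers. The per-(sample, probe) posterior over the four
components is a soft genotype call.

Downstream of the calls:

* ``snp_outliers`` summarises each sample by O_n, the average log2 odds of
  its SNP probes belonging to the outlier component — a generic indicator
  of contamination or poor technical quality (samples above about -4 merit
  exclusion).
* ``check_snp_agreement`` scores every sample pair by the soft fraction of
  SNPs on which they share a genotype, outlier mass softly excluded from
  both numerator and denominator; conflicts with the donor metadata
  (unexpected disagreement of same-donor pairs, unexpected agreement of
  different-donor pairs) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import FitError, ValidationError
from .preprocess import BetaMatrix

_EPS = 1e-6  # clip beta into the open interval for Beta densities
_LOGODDS_CLIP = 40.0  # |log2 odds| bound for degenerate posteriors

GENOTYPES = ("AA", "AB", "BB")
COMPONENTS = (*GENOTYPES, "outlier")


@dataclass
class SnpMixtureModel:
    """Fitted 3-Beta + uniform mixture over pooled SNP beta-values.

    ``weights`` are the four mixing proportions (AA, AB, BB, outlier);
    ``beta_params`` holds one (shape1, shape2) pair per genotype component,
    ordered by ascending mean. The outlier component is a fixed uniform
    density on [0, 1]; only its weight is learned.
    """

    weights: np.ndarray
    beta_params: np.ndarray  # (3, 2)
    loglik_trace: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.beta_params = np.asarray(self.beta_params, dtype=float)
        if self.weights.shape != (4,) or not np.isclose(self.weights.sum(), 1.0):
            raise ValidationError("mixture weights must be 4 proportions summing to 1")
        if (self.weights < -1e-12).any():
            raise ValidationError("mixture weights must be non-negative")
        if self.beta_params.shape != (3, 2) or (self.beta_params <= 0).any():
            raise ValidationError("beta_params must be three positive (shape1, shape2) pairs")
        means = self.component_means()
        if not (means[0] < means[1] < means[2]):
            raise ValidationError("component means must be strictly ordered AA < AB < BB")

    def component_means(self) -> np.ndarray:
        a, b = self.beta_params[:, 0], self.beta_params[:, 1]
        return a / (a + b)

    def component_log_densities(self, beta: np.ndarray) -> np.ndarray:
        """Log densities of the 4 components at each beta value; shape (..., 4)."""
        x = np.clip(beta, _EPS, 1 - _EPS)
        logds = [stats.beta.logpdf(x, a, b) for a, b in self.beta_params]
        logds.append(np.zeros_like(x))  # log uniform density on [0, 1]
        return np.stack(logds, axis=-1)


@dataclass
class GenotypePosteriors:
    """(sample x SNP probe x 4) posterior probabilities; NaN slices where beta missing."""

    posts: np.ndarray
    sample_ids: pd.Index
    probe_ids: pd.Index

    def __post_init__(self) -> None:
        p = np.asarray(self.posts, dtype=float)
        if p.ndim != 3 or p.shape[2] != 4:
            raise ValidationError("posteriors must have shape (samples, probes, 4)")
        sums = p.sum(axis=2)
        ok = np.isnan(sums) | np.isclose(sums, 1.0, atol=1e-8)
        if not ok.all():
            raise ValidationError("each (sample, probe) posterior slice must sum to 1")
        self.posts = p

    @property
    def outlier(self) -> np.ndarray:
        return self.posts[:, :, 3]

    @property
    def genotype(self) -> np.ndarray:
        return self.posts[:, :, :3]

    def hard_calls(self) -> np.ndarray:
        """Most probable genotype index (0=AA, 1=AB, 2=BB) per cell, -1 where missing."""
        g = self.genotype
        calls = np.full(g.shape[:2], -1, dtype=int)
        ok = np.isfinite(g).all(axis=2)
        calls[ok] = np.argmax(g[ok], axis=1)
        return calls


@dataclass
class AgreementResult:
    """Pairwise fingerprint agreement scores and metadata conflicts."""

    pairs: pd.DataFrame  # sample_a, sample_b, donor_a, donor_b, agreement, n_effective
    conflicts: pd.DataFrame  # subset with conflict_type column
    threshold: float


# ---------------------------------------------------------------------------
# EM fitting


def _pool(beta_snp: BetaMatrix) -> np.ndarray:
    vals = beta_snp.beta.to_numpy(dtype=float).ravel()
    return vals[np.isfinite(vals)]


def _weighted_beta_mle(x: np.ndarray, w: np.ndarray,
                       start: Tuple[float, float]) -> Tuple[float, float]:
    """Weighted maximum-likelihood Beta shapes, warm-started; never worse than start."""
    wsum = w.sum()
    if wsum <= 0:
        return start
    logx = np.log(x)
    log1mx = np.log1p(-x)
    s1 = float(np.dot(w, logx) / wsum)
    s2 = float(np.dot(w, log1mx) / wsum)

    def negll(params):
        a, b = params
        return -(s1 * (a - 1) + s2 * (b - 1) - special.betaln(a, b))

    def grad(params):
        a, b = params
        dig = special.digamma(a + b)
        return np.array([-(s1 - special.digamma(a) + dig),
                         -(s2 - special.digamma(b) + dig)])

    res = optimize.minimize(negll, np.asarray(start, dtype=float), jac=grad,
                            method="L-BFGS-B",
                            bounds=[(1e-3, 1e4), (1e-3, 1e4)])
    if not res.success or negll(res.x) > negll(start) + 1e-12:
        return start  # preserve the EM ascent guarantee
    return float(res.x[0]), float(res.x[1])


def _moment_match(x: np.ndarray) -> Tuple[float, float]:
    m = float(np.mean(x))
    v = float(np.var(x))
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = max(min(v, m * (1 - m) * 0.99), 1e-6)
    common = m * (1 - m) / v - 1
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


_FALLBACK_PARAMS = np.array([[2.0, 38.0], [50.0, 50.0], [38.0, 2.0]])
# second EM start: tight genotype clusters with a heavier outlier weight,
# suited to cohorts where many beta-values sit between clusters
_TIGHT_PARAMS = np.array([[18.0, 342.0], [50.0, 50.0], [342.0, 18.0]])


def _initial_model(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Moment-matched init from the beta bins [0,.25], (.25,.75], (.75,1]."""
    bins = [x <= 0.25, (x > 0.25) & (x <= 0.75), x > 0.75]
    params = []
    weights = []
    for i, mask in enumerate(bins):
        if mask.sum() >= 5:
            params.append(_moment_match(np.clip(x[mask], _EPS, 1 - _EPS)))
        else:
            params.append(tuple(_FALLBACK_PARAMS[i]))
        weights.append(max(mask.mean(), 1e-3))
    w = np.array(weights, dtype=float)
    w = w / w.sum() * 0.99
    return np.append(w, 0.01), np.asarray(params, dtype=float)


def fit_snp_mixture(
    beta_snp: BetaMatrix,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SnpMixtureModel:
    """EM fit of the 4-component mixture to pooled SNP beta-values.

    Beta-values are pooled across all samples and SNP probes. The outlier
    component's density is fixed at 1 on [0, 1]; its weight is learned.
    Components are relabeled by ascending mean after fitting. The
    log-likelihood trace is non-decreasing; a degenerate fit triggers one
    refit from a fixed fallback initialization before raising
    :class:`FitError`.
    """
    if beta_snp.beta.shape[1] < 2:
        raise ValidationError("mixture fitting requires at least 2 samples")
    x = _pool(beta_snp)
    if x.size < 50:
        raise ValidationError(f"need >= 50 pooled beta-values, got {x.size}")
    x = np.clip(x, _EPS, 1 - _EPS)

    # multi-start EM: a moment-matched start and a tight-cluster start;
    # keep whichever converges to the higher log-likelihood
    w0, p0 = _initial_model(x)
    starts = [
        (w0, p0),
        (np.array([0.3, 0.3, 0.3, 0.1]), _TIGHT_PARAMS.copy()),
    ]
    best: Optional[SnpMixtureModel] = None
    last_error: Optional[FitError] = None
    for weights, params in starts:
        try:
            fit = _run_em(x, weights, params, max_iter, tol)
        except FitError as exc:
            last_error = exc
            continue
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    if best is None:
        try:
            return _run_em(x, np.array([0.33, 0.33, 0.33, 0.01]),
                           _FALLBACK_PARAMS.copy(), max_iter, tol)
        except FitError:
            raise last_error or FitError("mixture fit failed")
    return best


def _run_em(x: np.ndarray, weights: np.ndarray, params: np.ndarray,
            max_iter: int, tol: float) -> SnpMixtureModel:
    logx, log1mx = np.log(x), np.log1p(-x)
    trace: List[float] = []
    for _ in range(max_iter):
        logd = np.stack(
            [(a - 1) * logx + (b - 1) * log1mx - special.betaln(a, b)
             for a, b in params] + [np.zeros_like(x)], axis=1)
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(weights, 1e-300))
        joint = logd + logw
        norm = special.logsumexp(joint, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            raise FitError("non-finite log-likelihood during EM")
        resp = np.exp(joint - norm[:, None])
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        new_weights = resp.mean(axis=0)
        if (new_weights[:3] < 1e-10).any():
            raise FitError("a genotype component lost all mass")
        new_params = np.array([
            _weighted_beta_mle(x, resp[:, k], tuple(params[k])) for k in range(3)
        ])
        weights, params = new_weights, new_params

    order = np.argsort(params[:, 0] / params[:, 0:2].sum(axis=1))
    params = params[order]
    weights = np.append(weights[:3][order], weights[3])
    means = params[:, 0] / params.sum(axis=1)
    if not (means[0] < means[1] < means[2]):
        raise FitError("fitted component means are not separable")
    return SnpMixtureModel(weights=weights, beta_params=params, loglik_trace=trace)


# ---------------------------------------------------------------------------
# Calling, outliers, agreement


def call_genotypes(model: SnpMixtureModel, beta_snp: BetaMatrix) -> GenotypePosteriors:
    """Posterior over {AA, AB, BB, outlier} for every (sample, SNP probe)."""
    beta = beta_snp.beta.to_numpy(dtype=float).T  # samples x probes
    finite = np.isfinite(beta)
    if ((beta[finite] < 0) | (beta[finite] > 1)).any():
        raise ValidationError("beta-values outside [0, 1]")
    logd = model.component_log_densities(np.where(finite, beta, 0.5))
    with np.errstate(divide="ignore"):
        joint = logd + np.log(np.maximum(model.weights, 1e-300))
    posts = np.exp(joint - special.logsumexp(joint, axis=-1, keepdims=True))
    posts[~finite] = np.nan
    return GenotypePosteriors(posts=posts,
                              sample_ids=beta_snp.beta.columns,
                              probe_ids=beta_snp.beta.index)


def snp_outliers(posteriors: GenotypePosteriors) -> pd.Series:
    """O_n: per-sample mean log2 odds of SNP probes being outliers.

    Log-odds are clipped at +/-40 for degenerate posteriors of 0 or 1.
    Samples with no non-missing probe get a missing O_n.
    """
    p = posteriors.outlier
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = np.log2(p) - np.log2(1 - p)
    lo = np.clip(lo, -_LOGODDS_CLIP, _LOGODDS_CLIP)
    lo[~np.isfinite(posteriors.posts[:, :, 3])] = np.nan
    with np.errstate(invalid="ignore"):
        o = np.nanmean(lo, axis=1)
    return pd.Series(o, index=posteriors.sample_ids, name="snp_outlier_logodds")


def pairwise_agreement_matrix(posteriors: GenotypePosteriors) -> Tuple[np.ndarray, np.ndarray]:
    """Full sample x sample agreement matrix and effective probe counts.

    agreement(a, b) = sum_j sum_k q_a[j,k] q_b[j,k] / sum_j w_a[j] w_b[j]
    with q the genotype-component posteriors and w = 1 - p_outlier, so a
    probe partially classified as outlier is partially excluded from both
    numerator and denominator. Missing probes contribute zero to both.
    """
    q = np.nan_to_num(posteriors.genotype, nan=0.0)  # (N, J, 3)
    w = np.nan_to_num(1.0 - posteriors.outlier, nan=0.0)  # (N, J)
    n, j, _ = q.shape
    flat = q.reshape(n, j * 3)
    num = flat @ flat.T
    den = w @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        agree = np.where(den > 0, num / den, np.nan)
    return agree, den


def check_snp_agreement(
    posteriors: GenotypePosteriors,
    donor_ids: Optional[pd.Series] = None,
    conflict_threshold: float = 0.90,
) -> AgreementResult:
    """Score all unordered sample pairs and list metadata conflicts.

    Conflicts are pairs sharing a donor_id scoring below the threshold
    (unexpected_disagreement) or pairs with different donor_ids scoring at
    or above it (unexpected_agreement). With no donor metadata every pair
    is treated as a distinct donor.
    """
    samples = posteriors.sample_ids
    n = len(samples)
    if n < 2:
        raise ValidationError("agreement check requires at least 2 samples")
    if donor_ids is None:
        donor_ids = pd.Series(samples, index=samples)
    donors = donor_ids.reindex(samples).to_numpy()

    agree, den = pairwise_agreement_matrix(posteriors)
    ia, ib = np.triu_indices(n, k=1)
    pairs = pd.DataFrame({
        "sample_a": np.asarray(samples)[ia],
        "sample_b": np.asarray(samples)[ib],
        "donor_a": donors[ia],
        "donor_b": donors[ib],
        "agreement": agree[ia, ib],
        "n_effective": den[ia, ib],
    })
    same_donor = pairs["donor_a"] == pairs["donor_b"]
    low = pairs["agreement"] < conflict_threshold
    conflict_type = np.where(same_donor & low, "unexpected_disagreement",
                             np.where(~same_donor & ~low, "unexpected_agreement", ""))
    conflicts = pairs[conflict_type != ""].copy()
    conflicts["conflict_type"] = conflict_type[conflict_type != ""]
    return AgreementResult(pairs=pairs, conflicts=conflicts,
                           threshold=conflict_threshold)


def write_agreement_report(result: AgreementResult, path) -> None:
    cols = ["sample_a", "sample_b", "donor_a", "donor_b", "agreement", "conflict_type"]
    result.conflicts[cols].to_csv(path, sep="\t", index=False, na_rep="")
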