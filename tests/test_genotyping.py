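"""Mixture-model genotype calling, outlier log-odds, fingerprint agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylqc.exceptions import FitError, ValidationError
from methylqc.genotyping import (
    GenotypePosteriors,
    SnpMixtureModel,
    call_genotypes,
    check_snp_agreement,
    fit_snp_mixture,
    pairwise_agreement_matrix,
    snp_outliers,
)
from methylqc.preprocess import BetaMatrix, compute_beta
from methylqc.simulate import SimulationConfig, simulate_dataset

TRUE_WEIGHTS = np.array([0.3, 0.4, 0.25, 0.05])
TRUE_PARAMS = np.array([[2.0, 38.0], [40.0, 40.0], [38.0, 2.0]])  # means .05/.5/.95


def _mixture_draws(rng, n):
    comp = rng.choice(4, size=n, p=TRUE_WEIGHTS)
    x = np.empty(n)
    for k in range(3):
        m = comp == k
        x[m] = rng.beta(*TRUE_PARAMS[k], size=m.sum())
    x[comp == 3] = rng.uniform(size=(comp == 3).sum())
    return x


def _as_beta_matrix(x, n_probes=50):
    n = len(x)
    n_samples = n // n_probes
    mat = x[: n_probes * n_samples].reshape(n_probes, n_samples)
    return BetaMatrix(pd.DataFrame(
        mat, index=pd.Index([f"rs{i:02d}" for i in range(n_probes)], name="probe_id"),
        columns=[f"s{i}" for i in range(n_samples)]))


@pytest.fixture(scope="module")
def known_mixture_fit():
    rng = np.random.default_rng(17)
    beta = _as_beta_matrix(_mixture_draws(rng, 5000))
    return beta, fit_snp_mixture(beta, seed=0)


def test_em_recovers_generating_parameters(known_mixture_fit):
    """Component means recovered within 0.02 of truth at n=5000 pooled draws."""
    _, model = known_mixture_fit
    true_means = TRUE_PARAMS[:, 0] / TRUE_PARAMS.sum(axis=1)
    assert np.abs(model.component_means() - true_means).max() < 0.02
    assert np.abs(model.weights - TRUE_WEIGHTS).max() < 0.05


def test_em_loglik_trace_monotone(known_mixture_fit):
    _, model = known_mixture_fit
    trace = np.asarray(model.loglik_trace)
    assert len(trace) >= 2
    assert (np.diff(trace) >= -1e-7).all()


def test_em_degenerate_input_rejected():
    """All-identical beta-values cannot support three separated genotypes."""
    beta = _as_beta_matrix(np.full(500, 0.5), n_probes=10)
    with pytest.raises((FitError, ValidationError)):
        fit_snp_mixture(beta, seed=0)


def test_em_beats_kmeans_on_heldout_loglik(known_mixture_fit):
    """The EM fit out-scores a k-means-style hard-assignment mixture."""
    from sklearn.cluster import KMeans

    beta, model = known_mixture_fit
    rng = np.random.default_rng(23)
    held = np.clip(_mixture_draws(rng, 2000), 1e-6, 1 - 1e-6)

    train = beta.beta.to_numpy().ravel()
    km = KMeans(n_clusters=3, n_init=5, random_state=0).fit(train.reshape(-1, 1))
    labels = km.labels_
    order = np.argsort(km.cluster_centers_.ravel())
    w, params = [], []
    for k in order:
        xs = np.clip(train[labels == k], 1e-6, 1 - 1e-6)
        m, v = xs.mean(), max(xs.var(), 1e-6)
        common = m * (1 - m) / v - 1
        params.append((m * common, (1 - m) * common))
        w.append(len(xs) / len(train))

    def mixture_ll(weights, beta_params, x):
        dens = np.zeros_like(x)
        for wk, (a, b) in zip(weights[:3], beta_params):
            dens += wk * stats.beta.pdf(x, a, b)
        if len(weights) == 4:
            dens += weights[3]
        return np.log(dens).sum()

    ll_em = mixture_ll(model.weights, model.beta_params, held)
    ll_km = mixture_ll(np.asarray(w), params, held)
    assert ll_em > ll_km


def test_posteriors_normalize_and_propagate_missing(known_mixture_fit):
    beta, model = known_mixture_fit
    b = beta.beta.copy()
    b.iloc[0, 0] = np.nan
    posts = call_genotypes(model, BetaMatrix(b))
    sums = posts.posts.sum(axis=2)
    assert np.isnan(posts.posts[0, 0]).all()
    finite = ~np.isnan(sums)
    assert np.allclose(sums[finite], 1.0, atol=1e-8)


def test_posterior_matches_bayes_rule_by_hand():
    """Posterior for a low beta under a low-mean AA component is computed by hand."""
    model = SnpMixtureModel(weights=np.array([0.3, 0.4, 0.25, 0.05]),
                            beta_params=TRUE_PARAMS)
    x = 0.02
    dens = np.array([stats.beta.pdf(x, a, b) for a, b in TRUE_PARAMS] + [1.0])
    expected = model.weights * dens / (model.weights * dens).sum()
    beta = BetaMatrix(pd.DataFrame([[x]], index=pd.Index(["rs1"], name="probe_id"),
                                   columns=["s1"]))
    posts = call_genotypes(model, beta)
    assert np.allclose(posts.posts[0, 0], expected, atol=1e-10)
    assert posts.posts[0, 0, 0] > 0.9


def test_beta_out_of_range_rejected(known_mixture_fit):
    _, model = known_mixture_fit
    # BetaMatrix itself rejects out-of-range values, so bypass it
    bad = BetaMatrix.__new__(BetaMatrix)
    bad.beta = pd.DataFrame([[1.5]], index=pd.Index(["rs1"], name="probe_id"),
                            columns=["s1"])
    with pytest.raises(ValidationError):
        call_genotypes(model, bad)


# ---------------------------------------------------------------------------
# snp_outliers


def _posts_from_array(arr):
    arr = np.asarray(arr, dtype=float)
    return GenotypePosteriors(
        posts=arr,
        sample_ids=pd.Index([f"s{i}" for i in range(arr.shape[0])]),
        probe_ids=pd.Index([f"rs{j}" for j in range(arr.shape[1])]))


def test_outlier_logodds_of_half_is_zero():
    posts = _posts_from_array(np.tile([0.2, 0.2, 0.1, 0.5], (2, 5, 1)))
    o = snp_outliers(posts)
    assert np.allclose(o.to_numpy(), 0.0)


def test_clean_cohort_outlier_logodds_below_cutoff(clean_sim):
    """Clean trimodal samples sit well below the -4 log2-odds flagging cutoff."""
    dataset, manifest, _ = clean_sim
    beta = compute_beta(dataset).restrict(manifest.snp_probes())
    model = fit_snp_mixture(beta, seed=0)
    o = snp_outliers(call_genotypes(model, beta))
    assert (o < -4).all()


# ---------------------------------------------------------------------------
# agreement


def _hard_posts(genotypes, outlier=None):
    """One-hot genotype posteriors; genotypes is (samples x probes) in {0,1,2}."""
    g = np.asarray(genotypes)
    posts = np.zeros((*g.shape, 4))
    for k in range(3):
        posts[..., k] = (g == k)
    if outlier is not None:
        posts = posts * (1 - np.asarray(outlier)[..., None])
        posts[..., 3] = outlier
    return _posts_from_array(posts)


def test_duplicate_pair_agreement_is_one():
    g = np.array([[0, 1, 2, 1, 0]])
    posts = _hard_posts(np.vstack([g, g]))
    res = check_snp_agreement(posts)
    assert res.pairs["agreement"].iloc[0] == pytest.approx(1.0)


def test_opposite_homozygotes_agreement_is_zero():
    posts = _hard_posts(np.array([[0, 0, 0, 0], [2, 2, 2, 2]]))
    res = check_snp_agreement(posts)
    assert res.pairs["agreement"].iloc[0] == pytest.approx(0.0)


def test_agreement_symmetric_and_bounded(clean_sim):
    dataset, manifest, _ = clean_sim
    beta = compute_beta(dataset).restrict(manifest.snp_probes())
    model = fit_snp_mixture(beta, seed=0)
    posts = call_genotypes(model, beta)
    agree, den = pairwise_agreement_matrix(posts)
    assert np.allclose(agree, agree.T)
    assert np.nanmin(agree) >= 0 and np.nanmax(agree) <= 1 + 1e-9
    # diagonal: self agreement ~1 (tiny outlier mass only)
    assert np.nanmin(np.diag(agree)) > 0.95


def test_partial_outlier_mass_softly_excludes_probe():
    """Outlier mass at one probe shrinks its weight in numerator and denominator."""
    g = np.array([[0, 1], [0, 1]])
    full = check_snp_agreement(_hard_posts(g)).pairs["agreement"].iloc[0]
    out = np.array([[0.5, 0.0], [0.5, 0.0]])
    partial = check_snp_agreement(_hard_posts(g, out)).pairs
    # both probes agree, so agreement stays 1 but effective count drops
    assert full == pytest.approx(1.0)
    assert partial["agreement"].iloc[0] == pytest.approx(1.0)
    assert partial["n_effective"].iloc[0] == pytest.approx(1.25)  # 0.25 + 1.0


def test_pair_count_is_n_choose_2():
    posts = _hard_posts(np.zeros((5, 4), dtype=int))
    res = check_snp_agreement(posts)
    assert len(res.pairs) == 10


def hwe_expected_agreement(p):
    """Brute-force enumeration of P(two unrelated donors share a genotype)."""
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    total = 0.0
    for ga, pa in enumerate(probs):
        for gb, pb in enumerate(probs):
            if ga == gb:
                total += pa * pb
    return total


def test_unrelated_agreement_matches_hwe_enumeration():
    """Mean unrelated-pair agreement approximates the HWE collision probability."""
    rng = np.random.default_rng(31)
    p = 0.5
    g = rng.choice(3, size=(300, 65), p=[(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    agree, _ = pairwise_agreement_matrix(_hard_posts(g))
    iu = np.triu_indices(300, k=1)
    assert np.mean(agree[iu]) == pytest.approx(hwe_expected_agreement(p), abs=0.01)


def test_conflicts_against_donor_metadata():
    """Same-donor disagreement and different-donor agreement are both reported."""
    g = np.array([
        [0, 1, 2, 1, 0, 2],   # s0 (donor A)
        [0, 1, 2, 1, 0, 2],   # s1 duplicate of s0, but labeled donor B
        [2, 0, 1, 0, 2, 1],   # s2 labeled donor A but different person
    ])
    posts = _hard_posts(g)
    donors = pd.Series(["A", "B", "A"], index=posts.sample_ids)
    res = check_snp_agreement(posts, donors, conflict_threshold=0.9)
    kinds = dict(zip(zip(res.conflicts["sample_a"], res.conflicts["sample_b"]),
                     res.conflicts["conflict_type"]))
    assert kinds[("s0", "s1")] == "unexpected_agreement"
    assert kinds[("s0", "s2")] == "unexpected_disagreement"


def test_replicates_in_cohort_are_recovered():
    """Technical replicates score near 1 and are separable from unrelated pairs."""
    cfg = SimulationConfig(n_samples=30, n_replicates=5, seed=41)
    ds, manifest, truth = simulate_dataset(cfg)
    beta = compute_beta(ds).restrict(manifest.snp_probes())
    model = fit_snp_mixture(beta, seed=0)
    posts = call_genotypes(model, beta)
    res = check_snp_agreement(posts, ds.samples["donor_id"])
    same = res.pairs["donor_a"] == res.pairs["donor_b"]
    assert res.pairs.loc[same, "agreement"].min() >= 0.95
    assert res.pairs.loc[~same, "agreement"].max() <= 0.7
    assert len(res.conflicts) == 0
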