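"""Beta computation, dye-bias correction and detection p-values."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylqc.exceptions import ValidationError
from methylqc.preprocess import (
    compute_beta,
    correct_dye_bias,
    detection_pvalues,
    dye_bias_pairs,
    undetected_fraction,
)
from methylqc.simulate import SimulationConfig, simulate_dataset

from conftest import make_dataset, tiny_manifest


@pytest.mark.parametrize("u, m, expected", [
    (500.0, 500.0, 0.5),
    (1000.0, 0.0, 0.0),
    (0.0, 1000.0, 1.0),
    (0.0, 0.0, np.nan),
    (np.nan, 100.0, np.nan),
])
def test_beta_definition(u, m, expected):
    """beta = M/(M+U); zero denominator or missing input yields missing."""
    ds = make_dataset([[u]], [[m]], ["cg01"], ["s1"])
    b = compute_beta(ds).beta.iloc[0, 0]
    if np.isnan(expected):
        assert np.isnan(b)
    else:
        assert b == pytest.approx(expected)


@given(scale=st.floats(1e-3, 1e6), u=st.floats(0, 1e5), m=st.floats(1e-9, 1e5))
@settings(max_examples=50, derandomize=True)
def test_beta_scale_invariance(scale, u, m):
    """A common positive rescaling of (U, M) leaves beta unchanged."""
    a = compute_beta(make_dataset([[u]], [[m]], ["cg01"], ["s1"])).beta.iloc[0, 0]
    b = compute_beta(make_dataset([[u * scale]], [[m * scale]],
                                  ["cg01"], ["s1"])).beta.iloc[0, 0]
    assert b == pytest.approx(a, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# dye bias


def _dye_fixture(red_factor=1.0, n_samples=3, seed=0):
    """Simulated cohort with every red-channel intensity scaled by red_factor."""
    cfg = SimulationConfig(n_samples=n_samples, n_autosomal_probes=50,
                           n_x_probes=10, n_y_probes=5, n_snp_probes=10,
                           intensity_noise_sd=0.02, seed=seed)
    ds, manifest, _ = simulate_dataset(cfg)
    if red_factor != 1.0:
        from methylqc.preprocess import _red_probe_mask
        u_red, m_red = _red_probe_mask(manifest, ds.U.index)
        biased_U = ds.U.copy()
        biased_M = ds.M.copy()
        biased_U.iloc[u_red, :] *= red_factor
        biased_M.iloc[m_red, :] *= red_factor
        from methylqc.io import MethylationDataset
        ds = MethylationDataset(U=biased_U, M=biased_M,
                                controls_grn=ds.controls_grn,
                                controls_red=ds.controls_red * red_factor,
                                samples=ds.samples, manifest=manifest)
    return ds, manifest


def test_dye_bias_identity_when_channels_match():
    """If paired control intensities already agree, correction is a no-op."""
    ds, _ = _dye_fixture()
    pairs = dye_bias_pairs(ds)
    assert len(pairs) >= 3
    # force exact channel agreement on the pairs
    for g, r in pairs:
        ds.controls_red.loc[r] = ds.controls_grn.loc[g].to_numpy()
    out = correct_dye_bias(ds)
    assert np.allclose(out.U.to_numpy(), ds.U.to_numpy(), rtol=1e-6)
    assert np.allclose(out.M.to_numpy(), ds.M.to_numpy(), rtol=1e-6)


def test_dye_bias_recovers_injected_red_scaling():
    """A 2x multiplicative red bias is removed to within 5% on regular probes."""
    truth, manifest = _dye_fixture(red_factor=1.0, seed=3)
    biased, _ = _dye_fixture(red_factor=2.0, seed=3)
    corrected = correct_dye_bias(biased)
    from methylqc.preprocess import _red_probe_mask
    u_red, m_red = _red_probe_mask(manifest, truth.U.index)
    tu, cu = truth.U.to_numpy()[u_red], corrected.U.to_numpy()[u_red]
    tm, cm = truth.M.to_numpy()[m_red], corrected.M.to_numpy()[m_red]
    ratio_u = cu[tu > 1] / tu[tu > 1]
    ratio_m = cm[tm > 1] / tm[tm > 1]
    assert np.nanmedian(np.abs(ratio_u - 1)) < 0.05
    assert np.nanmedian(np.abs(ratio_m - 1)) < 0.05
    assert not corrected.samples["dye_bias_skipped"].any()


def test_dye_bias_preserves_intensity_ranks():
    """The per-sample red-channel map is monotone, so ranks are preserved."""
    ds, manifest = _dye_fixture(red_factor=2.0, seed=7)
    out = correct_dye_bias(ds)
    from methylqc.preprocess import _red_probe_mask
    u_red, _ = _red_probe_mask(manifest, ds.U.index)
    for s in range(ds.n_samples):
        before = ds.U.to_numpy()[u_red, s]
        after = out.U.to_numpy()[u_red, s]
        assert (np.argsort(before) == np.argsort(after)).all()


def test_dye_bias_skips_samples_without_pairs():
    ds = make_dataset([[100.0]], [[100.0]], ["cg01"], ["s1"],
                      manifest=tiny_manifest())
    out = correct_dye_bias(ds)
    assert out.samples["dye_bias_skipped"].all()
    assert np.allclose(out.U.to_numpy(), ds.U.to_numpy())


# ---------------------------------------------------------------------------
# detection p-values


def _detection_fixture():
    rng = np.random.default_rng(2)
    n_neg = 60
    probe_ids = ["cg_strong", "cg_mid"]
    t = pd.DataFrame({
        "probe_id": probe_ids + [f"ctl_negative_{i}" for i in range(n_neg)],
        "chromosome": "1",
        "probe_class": ["cpg"] * 2 + ["control"] * n_neg,
        "control_category": [None] * 2 + ["negative"] * n_neg,
        "channel_design": "typeII",
    }).set_index("probe_id")
    from methylqc.io import Manifest
    manifest = Manifest(t)
    neg = rng.normal(100, 10, size=(n_neg, 1)).clip(1)
    cidx = pd.Index(list(t.index[2:]), name="probe_id")
    controls = pd.DataFrame(neg, index=cidx, columns=["s1"])
    # strong probe far above background; mid probe exactly at the background mean
    mid_total = float(neg.mean() * 2)  # typeII background = grn mean + red mean
    U = [[neg.max() * 10], [mid_total / 2]]
    M = [[neg.max() * 10], [mid_total / 2]]
    ds = make_dataset(U, M, probe_ids, ["s1"], manifest=manifest,
                      controls_grn=controls, controls_red=controls.copy())
    return ds


def test_detection_pvalue_tails():
    """Far-above-background probes are detected; background-level ones are not."""
    ds = _detection_fixture()
    p = detection_pvalues(ds)
    assert p.loc["cg_strong", "s1"] < 0.01
    assert p.loc["cg_mid", "s1"] == pytest.approx(0.5, abs=0.05)


def test_detection_pvalues_monotone_in_total():
    """p-values lie in [0,1] and never increase with total intensity."""
    ds, _ = _dye_fixture(seed=9)
    p = detection_pvalues(ds).to_numpy()
    total = ds.total_intensity().to_numpy()
    assert np.nanmin(p) >= 0 and np.nanmax(p) <= 1
    for s in range(ds.n_samples):
        order = np.argsort(total[:, s])
        assert (np.diff(p[order, s]) <= 1e-12).all()


def test_detection_requires_negative_controls():
    ds = make_dataset([[100.0]], [[100.0]], ["cg01"], ["s1"],
                      manifest=tiny_manifest())
    # tiny_manifest has a negative control but the dataset carries none
    with pytest.raises(ValidationError, match="negative"):
        detection_pvalues(ds)


def test_suppressed_sample_exceeds_one_percent_rule():
    """A sample whose signal collapses to background fails the >1% criterion."""
    cfg = SimulationConfig(n_samples=10, detection_failures=[4], seed=21)
    ds, _, _ = simulate_dataset(cfg)
    frac = undetected_fraction(detection_pvalues(ds))
    assert frac.iloc[4] > 0.01
    ok = frac.drop(frac.index[4])
    assert (ok <= 0.01).all()
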