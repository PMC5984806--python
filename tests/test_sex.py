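"""Sex inference: normalized allosomal intensities, robust cutoffs, quadrant calls."""

import numpy as np
import pandas as pd
import pytest

from methylqc.exceptions import ValidationError
from methylqc.sex import (
    check_sex,
    hodges_lehmann_cutoff,
    normalized_chr_intensities,
    predict_sex,
)
from methylqc.simulate import SimulationConfig, simulate_dataset

from conftest import make_dataset


def _allosome_manifest(n_auto=4, n_x=3, n_y=2):
    from methylqc.io import Manifest
    ids = ([f"cgA{i}" for i in range(n_auto)] + [f"cgX{i}" for i in range(n_x)]
           + [f"cgY{i}" for i in range(n_y)])
    chrom = ["1"] * n_auto + ["X"] * n_x + ["Y"] * n_y
    return Manifest(pd.DataFrame({
        "probe_id": ids, "chromosome": chrom, "probe_class": "cpg",
        "control_category": None, "channel_design": "typeII",
    }).set_index("probe_id")), ids


def test_equal_intensities_normalize_to_one():
    manifest, ids = _allosome_manifest()
    U = np.full((len(ids), 1), 500.0)
    ds = make_dataset(U, U, ids, ["s1"], manifest=manifest)
    norm = normalized_chr_intensities(ds)
    assert norm["tX_norm"].iloc[0] == pytest.approx(1.0)
    assert norm["tY_norm"].iloc[0] == pytest.approx(1.0)


def test_global_rescaling_leaves_ratios_unchanged():
    manifest, ids = _allosome_manifest()
    rng = np.random.default_rng(3)
    U = rng.uniform(100, 1000, size=(len(ids), 1))
    M = rng.uniform(100, 1000, size=(len(ids), 1))
    a = normalized_chr_intensities(make_dataset(U, M, ids, ["s1"], manifest=manifest))
    b = normalized_chr_intensities(make_dataset(2 * U, 2 * M, ids, ["s1"],
                                                manifest=manifest))
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_female_y_probes_at_background_level():
    """Y probes at a tenth of the autosomal level give tY_norm of about 0.1."""
    manifest, ids = _allosome_manifest()
    total = np.array([1000.0] * 7 + [100.0] * 2)  # autosomes+X at 1000, Y at 100
    U = (total / 2)[:, None]
    ds = make_dataset(U, U, ids, ["s1"], manifest=manifest)
    norm = normalized_chr_intensities(ds)
    assert norm["tY_norm"].iloc[0] == pytest.approx(0.1)
    assert norm["tX_norm"].iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Hodges-Lehmann cutoff


def hl_oracle(males, females):
    """Brute-force median of all pairwise (male, female) averages."""
    pairs = [(m + f) / 2.0 for m in males for f in females]
    return float(np.median(pairs))


def _series(values, sexes):
    idx = pd.Index([f"s{i}" for i in range(len(values))])
    return pd.Series(values, index=idx), pd.Series(sexes, index=idx)


def test_single_pair_midpoint():
    v, s = _series([2.0, 4.0], ["male", "female"])
    assert hodges_lehmann_cutoff(v, s) == pytest.approx(3.0)


def test_small_cohort_enumeration():
    """males {1,2} x females {5,7}: median of {3, 3.5, 4, 4.5} = 3.75."""
    v, s = _series([1.0, 2.0, 5.0, 7.0], ["male", "male", "female", "female"])
    assert hodges_lehmann_cutoff(v, s) == pytest.approx(3.75)


def test_matches_bruteforce_oracle_on_random_cohort():
    rng = np.random.default_rng(9)
    n = 150
    sexes = np.where(rng.uniform(size=n) < 0.5, "male", "female")
    vals = np.where(sexes == "male", rng.normal(2, 0.3, n), rng.normal(5, 0.4, n))
    v, s = _series(vals, sexes)
    males = vals[sexes == "male"]
    females = vals[sexes == "female"]
    assert hodges_lehmann_cutoff(v, s) == hl_oracle(males, females)


def test_empty_sex_class_raises():
    v, s = _series([1.0, 2.0], ["male", "male"])
    with pytest.raises(ValidationError, match="manually"):
        hodges_lehmann_cutoff(v, s)


def test_cutoff_robust_to_minority_label_swaps():
    """Swapping up to 40% of one class's labels keeps the cutoff separating."""
    rng = np.random.default_rng(15)
    n = 100
    sexes = np.array(["male"] * 50 + ["female"] * 50)
    vals = np.where(sexes == "male", rng.normal(1, 0.05, n), rng.normal(3, 0.05, n))
    v, s = _series(vals, sexes)
    clean = hodges_lehmann_cutoff(v, s)
    swapped = sexes.copy()
    swapped[:20] = "female"  # 40% of males relabeled
    _, s2 = _series(vals, swapped)
    corrupted = hodges_lehmann_cutoff(v, s2)
    lo, hi = vals[sexes == "male"].max(), vals[sexes == "female"].min()
    assert lo < clean < hi
    assert lo < corrupted < hi


# ---------------------------------------------------------------------------
# prediction


@pytest.mark.parametrize("tx, ty, expected", [
    (0.5, 0.8, "male"),      # low X, high Y
    (1.0, 0.1, "female"),    # high X, low Y
    (1.0, 0.8, "unclear"),   # upper right: XXY-compatible
    (0.5, 0.1, "unclear"),   # lower left
    (0.75, 0.8, "unclear"),  # tie on the X cutoff is conservative
])
def test_quadrant_calls(tx, ty, expected):
    idx = pd.Index(["s1"])
    res = predict_sex(pd.Series([tx], index=idx), pd.Series([ty], index=idx),
                      cutoff_x=0.75, cutoff_y=0.45,
                      recorded_sex=pd.Series(["female"], index=idx))
    assert res.table["predicted_sex"].iloc[0] == expected
    if expected == "female":
        assert not res.table["mismatch"].iloc[0]
    if expected == "unclear":
        assert not res.table["mismatch"].iloc[0]


def test_recorded_female_in_female_quadrant_is_ok():
    idx = pd.Index(["s1"])
    res = predict_sex(pd.Series([1.0], index=idx), pd.Series([0.1], index=idx),
                      0.75, 0.45, pd.Series(["female"], index=idx))
    assert res.table["status"].iloc[0] == "ok"


def test_cross_sex_swaps_detected_exactly(clean_sim):
    """Known label swaps are flagged as mismatches with no false positives."""
    swaps = [2, 9, 17]
    cfg = SimulationConfig(n_samples=60, sex_swaps=swaps, seed=19)
    ds, _, truth = simulate_dataset(cfg)
    res = check_sex(ds)
    flagged = set(res.table.index[res.table["status"] == "mismatch"])
    assert flagged == {f"s{i:04d}" for i in swaps}
    assert (res.table["status"] == "unclear").sum() == 0
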