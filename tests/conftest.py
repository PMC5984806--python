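"""Shared fixtures: small simulated cohorts and hand-built fixtures."""

import numpy as np
import pandas as pd
import pytest

from methylqc.io import Manifest, MethylationDataset
from methylqc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_sim():
    """A clean 40-sample cohort: no failures, no contamination, no mislabels."""
    cfg = SimulationConfig(n_samples=40, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset(clean_sim):
    return clean_sim[0]


@pytest.fixture(scope="session")
def clean_manifest(clean_sim):
    return clean_sim[1]


def tiny_manifest():
    """Three CpG probes plus one negative control, hand-built."""
    t = pd.DataFrame({
        "probe_id": ["cg01", "cg02", "cg03", "ctl_negative_1"],
        "chromosome": ["1", "2", "X", "1"],
        "probe_class": ["cpg", "cpg", "cpg", "control"],
        "control_category": [None, None, None, "negative"],
        "channel_design": ["typeII", "typeI_green", "typeI_red", "typeII"],
    }).set_index("probe_id")
    return Manifest(t)


def make_dataset(U, M, probe_ids, sample_ids, manifest=None,
                 controls_grn=None, controls_red=None, samples=None):
    """Assemble a MethylationDataset from raw arrays."""
    idx = pd.Index(probe_ids, name="probe_id")
    U = pd.DataFrame(np.asarray(U, dtype=float), index=idx, columns=sample_ids)
    M = pd.DataFrame(np.asarray(M, dtype=float), index=idx, columns=sample_ids)
    if controls_grn is None:
        cidx = pd.Index([], name="probe_id")
        controls_grn = pd.DataFrame(index=cidx, columns=sample_ids, dtype=float)
        controls_red = controls_grn.copy()
    if samples is None:
        samples = pd.DataFrame(
            {"donor_id": sample_ids, "recorded_sex": "unknown"},
            index=pd.Index(sample_ids, name="sample_id"))
    return MethylationDataset(U=U, M=M, controls_grn=controls_grn,
                              controls_red=controls_red, samples=samples,
                              manifest=manifest)
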