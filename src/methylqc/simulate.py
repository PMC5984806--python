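"""Synthetic methylation-array cohorts with known ground truth.

Every QC check in the package is testable without real data: the generator
emits a full :class:`~methylqc.io.MethylationDataset` (U/M intensities,
two-channel control probes, sample metadata), a matching manifest, and a
truth table recording every latent variable it drew. It emulates:

* trimodal SNP-probe beta distributions under Hardy-Weinberg genotypes,
  with Beta-distributed noise around genotype means;
* sex-dependent allosomal intensity levels (two X doses and no Y for
  females, one X and one Y for males; the female Y level is residual
  background);
* control-probe signal/background structure matching the default control
  policy, with injectable per-category failures;
* single-source DNA contamination: SNP beta-values move convexly toward
  the source's expected beta by the per-sample degree gamma, and (for a
  male source in a female host) the Y-probe dose rises with gamma —
  mirroring both signals the contamination checks exploit;
* mislabeling designs: recorded-sex swaps and donor-id swaps, plus
  technical replicates sharing a donor's genotype.

The same seed always yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import Manifest, MethylationDataset

__all__ = ["SimulationConfig", "TruthTable", "simulate_dataset"]

# Control probe layout: (probe_id, category, grn level, red level,
# failed grn level, failed red level); levels are fractions of
# intensity_scale, None = unchanged under failure. The identifiers match
# the regex groups of the default control policy.
_SIG, _MED, _LOW, _BKG, _HALF_BKG, _NEG = 0.6, 0.3, 0.15, 0.03, 0.015, 0.02
CONTROL_LAYOUT = [
    ("ctl_restoration_1", "restoration", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_staining_biotin_high", "staining", _MED, _BKG, _HALF_BKG, None),
    ("ctl_staining_biotin_bkg", "staining", _BKG, _BKG, None, None),
    ("ctl_staining_dnp_high", "staining", _BKG, _MED, None, _HALF_BKG),
    ("ctl_staining_dnp_bkg", "staining", _BKG, _BKG, None, None),
    ("ctl_extension_a", "extension", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_extension_t", "extension", _BKG, _LOW, None, _HALF_BKG),
    ("ctl_extension_c", "extension", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_extension_g", "extension", _LOW, _BKG, _HALF_BKG, None),
    ("ctl_hyb_high", "hybridization", _SIG, _BKG, _BKG, None),
    ("ctl_hyb_medium", "hybridization", _MED, _BKG, None, None),
    ("ctl_hyb_low", "hybridization", _LOW, _BKG, None, None),
    ("ctl_target_removal_1", "target_removal", _HALF_BKG, _BKG, _SIG, None),
    ("ctl_target_removal_2", "target_removal", _HALF_BKG, _BKG, _SIG, None),
    ("ctl_bc1_c1", "bisulfite_conversion_I", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_bc1_c2", "bisulfite_conversion_I", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_bc1_c3", "bisulfite_conversion_I", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_bc1_u1", "bisulfite_conversion_I", _BKG, _BKG, None, None),
    ("ctl_bc1_u2", "bisulfite_conversion_I", _BKG, _BKG, None, None),
    ("ctl_bc1_u3", "bisulfite_conversion_I", _BKG, _BKG, None, None),
    ("ctl_bc1_c4", "bisulfite_conversion_I", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_bc1_c5", "bisulfite_conversion_I", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_bc1_c6", "bisulfite_conversion_I", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_bc1_u4", "bisulfite_conversion_I", _BKG, _BKG, None, None),
    ("ctl_bc1_u5", "bisulfite_conversion_I", _BKG, _BKG, None, None),
    ("ctl_bc1_u6", "bisulfite_conversion_I", _BKG, _BKG, None, None),
    ("ctl_bc2_1", "bisulfite_conversion_II", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_bc2_2", "bisulfite_conversion_II", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_bc2_3", "bisulfite_conversion_II", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_bc2_4", "bisulfite_conversion_II", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_spec1_pm_g1", "specificity_I", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_spec1_pm_g2", "specificity_I", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_spec1_pm_g3", "specificity_I", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_spec1_mm_g1", "specificity_I", _BKG, _BKG, None, None),
    ("ctl_spec1_mm_g2", "specificity_I", _BKG, _BKG, None, None),
    ("ctl_spec1_mm_g3", "specificity_I", _BKG, _BKG, None, None),
    ("ctl_spec1_pm_r1", "specificity_I", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_spec1_pm_r2", "specificity_I", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_spec1_pm_r3", "specificity_I", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_spec1_mm_r1", "specificity_I", _BKG, _BKG, None, None),
    ("ctl_spec1_mm_r2", "specificity_I", _BKG, _BKG, None, None),
    ("ctl_spec1_mm_r3", "specificity_I", _BKG, _BKG, None, None),
    ("ctl_spec2_1", "specificity_II", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_spec2_2", "specificity_II", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_spec2_3", "specificity_II", _BKG, _SIG, None, _HALF_BKG),
    # graded two-channel normalization pairs (extension category) anchoring
    # the dye-bias regression across the intensity range; not referenced by
    # any metric's probe patterns
    ("ctl_extension_pair_g1", "extension", 0.60, _BKG, None, None),
    ("ctl_extension_pair_g2", "extension", 0.45, _BKG, None, None),
    ("ctl_extension_pair_g3", "extension", 0.30, _BKG, None, None),
    ("ctl_extension_pair_g4", "extension", 0.15, _BKG, None, None),
    ("ctl_extension_pair_g5", "extension", 0.08, _BKG, None, None),
    ("ctl_extension_pair_g6", "extension", 0.065, _BKG, None, None),
    ("ctl_extension_pair_r1", "extension", _BKG, 0.60, None, None),
    ("ctl_extension_pair_r2", "extension", _BKG, 0.45, None, None),
    ("ctl_extension_pair_r3", "extension", _BKG, 0.30, None, None),
    ("ctl_extension_pair_r4", "extension", _BKG, 0.15, None, None),
    ("ctl_extension_pair_r5", "extension", _BKG, 0.08, None, None),
    ("ctl_extension_pair_r6", "extension", _BKG, 0.065, None, None),
    ("ctl_np_a", "non_polymorphic", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_np_t", "non_polymorphic", _BKG, _SIG, None, _HALF_BKG),
    ("ctl_np_c", "non_polymorphic", _SIG, _BKG, _HALF_BKG, None),
    ("ctl_np_g", "non_polymorphic", _SIG, _BKG, _HALF_BKG, None),
]


@dataclass
class SimulationConfig:
    """Fully determines a synthetic cohort given its seed.

    ``n_replicates`` appends technical replicates of the first donors;
    ``contamination_gamma`` (length = total sample count, including
    replicates) mixes SNP beta-values toward one foreign source;
    ``control_failures`` maps a control category to the sample indices
    whose probes of that category emit failure-level signal;
    ``sex_swaps``/``donor_swaps`` corrupt only the recorded metadata,
    leaving the underlying biology intact.
    """

    n_samples: int = 100
    n_autosomal_probes: int = 300
    n_x_probes: int = 60
    n_y_probes: int = 30
    n_snp_probes: int = 65
    n_negative_controls: int = 40
    allele_frequencies: float | Sequence[float] = 0.5
    female_fraction: float = 0.5
    genotype_means: Tuple[float, float, float] = (0.05, 0.5, 0.95)
    genotype_beta_sd: float = 0.05
    intensity_scale: float = 5000.0
    intensity_noise_sd: float = 0.1
    cpg_noise_sd: float = 0.02
    x_dose: Dict[str, float] = field(default_factory=lambda: {"female": 1.0, "male": 0.5})
    y_dose: Dict[str, float] = field(default_factory=lambda: {"male": 0.8, "female": 0.1})
    contamination_gamma: Optional[Sequence[float]] = None
    contamination_source_sex: str = "male"
    control_failures: Dict[str, Sequence[int]] = field(default_factory=dict)
    detection_failures: Sequence[int] = ()
    sex_swaps: Sequence[int] = ()
    donor_swaps: Sequence[Tuple[int, int]] = ()
    n_replicates: int = 0
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_samples + self.n_replicates

    def validate(self) -> None:
        counts = (self.n_samples, self.n_autosomal_probes, self.n_x_probes,
                  self.n_y_probes, self.n_snp_probes, self.n_negative_controls)
        if any(int(v) <= 0 for v in counts):
            raise ValidationError("all sample/probe counts must be positive")
        p = np.atleast_1d(np.asarray(self.allele_frequencies, dtype=float))
        if p.size not in (1, self.n_snp_probes):
            raise ValidationError("allele_frequencies must be scalar or one per SNP probe")
        if ((p < 0) | (p > 1)).any() or not 0 <= self.female_fraction <= 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.n_replicates > self.n_samples or self.n_replicates < 0:
            raise ValidationError("n_replicates must lie in [0, n_samples]")
        if self.contamination_gamma is not None:
            g = np.asarray(self.contamination_gamma, dtype=float)
            if g.shape != (self.n_total,):
                raise ValidationError(
                    f"contamination_gamma must have length {self.n_total}")
            if ((g < 0) | (g >= 1)).any():
                raise ValidationError("contamination_gamma must lie in [0, 1)")
        for idx in (*self.detection_failures, *self.sex_swaps):
            if not 0 <= int(idx) < self.n_total:
                raise ValidationError(f"sample index {idx} out of range")
        for cat, idxs in self.control_failures.items():
            if cat not in {c for _, c, *_ in CONTROL_LAYOUT}:
                raise ValidationError(f"unknown control category '{cat}' in failures")
            for idx in idxs:
                if not 0 <= int(idx) < self.n_total:
                    raise ValidationError(f"sample index {idx} out of range")
        if self.contamination_source_sex not in ("male", "female"):
            raise ValidationError("contamination_source_sex must be male or female")


@dataclass
class TruthTable:
    """Every latent variable drawn by the generator.

    ``samples`` has one row per sample (true/recorded sex and donor, gamma,
    injected failures, replicate provenance); ``genotypes`` is the
    (sample x SNP) B-allele count matrix, ``source_genotypes`` the foreign
    source's, and ``c`` its expected beta per SNP.
    """

    samples: pd.DataFrame
    genotypes: np.ndarray
    source_genotypes: np.ndarray
    c: np.ndarray
    allele_frequencies: np.ndarray

    def to_tsv(self, path) -> None:
        self.samples.reset_index(names="sample_id").to_csv(
            path, sep="\t", index=False, na_rep="")


def _beta_noise(rng, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta-distributed draws with the given mean and (approximate) sd."""
    m = np.clip(mean, 1e-3, 1 - 1e-3)
    nu = np.maximum(m * (1 - m) / sd ** 2 - 1, 0.5)
    return rng.beta(m * nu, (1 - m) * nu)


def _hwe_genotypes(rng, p: np.ndarray, size) -> np.ndarray:
    """(size x len(p)) B-allele counts (0/1/2) under Hardy-Weinberg at frequency p."""
    probs = np.cumsum(np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1), axis=-1)
    u = rng.uniform(size=(*size, len(p), 1))
    return (u > probs[None, :, :]).sum(axis=-1)


def simulate_dataset(config: SimulationConfig) -> Tuple[MethylationDataset, Manifest, TruthTable]:
    """Draw one synthetic cohort; identical seeds yield identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    j = config.n_snp_probes
    means = np.asarray(config.genotype_means, dtype=float)
    scale = config.intensity_scale

    # --- donors, sexes, replicates ----------------------------------------
    sample_ids = [f"s{i:04d}" for i in range(n)]
    donor_ids = np.array([f"d{i:04d}" for i in range(config.n_samples)]
                         + [f"d{i:04d}" for i in range(config.n_replicates)])
    replicate_of = np.array([""] * config.n_samples
                            + [f"s{i:04d}" for i in range(config.n_replicates)])
    base = np.concatenate([np.arange(config.n_samples), np.arange(config.n_replicates)])

    sex_base = np.where(rng.uniform(size=config.n_samples) < config.female_fraction,
                        "female", "male")
    true_sex = sex_base[base]
    recorded_sex = true_sex.copy()
    for idx in config.sex_swaps:
        recorded_sex[idx] = "female" if true_sex[idx] == "male" else "male"
    recorded_donor = donor_ids.copy()
    for a, b in config.donor_swaps:
        recorded_donor[[a, b]] = recorded_donor[[b, a]]

    # --- SNP genotypes and contamination ----------------------------------
    p = np.broadcast_to(np.atleast_1d(np.asarray(config.allele_frequencies, dtype=float)),
                        (j,)).copy()
    geno_base = _hwe_genotypes(rng, p, (config.n_samples,))
    genotypes = geno_base[base]
    source_geno = _hwe_genotypes(rng, p, (1,))[0]
    c = means[source_geno]
    gamma = (np.zeros(n) if config.contamination_gamma is None
             else np.asarray(config.contamination_gamma, dtype=float))

    beta_clean = _beta_noise(rng, means[genotypes], config.genotype_beta_sd)
    beta_snp = (1 - gamma[:, None]) * beta_clean + gamma[:, None] * c[None, :]

    # --- manifest ----------------------------------------------------------
    rows = []
    autosomes = [str(i % 22 + 1) for i in range(config.n_autosomal_probes)]
    for i in range(config.n_autosomal_probes):
        design = ("typeI_green" if i % 10 == 0
                  else "typeI_red" if i % 10 == 1 else "typeII")
        rows.append((f"cg{i:06d}", autosomes[i], "cpg", None, design))
    for i in range(config.n_x_probes):
        rows.append((f"cgX{i:05d}", "X", "cpg", None, "typeII"))
    for i in range(config.n_y_probes):
        rows.append((f"cgY{i:05d}", "Y", "cpg", None, "typeII"))
    for i in range(j):
        rows.append((f"rs{i:04d}", str(i % 22 + 1), "snp", None, "typeII"))
    layout = list(CONTROL_LAYOUT) + [
        (f"ctl_negative_{i + 1}", "negative", _NEG, _NEG, None, None)
        for i in range(config.n_negative_controls)
    ]
    for probe_id, category, *_ in layout:
        rows.append((probe_id, "1", "control", category, "typeII"))
    manifest = Manifest(pd.DataFrame(
        rows, columns=["probe_id", "chromosome", "probe_class",
                       "control_category", "channel_design"],
    ).set_index("probe_id"))

    # --- methylation probes: beta and dose --------------------------------
    n_cpg = config.n_autosomal_probes + config.n_x_probes + config.n_y_probes
    baseline = rng.beta(0.4, 0.4, size=n_cpg)
    beta_cpg = np.clip(baseline[:, None]
                       + rng.normal(0, config.cpg_noise_sd, size=(n_cpg, n)), 0, 1)

    dose = np.ones((n_cpg + j, n))
    is_female = true_sex == "female"
    x_dose = np.where(is_female, config.x_dose["female"], config.x_dose["male"])
    y_dose = np.where(is_female, config.y_dose["female"], config.y_dose["male"])
    if config.contamination_source_sex == "male":
        # a male source adds Y material to female hosts and dilutes their X
        x_src, y_src = config.x_dose["male"], config.y_dose["male"]
    else:
        x_src, y_src = config.x_dose["female"], config.y_dose["female"]
    x_dose = (1 - gamma) * x_dose + gamma * x_src
    y_dose = (1 - gamma) * y_dose + gamma * y_src
    sl_x = slice(config.n_autosomal_probes, config.n_autosomal_probes + config.n_x_probes)
    sl_y = slice(sl_x.stop, sl_x.stop + config.n_y_probes)
    dose[sl_x] = x_dose[None, :]
    dose[sl_y] = y_dose[None, :]

    beta_all = np.vstack([beta_cpg, beta_snp.T])
    total = scale * dose * rng.lognormal(0.0, config.intensity_noise_sd,
                                         size=dose.shape)
    for idx in config.detection_failures:
        # signal suppressed to background: totals near the negative-control level
        total[:n_cpg, idx] = 2 * _NEG * scale * rng.lognormal(
            0.0, 0.3, size=n_cpg)
    M = beta_all * total
    U = (1 - beta_all) * total

    probe_ids = [r[0] for r in rows[:n_cpg + j]]
    U = pd.DataFrame(U, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    M = pd.DataFrame(M, index=U.index, columns=sample_ids)

    # --- control probes -----------------------------------------------------
    ctl_ids = [r[0] for r in layout]
    grn = np.empty((len(layout), n))
    red = np.empty((len(layout), n))
    failed_by: Dict[int, list] = {i: [] for i in range(n)}
    for row_i, (probe_id, category, g_lvl, r_lvl, g_fail, r_fail) in enumerate(layout):
        g = np.full(n, g_lvl)
        r = np.full(n, r_lvl)
        for idx in config.control_failures.get(category, ()):
            if g_fail is not None:
                g[idx] = g_fail
            if r_fail is not None:
                r[idx] = r_fail
            failed_by[idx].append(category)
        grn[row_i] = scale * g * rng.lognormal(0, config.intensity_noise_sd, n)
        red[row_i] = scale * r * rng.lognormal(0, config.intensity_noise_sd, n)
    controls_grn = pd.DataFrame(grn, index=pd.Index(ctl_ids, name="probe_id"),
                                columns=sample_ids)
    controls_red = pd.DataFrame(red, index=controls_grn.index, columns=sample_ids)

    samples = pd.DataFrame({
        "donor_id": recorded_donor,
        "recorded_sex": recorded_sex,
    }, index=pd.Index(sample_ids, name="sample_id"))
    dataset = MethylationDataset(U=U, M=M, controls_grn=controls_grn,
                                 controls_red=controls_red, samples=samples,
                                 manifest=manifest)

    truth_samples = pd.DataFrame({
        "true_sex": true_sex,
        "recorded_sex": recorded_sex,
        "true_donor": donor_ids,
        "recorded_donor": recorded_donor,
        "gamma": gamma,
        "detection_failure": [i in set(config.detection_failures) for i in range(n)],
        "failed_categories": [",".join(sorted(set(failed_by[i]))) for i in range(n)],
        "replicate_of": replicate_of,
        "sex_mislabeled": [i in set(config.sex_swaps) for i in range(n)],
    }, index=samples.index)
    truth = TruthTable(samples=truth_samples, genotypes=genotypes,
                       source_genotypes=source_geno, c=c, allele_frequencies=p)
    return dataset, manifest, truth
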