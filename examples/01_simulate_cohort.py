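"""Simulate a methylation-array cohort with known ground truth and save it.

The generator emits paired U/M intensity matrices, two-channel control-probe
intensities, sample metadata, a probe manifest, and a truth table recording
every latent variable (sex, genotypes, contamination, injected failures).
"""

from pathlib import Path

from methylqc import SimulationConfig, simulate_dataset, write_dataset, write_manifest

out = Path("sim_cohort")
out.mkdir(exist_ok=True)

config = SimulationConfig(n_samples=50, n_replicates=4, sex_swaps=[3, 17], seed=42)
dataset, manifest, truth = simulate_dataset(config)

write_dataset(dataset, out / "intensities.tsv", out / "controls.tsv", out / "samples.tsv")
write_manifest(manifest, out / "manifest.tsv")
truth.to_tsv(out / "truth.tsv")

print(f"samples: {dataset.n_samples} (incl. {config.n_replicates} technical replicates)")
print(f"probes:  {dataset.U.shape[0]} methylation + {dataset.controls_grn.shape[0]} control")
print(f"recorded-sex errors planted: {int(truth.samples['sex_mislabeled'].sum())}")
print(f"files written to {out}/")
# The truth table is what downstream QC checks are validated against: every
# mismatch or conflict a check reports should trace back to a planted error.
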