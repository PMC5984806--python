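"""Compute the 17 BeadArray control metrics and flag failing samples.

Three samples get an injected bisulfite-conversion failure; their converted
control probes emit background-level signal, so the "Bisulfite conversion II"
ratio drops below the threshold of 1 and exactly those samples are flagged.
"""

from methylqc import SimulationConfig, control_metrics, flag_samples, simulate_dataset

config = SimulationConfig(
    n_samples=20,
    control_failures={"bisulfite_conversion_II": [4, 11, 15]},
    seed=7,
)
dataset, _, truth = simulate_dataset(config)

results = control_metrics(dataset)
bc2 = results[results["metric"] == "Bisulfite conversion II"]
print(bc2[["sample_id", "value", "threshold", "flagged"]].round(2).to_string(index=False))

flagged = flag_samples(results)
print(f"\nsamples flagged by any of the 17 metrics: {sorted(flagged.index[flagged])}")
print("planted failures:", sorted(truth.samples.index[truth.samples.failed_categories != ""]))
# A value is the mean signal of a metric's foreground control group divided
# by its background group; values below threshold indicate the monitored
# experimental step (here: bisulfite conversion) underperformed.
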