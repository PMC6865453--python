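"""Run the whole pipeline from one declarative config.

Simulation, spectral band selection, cross-validated decoding, alignment
and every statistic run from a single RunConfig; outputs (TSV tables,
named-array archives, JSON cluster results, the resolved config and a
log) land in a run directory, each carrying the config hash.  Rerunning
the same config reproduces every stochastic output exactly.
"""

import json

import alphatune as at

config = at.RunConfig(
    seed=7,
    out_dir="scratch_run",
    n_subjects=12,               # scaled down for a quick demonstration
    n_trials_per_location=12,
    time_start=-3.75,
    time_step=0.25,
    n_permutations=500,
)

out = at.run_all(config)
stats = json.loads((out / "stats.json").read_text())

print(f"run directory: {out}  (config hash {stats['config_hash']})")
print(f"delay tuning magnitude:    {stats['delay_tuning_magnitude_mean']:+.3f}")
print(f"baseline tuning magnitude: {stats['baseline_tuning_magnitude_mean']:+.3f}")
print(f"significant delay-vs-baseline clusters: {stats['n_significant_tuning_clusters']}")
best = min(
    (c["p"] for c in stats["tuning_behavior_correlation"]["clusters"] if c["mass"] < 0),
    default=1.0,
)
print(f"best negative brain-behavior cluster p: {best:.4f}")
print(
    "\nA peaked delay magnitude with a flat baseline and a significant "
    "negative behavior cluster reproduces the full analysis chain end to end."
)
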