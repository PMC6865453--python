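"""Delay-period tuning versus a flat precue baseline, tested at the group level.

Simulates a 30-subject cohort, decodes alpha-band tuning from a delay bin
(-0.5 s) and a precue baseline bin (-3.5 s), and tests the paired
difference of the aligned curves with the cluster-based permutation test
(circular offset adjacency, max-|mass| null).
"""

import warnings

import numpy as np

import alphatune as at

warnings.filterwarnings("ignore", message="dropped")  # fold equalization
basis = at.make_basis(8)
cohort = at.simulate_cohort(30, seed=42, time_bins=[-3.5, -0.5])

diffs, delay_curves, base_curves = [], [], []
for s in cohort:
    res = at.crossval_decode(s.power.power[:, :, 0, :], s.trials, basis, k=6, seed=0)
    tun = at.align_and_average(res, s.trials, basis)
    base_curves.append(tun.unique_values[:, 0])
    delay_curves.append(tun.unique_values[:, 1])
    diffs.append(tun.unique_values[:, 1] - tun.unique_values[:, 0])

result = at.cluster_permutation(np.stack(diffs), n_perm=1000, seed=7)

offs = np.arange(8) * 45.0 - 180.0
print("offset |  delay  | baseline")
for o, d, b in zip(offs, np.mean(delay_curves, axis=0), np.mean(base_curves, axis=0)):
    print(f"{o:+5.0f}  | {d:+.3f}  | {b:+.3f}")
for c in result.clusters[:3]:
    print(f"cluster mass {c.mass:+.1f}, p = {c.p_value:.4f}")
print(
    "\nDelay bins show a peaked curve at 0 deg while baseline bins are flat; "
    "a cluster p below .05 means the dissociation survives multiple-"
    "comparison control across offsets."
)
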