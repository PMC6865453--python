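"""Decode spatial location tuning from one synthetic subject.

Simulates a subject holding one of 16 cued polar-angle locations in mind
while delay-period alpha power is depressed at the attended location,
then recovers the channel tuning function with the sixfold
cross-validated inverted encoding model.
"""

import warnings

import numpy as np

import alphatune as at

warnings.filterwarnings("ignore", message="dropped")  # fold equalization
basis = at.make_basis(8)
mixing = at.make_mixing(32, 8, np.random.default_rng(0))
truth = at.GroundTruth(mixing=mixing, tuning_depth=0.5, noise_sd=0.5)

design = at.make_design(40, 16, seed=1)           # 640 trials, 40 per location
power = at.simulate_power(design, truth, basis, time_bins=[-0.5], rng=np.random.default_rng(2))

res = at.crossval_decode(power.power[:, :, 0, 0], design, basis, k=6, seed=3)
tuning = at.align_and_average(res, design, basis)

print("offset (deg) | decoded channel response")
for off, val in zip(tuning.offsets_deg, tuning.values):
    print(f"{off:+9.0f}    | {val:+.3f} " + "#" * int(max(val, 0) * 40))
print(f"\ntuning magnitude: {at.tuning_magnitude(tuning):.3f}")
print(
    "A peak at 0 deg offset with a bell-shaped falloff means the decoder "
    "recovered the attended location from sensor alpha power; the magnitude "
    "is the near-peak minus near-trough mean response."
)
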