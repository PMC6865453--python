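# alphatune

Inverted encoding models of spatial location tuning in alpha-band power.

## The problem

During covert spatial attention, posterior alpha oscillations (8–13 Hz)
are not just lateralized: their power is depressed in a retinotopically
specific way at the attended location. `alphatune` is a library for
recovering that location tuning from multichannel sensor data (MEG/EEG
style recordings) and linking it to behavior. It is aimed at
cognitive-neuroscience analysts who want a tested, fully reproducible
implementation of the inverted-encoding-model (IEM) pipeline — including
a synthetic-data generator with known ground truth, so every stage of
the analysis has an exact recovery test.

## The model

Sensor band power on trial *j* is modeled as a weighted sum of *l* = 8
idealized location channels with half-wave rectified, squared sinusoid
tuning curves, evenly spaced over polar angle:

    b_k(θ) = [max(0, cos(θ − c_k))]²,   c_k = k·45°,   Σ_k b_k(θ) = 2

With channel responses **C**₁ (l × n) on training trials and sensor
power **B**₁ (m × n), the decoding weights are the least-squares
solution of **C**₁ ≈ **W B**₁:

    W = C₁B₁ᵀ(B₁B₁ᵀ)⁻¹            Ĉ₂ = W B₂

estimated with stratified sixfold cross-validation (every fold samples
every location equally). Decoded responses are circularly aligned so
each trial's true location sits at 0° offset; an accurate model shows a
peak at 0° and a trough at ±180°. Weights are made interpretable as
sensor topographies via the activation-pattern (Haufe) transform
`A = cov(B₁) Wᵀ cov(Ĉ₁)⁺`. Group inference uses cluster-based Monte
Carlo permutation tests on time × offset maps (circular offset
adjacency, maximum-|cluster mass| null), and brain–behavior linkage uses
across-subject Spearman correlation between tuning maps and each
subject's flanker cost (Cohen's *d*).

## Worked example

```bash
python examples/decode_location_tuning.py
```

simulates one subject (640 trials, 16 locations, 32 sensors, tuning
depth 0.5, power noise SD 0.5) and decodes the channel tuning function:

```
offset (deg) | decoded channel response
     -180    | +0.076 ###
     -135    | +0.067 ##
      -90    | +0.115 ####
      -45    | +0.355 ##############
       +0    | +0.593 #######################
      +45    | +0.500 ####################
      +90    | +0.213 ########
     +135    | +0.075 ##
     +180    | +0.076 ###

tuning magnitude: 0.410
```

The curve peaks at 0° offset — the decoder recovered the attended
location from sensor alpha power alone — and falls off in the
bell shape the basis imposes; the magnitude (mean of the −45°…+45°
responses minus mean of the 135°…225° responses) quantifies the tuning.
The other examples run the group-level analyses: delay-versus-baseline
dissociation, the negative tuning–distractibility correlation map, the
fast/slow median split, and a full config-driven pipeline run
(`full_pipeline_run.py`).

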