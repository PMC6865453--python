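"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a covert spatial attention study: on each trial a
cue points to one of 16 equally spaced polar-angle locations which must be
held in mind through a delay; during the delay, alpha-band (~10 Hz) power
at sensors is depressed in proportion to a location-tuned gain, absent in
a precue baseline interval.  Eight latent location channels mix linearly
into the sensors, and reaction times carry a flanker (congruency) cost
whose size shrinks with the subject's tuning depth — the across-subject
brain–behavior link the statistics module is meant to recover.

Every draw is controlled by a single seed, so downstream stages have exact
ground-truth recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .encoding import BasisSet, make_basis
from .spectral import PowerArray, SensorEpochs

__all__ = [
    "GroundTruth",
    "SubjectData",
    "make_design",
    "make_mixing",
    "simulate_power",
    "simulate_timeseries",
    "simulate_behavior",
    "simulate_cohort",
]

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"


@dataclass
class GroundTruth:
    """Generative parameters for one synthetic subject.

    Parameters
    ----------
    mixing
        Sensors x latent-channels nonnegative power gains; must have full
        column rank when there are at least as many sensors as channels.
    tuning_depth
        Fractional alpha-power depression at the attended location,
        in [0, 1): latent channel k carries
        ``baseline_power * (1 − tuning_depth * b_k(angle))`` during the
        delay and ``baseline_power`` elsewhere.
    noise_sd
        SD of additive Gaussian sensor-power noise (same units as power).
    delay_window, baseline_window
        Disjoint [start, end] intervals in seconds (target onset at 0).
    flanker_base_cost_ms, flanker_depth_slope_ms
        The incongruent-minus-congruent RT cost is
        ``max(0, base + slope * tuning_depth)``; a negative slope yields
        the negative depth-to-cost link across subjects.
    """

    mixing: np.ndarray
    tuning_depth: float = 0.5
    baseline_power: float = 1.0
    noise_sd: float = 0.5
    delay_window: tuple[float, float] = (-1.0, 0.0)
    baseline_window: tuple[float, float] = (-4.0, -3.0)
    flanker_base_cost_ms: float = 80.0
    flanker_depth_slope_ms: float = -80.0
    rt_base_ms: float = 500.0
    rt_noise_sd_ms: float = 40.0
    seed: int = 0

    def __post_init__(self):
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.ndim != 2:
            raise ValueError("mixing must be a sensors x channels matrix")
        m, l = self.mixing.shape
        if m >= l and np.linalg.matrix_rank(self.mixing) < l:
            raise ValueError("mixing matrix is column-rank deficient")
        if not 0.0 <= self.tuning_depth < 1.0:
            raise ValueError(f"tuning_depth must be in [0, 1), got {self.tuning_depth}")
        d0, d1 = self.delay_window
        b0, b1 = self.baseline_window
        if not (d0 < d1 and b0 < b1):
            raise ValueError("windows must be increasing [start, end] pairs")
        if max(d0, b0) < min(d1, b1):
            raise ValueError("delay_window and baseline_window must be disjoint")

    @property
    def n_sensors(self) -> int:
        return self.mixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[1]


@dataclass
class SubjectData:
    """One synthetic subject: metadata table, neural data and ground truth."""

    subject: str
    trials: pd.DataFrame
    power: PowerArray | None
    epochs: SensorEpochs | None
    truth: GroundTruth
    depth: float


def make_design(
    n_trials_per_location: int, n_locations: int = 16, seed: int = 0
) -> pd.DataFrame:
    """Balanced pseudorandom trial list over equally spaced locations.

    Each location (angle ``location * 360 / n_locations`` degrees) occurs
    exactly ``n_trials_per_location`` times, with congruency balanced
    within each location; trial order is shuffled under ``seed``.
    """
    if n_trials_per_location < 1 or n_locations < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    locations = np.repeat(np.arange(n_locations), n_trials_per_location)
    # alternate congruency within each location, then shuffle globally
    congr = np.tile(
        np.resize([CONGRUENT, INCONGRUENT], n_trials_per_location), n_locations
    )
    order = rng.permutation(len(locations))
    df = pd.DataFrame(
        {
            "subject": "sim",
            "trial": np.arange(len(locations)),
            "location": locations[order],
            "angle_deg": locations[order] * (360.0 / n_locations),
            "congruency": congr[order],
            "rt_ms": np.nan,
            "correct": pd.array([pd.NA] * len(locations), dtype="boolean"),
        }
    )
    return df


def make_mixing(
    n_sensors: int,
    n_channels: int = 8,
    rng: np.random.Generator | None = None,
    background: float = 0.15,
) -> np.ndarray:
    """Random nonnegative sensor mixing with full column rank.

    Each sensor carries a weak uniform background gain from every latent
    channel plus a strong gain from one preferred channel (channels are
    cycled across sensors), loosely emulating retinotopically clustered
    sensor sensitivity.
    """
    rng = np.random.default_rng(rng)
    for _ in range(10):
        mix = rng.uniform(0.2, 1.0, size=(n_sensors, n_channels)) * background
        preferred = (np.arange(n_sensors) + rng.integers(n_channels)) % n_channels
        mix[np.arange(n_sensors), preferred] += rng.uniform(0.7, 1.3, size=n_sensors)
        if n_sensors < n_channels or np.linalg.matrix_rank(mix) == n_channels:
            return mix
    raise RuntimeError("failed to draw a full-rank mixing matrix")


def _latent_power(
    angles: np.ndarray,
    truth: GroundTruth,
    basis: BasisSet,
    time_bins: np.ndarray,
    depth_profile: np.ndarray | None,
) -> np.ndarray:
    """Latent channel power (n_trials x l x n_bins) under the tuning rule."""
    b = basis.evaluate(angles)  # l x n
    if depth_profile is None:
        in_delay = (time_bins >= truth.delay_window[0]) & (time_bins <= truth.delay_window[1])
        depth_profile = truth.tuning_depth * in_delay.astype(float)[None, :]
    depth_profile = np.broadcast_to(
        np.asarray(depth_profile, dtype=float), (len(angles), len(time_bins))
    )
    # g[j, k, t] = baseline * (1 − d_jt * b_k(theta_j))
    return truth.baseline_power * (
        1.0 - depth_profile[:, None, :] * b.T[:, :, None]
    )


def simulate_power(
    design: pd.DataFrame,
    truth: GroundTruth,
    basis: BasisSet | None = None,
    time_bins=(-0.5,),
    rng: np.random.Generator | None = None,
    depth_profile: np.ndarray | None = None,
) -> PowerArray:
    """Draw sensor alpha power directly in the power domain.

    For time bins inside the delay window, sensor power is
    ``mixing @ g(angle) + noise`` with latent channel k carrying
    ``baseline_power * (1 − tuning_depth * b_k(angle))``; outside the
    delay there is no location dependence.  ``depth_profile`` (trials x
    bins) overrides the boxcar depth-by-time rule, enabling per-trial
    tuning time courses.  Power is clipped at zero.

    The result is a :class:`~alphatune.spectral.PowerArray` with a single
    10 Hz frequency bin, so it flows through the same band-power selection
    as the spectral pipeline.
    """
    basis = basis or make_basis(truth.n_channels)
    if basis.n_channels != truth.n_channels:
        raise ValueError(
            f"basis has {basis.n_channels} channels but mixing expects {truth.n_channels}"
        )
    rng = np.random.default_rng(rng if rng is not None else truth.seed)
    time_bins = np.asarray(time_bins, dtype=float)
    angles = design["angle_deg"].to_numpy(dtype=float)
    g = _latent_power(angles, truth, basis, time_bins, depth_profile)
    power = np.einsum("mk,jkt->jmt", truth.mixing, g)
    if truth.noise_sd > 0:
        power = power + rng.normal(0.0, truth.noise_sd, size=power.shape)
    power = np.clip(power, 0.0, None)
    return PowerArray(
        power[:, :, None, :], freqs=np.array([10.0]), times=time_bins,
        window_s=np.nan, step_s=np.nan,
    )


def simulate_timeseries(
    design: pd.DataFrame,
    truth: GroundTruth,
    basis: BasisSet | None = None,
    fs: float = 200.0,
    carrier_freq: float = 10.0,
    epoch: tuple[float, float] = (-4.25, 0.5),
    ts_noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> SensorEpochs:
    """Oscillatory sensor time series whose band power follows the tuning rule.

    Each latent channel contributes a carrier-frequency sinusoid with an
    independent random phase per trial; its amplitude envelope is
    ``sqrt(2 * g_k(t))`` so the envelope's alpha-band power equals the
    power-domain generator's latent power ``g_k(t)``.  Channels mix into
    sensors with amplitude gains ``sqrt(mixing)``; since phases are
    incoherent, expected sensor band power is ``mixing @ g`` as in
    :func:`simulate_power`.  Broadband Gaussian noise of SD ``ts_noise_sd``
    is added per sample.
    """
    if fs < 4 * carrier_freq:
        raise ValueError(f"fs={fs} too low for carrier {carrier_freq} Hz (need >= 4x)")
    basis = basis or make_basis(truth.n_channels)
    rng = np.random.default_rng(rng if rng is not None else truth.seed)
    n_samp = int(round((epoch[1] - epoch[0]) * fs)) + 1
    times = epoch[0] + np.arange(n_samp) / fs
    angles = design["angle_deg"].to_numpy(dtype=float)
    g = _latent_power(angles, truth, basis, times, None)  # n x l x samples
    amp = np.sqrt(2.0 * np.clip(g, 0.0, None))
    phases = rng.uniform(0.0, 2 * np.pi, size=(len(angles), truth.n_channels))
    carrier = np.cos(
        2 * np.pi * carrier_freq * times[None, None, :] + phases[:, :, None]
    )
    amp_mix = np.sqrt(truth.mixing)  # amplitude-domain gains
    data = np.einsum("mk,jkt->jmt", amp_mix, amp * carrier)
    if ts_noise_sd > 0:
        data = data + rng.normal(0.0, ts_noise_sd, size=data.shape)
    return SensorEpochs(data, fs=fs, times=times)


def simulate_behavior(
    design: pd.DataFrame,
    truth: GroundTruth,
    subject_depth: float | None = None,
    rng: np.random.Generator | None = None,
    rt_penalty_ms: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fill reaction times and accuracy for a trial table.

    ``rt = rt_base + [incongruent] * max(0, base_cost + slope * depth)
    + penalty + noise``; the expected flanker cost therefore shrinks as
    tuning depth grows (for a negative slope).  ``rt_penalty_ms``
    optionally adds a per-trial slowing (used by the sustained-tuning
    cohort variant).  Accuracy is drawn at 96% (congruent) / 92%
    (incongruent).
    """
    depth = truth.tuning_depth if subject_depth is None else subject_depth
    if not 0.0 <= depth < 1.0:
        raise ValueError(f"subject_depth must be in [0, 1), got {depth}")
    rng = np.random.default_rng(rng if rng is not None else truth.seed)
    df = design.copy()
    incong = (df["congruency"] == INCONGRUENT).to_numpy()
    cost = max(0.0, truth.flanker_base_cost_ms + truth.flanker_depth_slope_ms * depth)
    rt = truth.rt_base_ms + incong * cost
    if rt_penalty_ms is not None:
        rt = rt + np.asarray(rt_penalty_ms, dtype=float)
    if truth.rt_noise_sd_ms > 0:
        rt = rt + rng.normal(0.0, truth.rt_noise_sd_ms, size=len(df))
    p_correct = np.where(incong, 0.92, 0.96)
    df["rt_ms"] = rt
    df["correct"] = rng.random(len(df)) < p_correct
    return df


def simulate_cohort(
    n_subjects: int = 30,
    truth: GroundTruth | None = None,
    seed: int = 0,
    n_trials_per_location: int = 40,
    n_locations: int = 16,
    n_sensors: int = 32,
    n_channels: int = 8,
    time_bins=(-0.5,),
    depth_range: tuple[float, float] = (0.2, 0.8),
    mode: str = "power",
    sustain_link: bool = False,
    sustain_drop_time: float = -0.5,
    sustain_rt_penalty_ms: float = 60.0,
    sustain_prob: float = 0.5,
    fs: float = 200.0,
) -> list[SubjectData]:
    """Generate a cohort of synthetic subjects.

    Per subject, a tuning depth is drawn uniformly from ``depth_range``
    (or taken from ``truth`` when the range endpoints coincide with it),
    an independent mixing matrix is drawn, and neural data are generated
    in the requested ``mode`` ("power": direct power arrays at
    ``time_bins``; "timeseries": oscillatory epochs at ``fs``).  Behavior
    carries the depth-linked flanker cost.

    With ``sustain_link=True``, each trial is latently "sustained" with
    probability ``sustain_prob``; non-sustained trials lose their tuning
    from ``sustain_drop_time`` onward and incur an RT penalty, creating
    the within-subject link between tuning sustainability and response
    speed probed by the median-split analysis.

    The seed fully determines every draw.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    template = truth
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    basis = make_basis(n_channels)
    subjects = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        depth = float(rng.uniform(*depth_range))
        mixing = make_mixing(n_sensors, n_channels, rng)
        kwargs = dict(tuning_depth=depth, mixing=mixing, seed=seed)
        st = (
            replace(template, **kwargs)
            if template is not None
            else GroundTruth(**kwargs)
        )
        design = make_design(n_trials_per_location, n_locations, seed=rng.integers(2**31))

        penalty = None
        depth_profile = None
        if sustain_link:
            sustained = rng.random(len(design)) < sustain_prob
            penalty = np.where(sustained, 0.0, sustain_rt_penalty_ms)
            tb = np.asarray(time_bins, dtype=float)
            in_delay = (tb >= st.delay_window[0]) & (tb <= st.delay_window[1])
            profile = np.tile(in_delay.astype(float), (len(design), 1)) * depth
            late = in_delay & (tb >= sustain_drop_time)
            profile[np.ix_(~sustained, late)] = 0.0
            depth_profile = profile

        trials = simulate_behavior(design, st, depth, rng, rt_penalty_ms=penalty)
        power = epochs = None
        if mode == "power":
            power = simulate_power(
                design, st, basis, time_bins, rng, depth_profile=depth_profile
            )
        elif mode == "timeseries":
            epochs = simulate_timeseries(design, st, basis, fs=fs, rng=rng)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        subjects.append(
            SubjectData(
                subject=f"S{i + 1:02d}", trials=trials, power=power,
                epochs=epochs, truth=st, depth=depth,
            )
        )
    return subjects
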