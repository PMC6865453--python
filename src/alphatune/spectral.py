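"""Sliding-window tapered FFT power estimation and alpha-band extraction.

Power is estimated per trial with a tapered FFT in a 500 ms Hann window
advanced in 50 ms steps, giving 2 Hz spectral resolution.  Power is
coherent-gain corrected so a unit-amplitude sinusoid at a bin center
yields 0.5 (amplitude squared over two) — this makes synthetic oracles
closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

__all__ = [
    "SensorEpochs",
    "PowerArray",
    "sliding_power",
    "band_power",
    "attention_contrast",
]


@dataclass
class SensorEpochs:
    """Epoched multichannel time series (trials x sensors x samples).

    ``times`` is uniform at spacing ``1/fs`` with the target onset at 0 s.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be trials x sensors x samples, got {self.data.shape}")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length does not match data")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1.0 / self.fs, rtol=0, atol=1e-9):
            raise ValueError("time axis is not uniform at 1/fs spacing")


@dataclass
class PowerArray:
    """Spectral power, trials x sensors x frequencies x time-bins.

    ``times`` holds window centers on the epoch time axis; frequency
    spacing is ``1/window_s`` (2 Hz for the 500 ms default).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    window_s: float = 0.5
    step_s: float = 0.05

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.ndim != 4:
            raise ValueError(
                f"power must be trials x sensors x freqs x times, got {self.power.shape}"
            )


def sliding_power(
    epochs: SensorEpochs,
    window_s: float = 0.5,
    step_s: float = 0.05,
    taper: str = "hann",
    fmax: float | None = None,
) -> PowerArray:
    """Sliding-window tapered FFT power of epoched data.

    Windows are placed only where they lie fully inside the epoch (no
    zero padding); the window center is reported on the epoch time axis.
    ``fmax`` optionally discards frequency bins above a cutoff to bound
    memory.

    Normalization: at a bin-center frequency a sinusoid of amplitude ``a``
    yields power ``a²/2``; a DC signal yields its squared mean in the
    0 Hz bin.
    """
    nw = epochs.fs * window_s
    if abs(nw - round(nw)) > 1e-9:
        raise ValueError(f"fs*window_s must be an integer sample count, got {nw}")
    nw = int(round(nw))
    n_samples = epochs.data.shape[2]
    if nw > n_samples:
        raise ValueError(f"window ({nw} samples) longer than epoch ({n_samples})")
    nstep = max(1, int(round(epochs.fs * step_s)))

    w = get_window(taper, nw, fftbins=True)
    wsum = w.sum()
    starts = np.arange(0, n_samples - nw + 1, nstep)
    centers = (epochs.times[starts] + epochs.times[starts + nw - 1]) / 2.0

    freqs = np.fft.rfftfreq(nw, d=1.0 / epochs.fs)
    keep = slice(None) if fmax is None else freqs <= fmax
    freqs_out = freqs[keep]

    n, m = epochs.data.shape[:2]
    out = np.empty((n, m, len(freqs_out), len(starts)))
    # per-bin scale: one-sided spectrum, coherent-gain corrected
    scale = np.full(len(freqs), 2.0 / wsum**2)
    scale[0] = 1.0 / wsum**2
    if nw % 2 == 0:
        scale[-1] = 1.0 / wsum**2
    scale = scale[keep]
    for i, s in enumerate(starts):
        seg = epochs.data[:, :, s : s + nw] * w
        spec = np.fft.rfft(seg, axis=2)[:, :, keep]
        out[:, :, :, i] = (spec.real**2 + spec.imag**2) * scale
    return PowerArray(out, freqs_out, centers, window_s=window_s, step_s=nstep / epochs.fs)


def band_power(
    pa: PowerArray,
    band: tuple[float, float] = (8.0, 13.0),
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Average power over a frequency band and (optionally) a time window.

    A frequency bin is included when its center lies in the closed band;
    with 2 Hz resolution the default alpha band [8, 13] Hz selects the
    {8, 10, 12} Hz bins.  Returns trials x sensors when ``window`` is
    given, else trials x sensors x time-bins.
    """
    fsel = (pa.freqs >= band[0]) & (pa.freqs <= band[1])
    if not np.any(fsel):
        raise ValueError(f"no frequency bins inside band {band} (freqs: {pa.freqs})")
    bp = pa.power[:, :, fsel, :].mean(axis=2)
    if window is None:
        return bp
    tsel = (pa.times >= window[0]) & (pa.times <= window[1])
    if not np.any(tsel):
        raise ValueError(f"no time bins inside window {window}")
    return bp[:, :, tsel].mean(axis=2)


def attention_contrast(p_left: np.ndarray, p_right: np.ndarray) -> np.ndarray:
    """Normalized power difference (L − R) / (L + R), elementwise.

    Bounded in [−1, 1]; cells where both inputs are zero are defined as 0
    (with a warning).
    """
    p_left = np.asarray(p_left, dtype=float)
    p_right = np.asarray(p_right, dtype=float)
    if p_left.shape != p_right.shape:
        raise ValueError(f"shape mismatch: {p_left.shape} vs {p_right.shape}")
    total = p_left + p_right
    zero = total == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} cells with zero total power set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, 0.0, (p_left - p_right) / np.where(zero, 1.0, total))
    return out
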