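"""Inverted encoding model of circular location tuning.

The model expresses band power at each sensor as a weighted sum of a small
number of idealized, location-tuned channels.  Fitting the weights on
training trials by ordinary least squares and applying them to held-out
trials "inverts" the model: it decodes a response for every channel on
every test trial.  Circularly aligning the decoded responses to each
trial's true location and averaging yields the channel tuning function,
whose peak at 0° offset quantifies location selectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BasisSet",
    "DecodeResult",
    "AlignedTuning",
    "make_basis",
    "channel_responses",
    "fit_weights",
    "decode",
    "crossval_decode",
    "align_and_average",
    "tuning_magnitude",
    "activation_patterns",
]


@dataclass(frozen=True)
class BasisSet:
    """A set of idealized circular tuning curves.

    Channel ``k`` responds with ``max(0, cos(theta - center_k)) ** exponent``
    — a half-wave rectified, squared (for the default exponent) sinusoid.
    For the default ``l = 8, exponent = 2`` the curves partition the circle:
    their sum is exactly ``l / 4 = 2`` at every angle.
    """

    centers_deg: np.ndarray
    exponent: int = 2

    @property
    def n_channels(self) -> int:
        return len(self.centers_deg)

    @property
    def spacing_deg(self) -> float:
        return 360.0 / self.n_channels

    def evaluate(self, angles_deg) -> np.ndarray:
        """Evaluate every basis function at the given angles.

        Returns an ``(l,)`` vector for scalar input, else an ``(l, n)``
        matrix with one column per angle.
        """
        angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
        delta = np.deg2rad(angles[None, :] - self.centers_deg[:, None])
        resp = np.maximum(0.0, np.cos(delta)) ** self.exponent
        if np.isscalar(angles_deg) or np.ndim(angles_deg) == 0:
            return resp[:, 0]
        return resp

    def nearest_center_index(self, angles_deg) -> np.ndarray:
        """Index of the basis center nearest each angle.

        Angles exactly halfway between two centers are assigned to the
        counterclockwise (lower-angle) center, deterministically.
        """
        frac = np.atleast_1d(np.asarray(angles_deg, dtype=float)) / self.spacing_deg
        lower = np.floor(frac)
        idx = np.where(frac - lower <= 0.5, lower, lower + 1)
        return (idx.astype(int)) % self.n_channels


def make_basis(l: int = 8, exponent: int = 2) -> BasisSet:
    """Construct ``l`` evenly spaced half-wave rectified cosine basis functions.

    Parameters
    ----------
    l
        Number of channels; centers at ``k * 360 / l`` degrees.  Must be
        at least 3 so the rectified curves still tile the circle.
    exponent
        Power applied to the rectified cosine (2 gives the squared form).
    """
    if l < 3:
        raise ValueError(f"need at least 3 basis functions, got l={l}")
    if exponent < 1:
        raise ValueError(f"exponent must be >= 1, got {exponent}")
    centers = np.arange(l) * (360.0 / l)
    return BasisSet(centers_deg=centers, exponent=int(exponent))


def channel_responses(design: pd.DataFrame, basis: BasisSet) -> np.ndarray:
    """Design matrix C (l x n): column j is the basis evaluated at trial j's angle."""
    if "angle_deg" not in design.columns:
        raise ValueError("design table has no 'angle_deg' column")
    angles = design["angle_deg"].to_numpy(dtype=float)
    if np.any(~np.isfinite(angles)):
        raise ValueError("design table contains missing angles")
    return basis.evaluate(angles)


def fit_weights(C1: np.ndarray, B1: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Estimate decoding weights W (l x m) by least squares on C1 ~ W B1.

    The OLS solution is ``W = C1 B1ᵀ (B1 B1ᵀ)⁻¹``.  When the training
    covariance ``B1 B1ᵀ`` is rank deficient (e.g. noiseless low-rank data)
    the minimum-norm least-squares solution is returned instead of raising;
    a positive ``ridge`` adds ``ridge * I`` to ``B1 B1ᵀ`` before inversion.
    """
    C1 = np.asarray(C1, dtype=float)
    B1 = np.asarray(B1, dtype=float)
    if C1.ndim != 2 or B1.ndim != 2 or C1.shape[1] != B1.shape[1]:
        raise ValueError(
            f"incompatible shapes: C1 {C1.shape}, B1 {B1.shape} (trials must match)"
        )
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if ridge > 0:
        m = B1.shape[0]
        G = B1 @ B1.T + ridge * np.eye(m)
        return np.linalg.solve(G, B1 @ C1.T).T
    # min ||C1 - W B1||_F  <=>  min ||B1ᵀ Wᵀ - C1ᵀ||_F, solved column-wise
    Wt, *_ = np.linalg.lstsq(B1.T, C1.T, rcond=None)
    return Wt.T


def decode(W: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Apply decoding weights to test data: Ĉ2 = W B2 (l x n_test)."""
    W = np.asarray(W, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    if W.shape[1] != B2.shape[0]:
        raise ValueError(f"W has {W.shape[1]} sensors but B2 has {B2.shape[0]}")
    return W @ B2


@dataclass
class DecodeResult:
    """Cross-validated decoded channel responses.

    ``responses`` has shape ``(l, n_trials)`` or ``(l, n_trials, n_times)``;
    trials that were dropped to equalize folds hold NaN and carry fold
    assignment −1.
    """

    responses: np.ndarray
    folds: np.ndarray
    n_dropped: int = 0

    @property
    def used(self) -> np.ndarray:
        return self.folds >= 0


def _stratified_folds(locations: np.ndarray, k: int, rng: np.random.Generator):
    """Assign each trial a fold 0..k−1, stratified by location.

    Within each location trials are shuffled, any remainder beyond a
    multiple of ``k`` is dropped (fold −1), and the rest split evenly so
    every fold samples every location equally often.
    """
    folds = np.full(len(locations), -1, dtype=int)
    deficient = []
    for loc in np.unique(locations):
        idx = np.flatnonzero(locations == loc)
        if len(idx) < k:
            deficient.append((loc, len(idx)))
            continue
        idx = rng.permutation(idx)
        per = len(idx) // k
        for f in range(k):
            folds[idx[f * per : (f + 1) * per]] = f
    if deficient:
        raise ValueError(
            "locations with fewer trials than folds: "
            + ", ".join(f"location {l} has {n} < {k}" for l, n in deficient)
        )
    return folds


def crossval_decode(
    power: np.ndarray,
    design: pd.DataFrame,
    basis: BasisSet,
    k: int = 6,
    seed: int | None = 0,
    ridge: float = 0.0,
) -> DecodeResult:
    """Stratified k-fold cross-validated decoding.

    Parameters
    ----------
    power
        Trials x sensors, or trials x sensors x time-bins.  With a time
        axis, weights are fit and applied independently per time bin.
    design
        Trial table providing ``location`` and ``angle_deg``.
    k
        Number of folds (sixfold by default); each fold samples every
        location equally, and every retained trial is decoded exactly once
        by weights fit on the other k−1 folds.
    seed
        Seeds the fold shuffle.  Remainder trials that cannot be spread
        evenly are dropped (reported in ``n_dropped``).
    """
    power = np.asarray(power, dtype=float)
    if power.ndim == 2:
        out = crossval_decode(power[:, :, None], design, basis, k, seed, ridge)
        return DecodeResult(out.responses[:, :, 0], out.folds, out.n_dropped)
    if power.ndim != 3 or power.shape[0] != len(design):
        raise ValueError(
            f"power must be (n_trials, n_sensors[, n_times]) with "
            f"{len(design)} trials, got {power.shape}"
        )
    n, m, nt = power.shape
    locations = design["location"].to_numpy()
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(locations, k, rng)
    n_dropped = int(np.sum(folds < 0))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} trials to equalize folds", stacklevel=2)

    C = channel_responses(design, basis)
    l = basis.n_channels
    decoded = np.full((l, n, nt), np.nan)
    for f in range(k):
        train = folds >= 0
        train &= folds != f
        test = folds == f
        for t in range(nt):
            W = fit_weights(C[:, train], power[train, :, t].T, ridge=ridge)
            decoded[:, test, t] = decode(W, power[test, :, t].T)
    return DecodeResult(decoded, folds, n_dropped)


@dataclass
class AlignedTuning:
    """Channel tuning function: decoded responses aligned to 0° offset.

    ``offsets_deg`` runs −180° … +180° in basis-spacing steps; the −180°
    and +180° entries are the same circular bin, duplicated so the curve
    closes when plotted.  ``values``/``sem`` have the offset axis first,
    optionally followed by a time axis.
    """

    offsets_deg: np.ndarray
    values: np.ndarray
    sem: np.ndarray
    n_trials: int
    times: np.ndarray | None = None

    @property
    def n_offsets(self) -> int:
        """Number of unique circular offset bins."""
        return len(self.offsets_deg) - 1

    @property
    def unique_offsets_deg(self) -> np.ndarray:
        return self.offsets_deg[:-1]

    @property
    def unique_values(self) -> np.ndarray:
        return self.values[:-1]


def _align_trials(decoded: np.ndarray, angles: np.ndarray, basis: BasisSet):
    """Rotate each trial's decoded vector so its true channel sits at 0° offset.

    Returns (aligned, offsets_deg): ``aligned[j]`` is ordered by offset
    −180° … +135° (l unique bins) and the offset axis in degrees.
    """
    l = basis.n_channels
    centers = basis.nearest_center_index(angles)
    half = l // 2
    steps = np.arange(-half, l - half)  # offsets −180° … +135° for l=8
    # aligned value at offset step s = decoded channel (center + s) mod l
    chan = (centers[None, :] + steps[:, None]) % l
    aligned = np.take_along_axis(
        decoded, chan[:, :, None] if decoded.ndim == 3 else chan, axis=0
    )
    return aligned, steps * basis.spacing_deg


def align_and_average(
    decoded: DecodeResult | np.ndarray,
    design: pd.DataFrame,
    basis: BasisSet,
    valid: np.ndarray | None = None,
) -> AlignedTuning:
    """Circularly align decoded responses to each trial's location and average.

    An accurate model yields a curve peaking at 0° offset and bottoming at
    ±180°; an uninformative one is flat.  Alignment is a pure rotation of
    each trial's decoded vector by whole channel steps, so the multiset of
    values per trial is preserved.

    ``valid`` optionally restricts the average to a boolean trial subset;
    by default trials dropped during cross-validation are excluded.
    """
    if isinstance(decoded, DecodeResult):
        resp, default_valid = decoded.responses, decoded.used
    else:
        resp = np.asarray(decoded, dtype=float)
        default_valid = ~np.any(np.isnan(resp), axis=tuple(i for i in range(resp.ndim) if i != 1))
    if valid is None:
        valid = default_valid
    angles = design["angle_deg"].to_numpy(dtype=float)
    resp = resp[:, valid]
    angles = angles[valid]
    n = resp.shape[1]
    if n == 0:
        raise ValueError("no valid trials to align")

    aligned, offs = _align_trials(resp, angles, basis)
    mean = aligned.mean(axis=1)
    sem = aligned.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    # close the circle: +180° duplicates the −180° bin
    offsets = np.concatenate([offs, [-offs[0]]])
    values = np.concatenate([mean, mean[:1]], axis=0)
    sems = np.concatenate([sem, sem[:1]], axis=0)
    return AlignedTuning(offsets, values, sems, n_trials=n)


def tuning_magnitude(at: AlignedTuning) -> float | np.ndarray:
    """Scalar tuning strength: mean near-peak minus mean near-trough response.

    Averages the aligned responses at offsets {−45°, 0°, +45°} and
    subtracts the average at {135°, ±180°, −135°}.  Zero for a flat curve
    and invariant to adding a constant to all offsets.  Returns one value
    per time bin when the tuning is time resolved.
    """
    offs = at.unique_offsets_deg
    vals = at.unique_values
    near = np.isin(offs, (-45.0, 0.0, 45.0))
    far = np.isin(offs, (135.0, 180.0, -180.0, -135.0))
    return vals[near].mean(axis=0) - vals[far].mean(axis=0)


def activation_patterns(
    W: np.ndarray,
    B1: np.ndarray,
    C1_hat: np.ndarray | None = None,
    rcond: float = 0.05,
) -> np.ndarray:
    """Transform decoding weights into forward-model activation patterns.

    ``A = cov(B1) Wᵀ cov(Ĉ1)⁺`` with ``Ĉ1 = W B1`` — one sensor pattern
    per channel (m x l).  Unlike the raw weights, which may express
    suppression of correlated noise, the patterns are interpretable as the
    sensor topography each channel drives.

    The decoded-response covariance is inverted on its principal subspace
    only: eigendirections carrying less than ``rcond`` of the dominant
    eigenvalue are truncated (with a warning).  For the default rectified
    cosine basis ``cov(C)`` is intrinsically rank deficient (the curves
    sum to a constant), so a plain inverse does not exist and the weakest
    directions carry mostly overfitting noise.
    """
    W = np.asarray(W, dtype=float)
    B1 = np.asarray(B1, dtype=float)
    l = W.shape[0]
    if B1.shape[1] <= l:
        raise ValueError(
            f"need more than {l} training trials to estimate covariances, "
            f"got {B1.shape[1]}"
        )
    if C1_hat is None:
        C1_hat = W @ B1
    sigma_b = np.cov(B1)
    sigma_c = np.cov(np.asarray(C1_hat, dtype=float))
    evals, evecs = np.linalg.eigh(sigma_c)
    keep = evals > rcond * evals.max()
    if not np.all(keep):
        warnings.warn(
            f"decoded-response covariance is rank deficient; inverting on its "
            f"{int(keep.sum())}-dimensional principal subspace",
            stacklevel=2,
        )
    inv_c = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    return sigma_b @ W.T @ inv_c
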