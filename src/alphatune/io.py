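"""Reading and writing the package's on-disk formats.

Trial tables are TSV with a fixed header; epochs and power arrays are
named-array archives (NumPy ``.npz``) with a JSON sidecar recording the
generating configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import PowerArray, SensorEpochs

TRIAL_COLUMNS = ["subject", "trial", "location", "angle_deg", "congruency", "rt_ms", "correct"]


def save_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False, columns=TRIAL_COLUMNS, float_format="%.6g")


def load_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _write_sidecar(path: Path, meta: dict | None) -> None:
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def save_epochs(epochs: SensorEpochs, path, meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, data=epochs.data, fs=epochs.fs, times=epochs.times)
    _write_sidecar(path, meta)


def load_epochs(path) -> SensorEpochs:
    with np.load(path) as z:
        return SensorEpochs(z["data"], float(z["fs"]), z["times"])


def save_power(pa: PowerArray, path, meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(
        path, power=pa.power, freqs=pa.freqs, times=pa.times,
        window_s=pa.window_s, step_s=pa.step_s,
    )
    _write_sidecar(path, meta)


def load_power(path) -> PowerArray:
    with np.load(path) as z:
        return PowerArray(
            z["power"], z["freqs"], z["times"],
            float(z["window_s"]), float(z["step_s"]),
        )
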