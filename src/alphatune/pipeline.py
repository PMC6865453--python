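"""End-to-end orchestration: simulate -> decode -> statistics -> report.

A single declarative :class:`RunConfig` drives every stage; one master
seed fans out deterministically to per-stage seeds, so rerunning an
identical config reproduces identical outputs.  Results land in a run
directory as TSV tables, named-array archives, JSON cluster results, a
resolved copy of the config and a log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as atio
from .encoding import align_and_average, crossval_decode, make_basis, tuning_magnitude
from .spectral import band_power
from .stats import cluster_permutation, flanker_effect, median_split_tuning, spearman_map
from .synthetic import simulate_cohort

__all__ = ["RunConfig", "run_all", "validate_inputs"]

logger = logging.getLogger("alphatune")


@dataclass
class RunConfig:
    """All pipeline parameters in one round-trippable document."""

    seed: int = 7
    out_dir: str = "alphatune_run"
    # cohort
    n_subjects: int = 30
    n_trials_per_location: int = 40
    n_locations: int = 16
    n_sensors: int = 32
    n_channels: int = 8
    depth_range: tuple[float, float] = (0.2, 0.8)
    baseline_power: float = 1.0
    noise_sd: float = 0.5
    # windows and time grid (seconds, target onset at 0)
    delay_window: tuple[float, float] = (-1.0, 0.0)
    baseline_window: tuple[float, float] = (-4.0, -3.0)
    time_start: float = -4.0
    time_stop: float = 0.25
    time_step: float = 0.25
    # spectral band and decoding
    band: tuple[float, float] = (8.0, 13.0)
    folds: int = 6
    ridge: float = 0.0
    # behavior
    flanker_base_cost_ms: float = 80.0
    flanker_depth_slope_ms: float = -80.0
    rt_base_ms: float = 500.0
    rt_noise_sd_ms: float = 40.0
    behavior_metric: str = "cohens_d"  # or "delta_rt"
    # statistics
    n_permutations: int = 1000
    cell_alpha: float = 0.05

    def time_bins(self) -> np.ndarray:
        n = int(round((self.time_stop - self.time_start) / self.time_step)) + 1
        return self.time_start + np.arange(n) * self.time_step

    def to_yaml(self, path=None) -> str:
        doc = yaml.safe_dump(_plain(dataclasses.asdict(self)), sort_keys=True)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {
            f.name: tuple(raw[f.name]) if isinstance(raw.get(f.name), list) else raw[f.name]
            for f in dataclasses.fields(cls)
            if f.name in raw
        }
        return cls(**kwargs)

    def hash(self) -> str:
        """Hash of the scientific parameters (the output path does not count)."""
        doc = {k: v for k, v in _plain(dataclasses.asdict(self)).items() if k != "out_dir"}
        return hashlib.sha256(yaml.safe_dump(doc, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline under one config; returns the run directory.

    Stages: cohort simulation (power mode), per-subject sixfold
    cross-validated decoding per time bin, circular alignment, then the
    delay-vs-baseline condition contrast, the across-subject
    tuning-behavior Spearman correlation with cluster inference, and the
    within-subject median-split analysis.  Any stage failure aborts with
    the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    cfg_hash = config.hash()
    config.to_yaml(out / "config.yaml")
    t0 = time.perf_counter()
    try:
        _run_stages(config, out, cfg_hash)
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        logger.info("total %.1fs", time.perf_counter() - t0)
        logger.removeHandler(handler)
        handler.close()
    return out


def _run_stages(config: RunConfig, out: Path, cfg_hash: str) -> None:
    basis = make_basis(config.n_channels)
    tb = config.time_bins()

    stage = "simulate"
    t0 = time.perf_counter()
    from .synthetic import GroundTruth  # template for shared params

    template = GroundTruth(
        mixing=np.eye(config.n_sensors, config.n_channels) + 0.01,  # replaced per subject
        baseline_power=config.baseline_power,
        noise_sd=config.noise_sd,
        delay_window=config.delay_window,
        baseline_window=config.baseline_window,
        flanker_base_cost_ms=config.flanker_base_cost_ms,
        flanker_depth_slope_ms=config.flanker_depth_slope_ms,
        rt_base_ms=config.rt_base_ms,
        rt_noise_sd_ms=config.rt_noise_sd_ms,
    )
    try:
        cohort = simulate_cohort(
            n_subjects=config.n_subjects,
            truth=template,
            seed=config.stage_seed("simulate"),
            n_trials_per_location=config.n_trials_per_location,
            n_locations=config.n_locations,
            n_sensors=config.n_sensors,
            n_channels=config.n_channels,
            time_bins=tb,
            depth_range=config.depth_range,
        )
        for s in cohort:
            atio.save_trials(s.trials, out / f"trials_{s.subject}.tsv")
        logger.info("simulate: %d subjects in %.1fs", len(cohort), time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}': {exc}") from exc

    stage = "decode"
    t0 = time.perf_counter()
    try:
        delay_curves, base_curves, maps, behavior, rows = [], [], [], [], []
        split_diffs = []
        for s in cohort:
            bp = band_power(s.power, band=config.band)  # trials x sensors x bins
            res = crossval_decode(
                bp, s.trials, basis, k=config.folds,
                seed=config.stage_seed(f"folds:{s.subject}"), ridge=config.ridge,
            )
            at = align_and_average(res, s.trials, basis)
            at.times = tb
            maps.append(at.unique_values.T)  # time x offsets
            in_delay = (tb >= config.delay_window[0]) & (tb <= config.delay_window[1])
            in_base = (tb >= config.baseline_window[0]) & (tb <= config.baseline_window[1])
            delay_curves.append(at.unique_values[:, in_delay].mean(axis=1))
            base_curves.append(at.unique_values[:, in_base].mean(axis=1))
            fx = flanker_effect(s.trials)
            behavior.append(fx.cohens_d if config.behavior_metric == "cohens_d" else fx.delta_rt_ms)
            slow, fast = median_split_tuning(res, s.trials, basis)
            split_diffs.append((fast.unique_values - slow.unique_values).T)
            for ti, tval in enumerate(tb):
                for oi, off in enumerate(at.unique_offsets_deg):
                    rows.append(
                        (s.subject, f"{tval:.3f}", f"{off:.0f}",
                         f"{at.unique_values[oi, ti]:.6g}", f"{at.sem[oi, ti]:.6g}")
                    )
        summary = pd.DataFrame(rows, columns=["subject", "time_s", "offset_deg", "mean", "sem"])
        summary.insert(0, "config_hash", cfg_hash)
        summary.to_csv(out / "tuning_summary.tsv", sep="\t", index=False)
        np.savez(
            out / "aligned_tuning.npz",
            maps=np.stack(maps), times=tb, offsets=basis.centers_deg - 180.0,
            delay_curves=np.stack(delay_curves), baseline_curves=np.stack(base_curves),
        )
        logger.info("decode: %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}': {exc}") from exc

    stage = "stats"
    t0 = time.perf_counter()
    try:
        maps = np.stack(maps)  # subjects x time x offsets
        behavior = np.asarray(behavior)
        contrast = cluster_permutation(
            np.stack(delay_curves) - np.stack(base_curves),
            n_perm=config.n_permutations, cell_alpha=config.cell_alpha,
            seed=config.stage_seed("stats:contrast"),
        )
        rho_map = spearman_map(maps, behavior)
        corr = cluster_permutation(
            maps, behavior=behavior, n_perm=config.n_permutations,
            cell_alpha=config.cell_alpha, seed=config.stage_seed("stats:corr"),
        )
        split = cluster_permutation(
            np.stack(split_diffs), n_perm=config.n_permutations,
            cell_alpha=config.cell_alpha, seed=config.stage_seed("stats:split"),
        )
        results = {
            "config_hash": cfg_hash,
            "delay_tuning_magnitude_mean": float(
                np.mean([_curve_magnitude(c) for c in delay_curves])
            ),
            "baseline_tuning_magnitude_mean": float(
                np.mean([_curve_magnitude(c) for c in base_curves])
            ),
            "delay_vs_baseline": _cluster_json(contrast),
            "tuning_behavior_correlation": _cluster_json(corr),
            "median_split_fast_vs_slow": _cluster_json(split),
            "n_significant_tuning_clusters": len(contrast.significant),
        }
        (out / "stats.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        pd.DataFrame(
            rho_map,
            index=[f"{t:.3f}" for t in tb],
            columns=[f"{o:.0f}" for o in basis.centers_deg - 180.0],
        ).to_csv(out / "spearman_map.tsv", sep="\t")
        logger.info("stats: %.1fs", time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}': {exc}") from exc


def _curve_magnitude(curve: np.ndarray) -> float:
    """Tuning magnitude of one 8-bin aligned curve ordered −180°…135°."""
    offs = np.arange(len(curve)) * (360.0 / len(curve)) - 180.0
    near = np.isin(offs, (-45.0, 0.0, 45.0))
    far = np.isin(offs, (135.0, 180.0, -180.0, -135.0))
    return float(curve[near].mean() - curve[far].mean())


def _cluster_json(result) -> dict:
    return {
        "threshold": result.threshold,
        "n_permutations": result.n_permutations,
        "clusters": [
            {"mass": c.mass, "p": c.p_value, "cells": c.cells.tolist()}
            for c in result.clusters
        ],
    }


def validate_inputs(trial_paths=(), array_paths=()) -> dict:
    """Schema-conformity report for user-supplied tables and archives.

    Checks trial-table columns and array-archive keys, and warns (rather
    than errors) on unbalanced location counts.  All violations are
    enumerated; inputs are never mutated.
    """
    errors, warnings_ = [], []
    for p in trial_paths:
        try:
            df = pd.read_csv(p, sep="\t")
        except Exception as exc:
            errors.append(f"{p}: unreadable ({exc})")
            continue
        missing = [c for c in atio.TRIAL_COLUMNS if c not in df.columns]
        if missing:
            errors.append(f"{p}: missing columns {missing}")
        if "location" in df.columns:
            counts = df["location"].value_counts()
            if counts.nunique() > 1:
                warnings_.append(f"{p}: unbalanced locations (counts {sorted(set(counts))})")
        if "angle_deg" in df.columns and "location" in df.columns:
            step = 360.0 / max(df["location"].nunique(), 1)
            bad = np.abs(df["angle_deg"] - df["location"] * step) > 1e-6
            if bad.any():
                errors.append(f"{p}: {int(bad.sum())} rows where angle_deg != location*{step:.4g}")
    for p in array_paths:
        try:
            with np.load(p) as z:
                keys = set(z.files)
        except Exception as exc:
            errors.append(f"{p}: unreadable ({exc})")
            continue
        if not ({"data", "fs", "times"} <= keys or {"power", "freqs", "times"} <= keys):
            errors.append(
                f"{p}: keys {sorted(keys)} match neither epochs (data/fs/times) "
                "nor power (power/freqs/times) schema"
            )
    return {"errors": errors, "warnings": warnings_, "ok": not errors}
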