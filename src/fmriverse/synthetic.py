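"""Seeded synthetic inputs for the pipeline-variability analyses.

Everything the pipeline consumes is generated here at toy scale: BIDS-style
event tables for an event-related design with parametric modulation (and a
paired average-activity condition), a 10 s block design, and a multi-basis
repeated-measures design; multi-subject BOLD volumes with known per-voxel
effects, low-frequency drift, motion-coupled nuisance and AR(1) noise; and
ensembles of group-level z maps with a controlled mean pairwise correlation.

The generators emulate the statistical structure of preprocessed task-fMRI
data — they do not simulate acquisition physics, distortion, or
registration error.  Every generator is a pure function of its config and
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import DesignError, EventTable, HrfSpec, build_signal_regressors
from .glm import StatMap

__all__ = [
    "SyntheticConfig",
    "ZmapEnsembleConfig",
    "DatasetBundle",
    "default_effect_map",
    "generate_event_table",
    "generate_group_bold",
    "generate_correlated_zmaps",
]


class SyntheticError(ValueError):
    pass


#: graded blob amplitudes of the default ground-truth map: the strong blobs
#: sit firmly above the group detection threshold at the default noise level,
#: the weak ones straddle it — which is what makes cluster-survival and
#: thresholding-amplification phenomena reproducible on synthetic data
DEFAULT_BLOB_AMPLITUDES = (1.0, 0.7, 0.5, 0.35, 0.08, 0.055)


def default_effect_map(grid_shape: tuple[int, int, int], amplitude: float = 1.0) -> np.ndarray:
    """Ground-truth effect map: six cubic blobs with graded amplitudes."""
    eff = np.zeros(grid_shape)
    nx, ny, nz = grid_shape
    size = max(2, min(grid_shape) // 5)
    centers = [
        (1, 1, 1),
        (nx - size - 1, 1, 1),
        (1, ny - size - 1, nz - size - 1),
        (nx - size - 1, ny - size - 1, nz - size - 1),
        (nx // 2 - size // 2, ny // 2 - size // 2, 1),
        (nx // 2 - size // 2, 1, nz - size - 1),
    ]
    for (cx, cy, cz), a in zip(centers, DEFAULT_BLOB_AMPLITUDES):
        eff[cx : cx + size, cy : cy + size, cz : cz + size] = a * amplitude
    return eff


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale parameters for the synthetic BOLD generator.

    Defaults mirror a small task-fMRI study at toy spatial scale: a 16^3
    voxel grid, TR 2 s, 160 volumes and 15 subjects, innovation SD 1 with
    lag-1 autocorrelation 0.4, weak multi-component drift and small
    motion-coupled nuisance.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    tr: float = 2.0
    n_volumes: int = 160
    n_subjects: int = 15
    effect_map: np.ndarray | None = None
    noise_sd: float = 1.0
    ar_coefficient: float = 0.4
    drift_amplitudes: tuple[float, ...] = (0.5, 0.3)
    motion_sd: float = 0.05
    subject_gain_sd: float = 0.3  # between-subject spread of response gain
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise SyntheticError("grid_shape entries must be positive")
        if not 0 <= self.ar_coefficient < 1:
            raise SyntheticError("ar_coefficient must be in [0, 1)")
        if self.tr <= 0 or self.n_volumes <= 0 or self.n_subjects <= 0:
            raise SyntheticError("tr, n_volumes and n_subjects must be positive")
        if self.noise_sd < 0 or self.motion_sd < 0 or self.subject_gain_sd < 0:
            raise SyntheticError("noise_sd, motion_sd and subject_gain_sd must be non-negative")

    def resolved_effect_map(self) -> np.ndarray:
        eff = self.effect_map
        if eff is None:
            return default_effect_map(self.grid_shape)
        eff = np.asarray(eff, dtype=float)
        if eff.shape != tuple(self.grid_shape):
            raise SyntheticError(
                f"effect_map shape {eff.shape} does not match grid {self.grid_shape}"
            )
        return eff


@dataclass(frozen=True)
class ZmapEnsembleConfig:
    """Ensemble of equicorrelated group-level z maps across k pipelines."""

    k: int = 26
    rho_bar: float = 0.7
    grid_shape: tuple[int, ...] = (16, 16, 16)
    effect_map: np.ndarray | None = None
    mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise SyntheticError("k must be >= 2")
        if not 0 <= self.rho_bar <= 1:
            raise SyntheticError("rho_bar must be in [0, 1]")


@dataclass
class DatasetBundle:
    """Per-subject BOLD volumes plus everything needed to analyse them."""

    subjects: list[np.ndarray]  # each (nx, ny, nz, n_volumes)
    events: EventTable
    motion_params: list[np.ndarray]  # each (n_volumes, 6)
    tr: float
    mask: np.ndarray
    ground_truth: dict
    kind: Literal["ds1_like", "ds109_like", "ds120_like"] = "ds1_like"

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.subjects}
        if len(shapes) != 1:
            raise SyntheticError("subjects must share one grid")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def frame_times(self) -> np.ndarray:
        n = self.subjects[0].shape[-1]
        return np.arange(n) * self.tr

    def save_ground_truth(self, path: str | Path) -> None:
        gt = dict(self.ground_truth)
        gt["effect_map"] = np.asarray(gt["effect_map"]).tolist()
        Path(path).write_text(json.dumps(gt))


def generate_event_table(
    design_kind: Literal["event_related", "block"],
    n_events: int,
    tr: float,
    n_volumes: int,
    seed: int = 0,
) -> EventTable:
    """Generate a task event table that fits inside the scan.

    Block designs alternate two conditions in 10 s blocks.  Event-related
    designs emit, per trial, a unit ``task_average`` event and a
    ``task_modulated`` event at the same onset whose modulation column holds
    a response-time-like value — the structure that makes modulated-versus-
    average orthogonalization meaningful.
    """
    if n_events < 1:
        raise SyntheticError("n_events must be >= 1")
    total = tr * n_volumes
    rng = np.random.default_rng(seed)
    if design_kind == "block":
        duration = 10.0
        lead = 2 * tr
        spacing = (total - lead) / n_events
        if spacing < duration + tr:
            raise DesignError(
                f"design does not fit: {n_events} blocks of {duration}s do not fit "
                f"in a {total}s scan"
            )
        onsets = lead + spacing * np.arange(n_events)
        conditions = ["belief" if i % 2 == 0 else "photo" for i in range(n_events)]
        df = pd.DataFrame(
            {
                "onset": onsets,
                "duration": duration,
                "condition": conditions,
                "modulation": np.nan,
            }
        )
        return EventTable(df)
    if design_kind != "event_related":
        raise SyntheticError(f"unknown design kind {design_kind!r}")
    lead = 3 * tr
    tail = 16.0  # let the response decay inside the scan
    window = total - lead - tail
    if window < n_events * tr:
        raise DesignError(
            f"design does not fit: {n_events} events do not fit in a {total}s scan"
        )
    slots = lead + window * np.arange(n_events) / n_events
    onsets = slots + rng.uniform(0, 0.5 * window / n_events, size=n_events)
    onsets.sort()
    rts = rng.uniform(0.8, 2.5, size=n_events)  # response-time-like modulators
    rows = []
    for onset, rt in zip(onsets, rts):
        rows.append((onset, 1.0, "task_average", np.nan))
        rows.append((onset, 1.0, "task_modulated", rt))
    df = pd.DataFrame(rows, columns=["onset", "duration", "condition", "modulation"])
    return EventTable(df)


def _ar1_series(rng: np.random.Generator, shape: tuple[int, ...], phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with innovation SD ``sd``."""
    eps = rng.standard_normal(shape) * sd
    if phi == 0:
        return eps
    out = np.empty(shape)
    out[..., 0] = eps[..., 0] / np.sqrt(1 - phi**2)  # stationary start
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + eps[..., t]
    return out


def _smooth_random_walks(rng: np.random.Generator, n: int, k: int, sd: float) -> np.ndarray:
    """k smooth random walks of length n (motion-parameter surrogates)."""
    steps = rng.standard_normal((n, k)) * sd
    walks = np.cumsum(steps, axis=0)
    return ndimage.uniform_filter1d(walks, size=5, axis=0, mode="nearest")


def generate_group_bold(
    config: SyntheticConfig,
    events: EventTable,
    hrf: HrfSpec | None = None,
    kind: Literal["ds1_like", "ds109_like", "ds120_like"] = "ds1_like",
) -> DatasetBundle:
    """Simulate per-subject 4-D BOLD volumes with a known ground truth.

    Each subject's series is ``effect_map x task regressor + drift +
    motion-coupled nuisance + AR(1) noise``.  The task regressor is the
    HRF-convolved regressor of the bundle's truth condition (the modulated
    condition when one exists, the first condition otherwise).  Motion
    nuisance enters through six smooth random walks coupled to fixed spatial
    loading maps; the walks themselves are returned as the motion
    regressors.
    """
    hrf = hrf or HrfSpec.preset("S")
    effect = config.resolved_effect_map()
    frame_times = np.arange(config.n_volumes) * config.tr
    if events.end_time > frame_times[-1] + config.tr:
        raise DesignError("events do not fit inside the scan")
    regressors = build_signal_regressors(events, hrf, frame_times)
    modulated = [
        c
        for c in events.conditions
        if np.isfinite(
            events.table.loc[events.table["condition"] == c, "modulation"]
        ).all()
    ]
    truth_condition = modulated[0] if modulated else events.conditions[0]
    task = regressors[truth_condition].to_numpy()

    rng = np.random.default_rng(config.seed)
    n_t = config.n_volumes
    subjects: list[np.ndarray] = []
    motion_params: list[np.ndarray] = []
    # slow scanner drift: periods of 240 s and up, within reach of all the
    # standard high-pass/detrending drift models
    drift_periods = 240.0 * (1 + np.arange(len(config.drift_amplitudes)))
    subject_seeds = rng.integers(0, 2**31 - 1, size=config.n_subjects)
    for s_seed in subject_seeds:
        srng = np.random.default_rng(s_seed)
        vol = np.empty((*config.grid_shape, n_t))
        # task signal with a per-subject response gain (between-subject
        # variance component; gains are kept non-negative)
        gain = max(0.0, 1.0 + config.subject_gain_sd * srng.standard_normal())
        vol[:] = gain * effect[..., None] * task[None, None, None, :]
        # low-frequency drift: shared temporal shape, per-voxel loading
        drift_t = np.zeros(n_t)
        for amp, period in zip(config.drift_amplitudes, drift_periods):
            phase = srng.uniform(0, 2 * np.pi)
            drift_t += amp * np.cos(2 * np.pi * frame_times / period + phase)
        drift_load = srng.uniform(0.5, 1.5, size=config.grid_shape)
        vol += drift_load[..., None] * drift_t[None, None, None, :]
        # motion nuisance through fixed spatial loadings
        walks = _smooth_random_walks(srng, n_t, 6, config.motion_sd)
        loadings = srng.standard_normal((*config.grid_shape, 6))
        loadings = ndimage.gaussian_filter(loadings, sigma=(2, 2, 2, 0))
        vol += np.einsum("xyzk,tk->xyzt", loadings, walks)
        # AR(1) noise
        vol += _ar1_series(
            srng, (*config.grid_shape, n_t), config.ar_coefficient, config.noise_sd
        )
        subjects.append(vol)
        motion_params.append(walks)

    ground_truth = {
        "effect_map": effect,
        "truth_condition": truth_condition,
        "subject_seeds": [int(s) for s in subject_seeds],
        "seed": config.seed,
        "ar_coefficient": config.ar_coefficient,
        "noise_sd": config.noise_sd,
    }
    return DatasetBundle(
        subjects=subjects,
        events=events,
        motion_params=motion_params,
        tr=config.tr,
        mask=np.ones(config.grid_shape, dtype=bool),
        ground_truth=ground_truth,
        kind=kind,
    )


def generate_correlated_zmaps(config: ZmapEnsembleConfig) -> list[StatMap]:
    """k z maps equicorrelated at ``rho_bar`` on a shared grid.

    Construction: ``z_i = sqrt(rho) * shared + sqrt(1 - rho) * unique_i +
    effect``, which has exactly the target pairwise correlation in
    expectation and unit marginal variance under the null.
    """
    shape = tuple(config.grid_shape)
    mask = (
        np.ones(shape, dtype=bool)
        if config.mask is None
        else np.asarray(config.mask, dtype=bool)
    )
    if mask.shape != shape:
        raise SyntheticError("mask shape does not match grid")
    effect = np.zeros(shape) if config.effect_map is None else np.asarray(config.effect_map)
    if effect.shape != shape:
        raise SyntheticError("effect_map shape does not match grid")
    rng = np.random.default_rng(config.seed)
    shared = rng.standard_normal(shape)
    rho = config.rho_bar
    maps = []
    for _ in range(config.k):
        unique = rng.standard_normal(shape)
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * unique + effect
        maps.append(StatMap(np.where(mask, z, 0.0), "z", None, mask))
    return maps
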