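"""Synthetic 4D fMRI generator with ground-truth percepts.

No imaging data ships with the method, so every downstream stage is
exercised on simulated runs that carry the statistical structure the
method assumes: category-selective regions (face-preferring FFA/OFA,
house-preferring PPA) whose BOLD response follows the block design (BNR)
or the stochastically alternating conscious percept (BR), on top of a
constant baseline, polynomial scanner drift and i.i.d. Gaussian noise.

The generator emits the ground truth (per-time-point percept/condition and
the planted region masks); only tests may compare pipeline output against
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.stats import gamma as gamma_dist

from .paradigm import (
    BehavioralLog,
    BlockDesign,
    bnr_design,
    br_design,
    condition_labels,
)

__all__ = [
    "Region",
    "SimConfig",
    "SimulatedRun",
    "canonical_hrf",
    "simulate_bnr",
    "simulate_rivalry_phases",
    "simulate_br",
    "simulate_subject",
    "default_regions",
]

#: number of slices covered by the rivalry acquisition (the "package")
BR_SLICES = 16
#: first localizer-grid slice inside the rivalry package
BR_Z_OFFSET = 7


@dataclass(frozen=True)
class Region:
    """A planted category-selective region on the localizer grid."""

    label: str
    slices: tuple  # (xslice, yslice, zslice) on the BNR grid
    preferred: str  # 'face' or 'house'
    amplitude_pct: float  # peak % signal change of the preferred response


def default_regions(amplitude_pct: float = 2.0) -> tuple[Region, ...]:
    """Five regions mirroring the typical localizer outcome: bilateral PPA
    (house-preferring), bilateral FFA and one OFA (face-preferring), all
    inside the 16-slice rivalry package."""
    a = amplitude_pct
    z = BR_Z_OFFSET
    return (
        Region("FFA_r", (slice(13, 16), slice(5, 8), slice(z + 4, z + 7)), "face", a),
        Region("FFA_l", (slice(4, 7), slice(5, 8), slice(z + 4, z + 7)), "face", 0.9 * a),
        Region("OFA_r", (slice(13, 16), slice(12, 15), slice(z + 9, z + 12)), "face", 0.8 * a),
        Region("PPA_r", (slice(12, 15), slice(8, 11), slice(z + 2, z + 5)), "house", a),
        Region("PPA_l", (slice(5, 8), slice(8, 11), slice(z + 2, z + 5)), "house", 0.95 * a),
    )


@dataclass
class SimConfig:
    """Parameters of a simulated subject.

    Defaults are the study conditions of the experiment being emulated:
    a 3 mm isotropic grid, ~1-3% stimulus-locked signal change, gamma
    dominance phases with mean 3.4 s, and a baseline of 1000 a.u. so
    percent-signal-change arithmetic is well conditioned.
    """

    grid: tuple = (20, 20, 30)  # localizer grid; BR covers its central slices
    voxel_size_mm: float = 3.0
    regions: tuple = field(default_factory=default_regions)
    baseline: float = 1000.0
    noise_sd_pct: float = 1.0  # per-voxel Gaussian noise SD as % of baseline
    #: SD of spontaneous fluctuations shared by all voxels of a region, % of
    #: baseline.  Coherent physiological noise survives ROI averaging (unlike
    #: the i.i.d. term) and is what gives rest-block signals realistic
    #: amplitude at the ROI level.
    region_noise_sd_pct: float = 0.5
    drift_coeffs: tuple = (0.0, 3.0)  # polynomial in normalized time, a.u.
    phase_mean_s: float = 3.4
    phase_shape: float = 3.0  # gamma shape; right-skewed like rivalry phases
    bold_delay_s: float = 6.0
    reaction_delay_s: float = 0.0
    #: False emulates a subject who does not experience rivalry: the BR-run
    #: regional signal is not locked to the reported percept
    br_percept_locked: bool = True
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["regions"] = [
            {
                "label": r.label,
                "slices": [[s.start, s.stop] for s in r.slices],
                "preferred": r.preferred,
                "amplitude_pct": r.amplitude_pct,
            }
            for r in self.regions
        ]
        return json.dumps(d, indent=1)


@dataclass
class SimulatedRun:
    """A simulated 4D run plus its design, ground truth and region masks."""

    volumes: np.ndarray  # (x, y, z, t)
    design: BlockDesign
    truth: np.ndarray  # per-task-time-point condition/percept labels
    masks: dict  # label -> boolean 3D array on this run's grid
    z_offset: int = 0  # slice offset of this grid within the localizer grid

    def save(self, nifti_path, sidecar_path=None, voxel_size_mm: float = 3.0):
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.volumes.astype(np.float32), affine), str(nifti_path))
        if sidecar_path is not None:
            payload = {
                "task_name": self.design.task_name,
                "tr": self.design.tr,
                "truth": list(self.truth),
                "z_offset": self.z_offset,
                "masks": {k: np.flatnonzero(v.ravel()).tolist() for k, v in self.masks.items()},
                "grid": list(self.volumes.shape[:3]),
            }
            Path(sidecar_path).write_text(json.dumps(payload))


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at ``tr``, peak-normalized.

    Standard parameterization: response peak near 5-6 s, undershoot near
    15 s with 1/6 relative amplitude.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0, duration_s, tr)
    peak = gamma_dist.pdf(t, a=6, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _convolve_to_length(indicator: np.ndarray, hrf: np.ndarray) -> np.ndarray:
    return np.convolve(indicator, hrf)[: len(indicator)]


def _drift(cfg: SimConfig, n: int) -> np.ndarray:
    x = np.linspace(-1, 1, n)
    return sum(c * x ** (i + 1) for i, c in enumerate(cfg.drift_coeffs)) if cfg.drift_coeffs else np.zeros(n)


def _assemble(cfg: SimConfig, design: BlockDesign, responses: list, grid, z_offset: int, rng) -> np.ndarray:
    """Baseline x (1 + regional response) + drift + noise, per voxel."""
    n = design.n_volumes
    vols = np.empty(grid + (n,), dtype=np.float64)
    vols[...] = cfg.baseline
    for region, resp in responses:
        coherent = (
            rng.normal(0.0, cfg.region_noise_sd_pct, size=n)
            if cfg.region_noise_sd_pct > 0
            else 0.0
        )
        xs, ys, zs = region.slices
        zs = slice(zs.start - z_offset, zs.stop - z_offset)
        if zs.start < 0 or zs.stop > grid[2]:
            continue  # region outside this acquisition's slice coverage
        vols[xs, ys, zs, :] = cfg.baseline * (1.0 + (resp + coherent) / 100.0)
    vols += _drift(cfg, n)
    if cfg.noise_sd_pct > 0:
        vols += rng.normal(0.0, cfg.baseline * cfg.noise_sd_pct / 100.0, size=vols.shape)
    return vols


def _region_masks(cfg: SimConfig, grid, z_offset: int) -> dict:
    masks = {}
    for r in cfg.regions:
        m = np.zeros(grid, dtype=bool)
        xs, ys, zs = r.slices
        zs = slice(zs.start - z_offset, zs.stop - z_offset)
        if 0 <= zs.start and zs.stop <= grid[2]:
            m[xs, ys, zs] = True
        masks[r.label] = m
    return masks


def simulate_bnr(cfg: SimConfig, design: BlockDesign | None = None) -> SimulatedRun:
    """Simulate the localizer run on the full 30-slice grid.

    Each region responds to its preferred condition's boxcar convolved with
    the canonical HRF, scaled to ``amplitude_pct`` percent of baseline.
    """
    design = design or bnr_design()
    rng = np.random.default_rng(cfg.seed)
    hrf = canonical_hrf(design.tr)
    labels = condition_labels(design)
    responses = []
    for region in cfg.regions:
        boxcar = (labels == region.preferred).astype(float)
        responses.append((region, region.amplitude_pct * _convolve_to_length(boxcar, hrf)))
    vols = _assemble(cfg, design, responses, cfg.grid, 0, rng)
    truth = labels[labels != "rest"]
    return SimulatedRun(vols, design, truth, _region_masks(cfg, cfg.grid, 0), z_offset=0)


def simulate_rivalry_phases(mean_s: float, shape: float, total_task_s: float, seed) -> list:
    """Alternating (percept, duration) dominance phases covering ``total_task_s``.

    Durations are i.i.d. gamma with the given mean and shape; the last phase
    is truncated so the sequence tiles the task time exactly.  The first
    percept is a fair coin.
    """
    if mean_s <= 0:
        raise ValueError("mean phase duration must be positive")
    rng = np.random.default_rng(seed)
    percept = "face" if rng.random() < 0.5 else "house"
    phases = []
    t = 0.0
    while t < total_task_s:
        d = float(rng.gamma(shape, mean_s / shape))
        d = min(d, total_task_s - t)
        if d > 1e-9:
            phases.append((percept, d))
        t += d
        percept = "house" if percept == "face" else "face"
    return phases


def _phases_to_task_seconds(phases, total_task_s: int) -> np.ndarray:
    """Percept label for each whole task second [0, total_task_s)."""
    out = np.empty(total_task_s, dtype=object)
    t = 0.0
    for percept, dur in phases:
        lo, hi = int(np.ceil(t - 1e-9)), int(np.ceil(t + dur - 1e-9))
        out[lo:min(hi, total_task_s)] = percept
        t += dur
    return out


def simulate_br(cfg: SimConfig, phases, design: BlockDesign | None = None):
    """Simulate the rivalry run (16-slice package) plus its behavioral log.

    Region responses follow a percept indicator — 1 whenever the region's
    preferred stimulus is consciously dominant during a picture block, else
    0 — convolved with the HRF.  The behavioral log has one event per phase
    onset, mapped from task time back to run time, optionally delayed by a
    reaction-time offset.
    """
    design = design or br_design()
    rng = np.random.default_rng(cfg.seed + 1)
    hrf = canonical_hrf(design.tr)
    labels = condition_labels(design)
    task_idx = np.flatnonzero(labels != "rest")
    n_task = len(task_idx)
    task_seconds_per_vol = int(round(design.tr))
    truth = _phases_to_task_seconds(phases, n_task * task_seconds_per_vol)[::task_seconds_per_vol]

    # run-time indicator of each percept, zero during rest
    indicator = {p: np.zeros(design.n_volumes) for p in ("face", "house")}
    for j, vol in enumerate(task_idx):
        if truth[j] is not None:
            indicator[truth[j]][vol] = 1.0

    grid = cfg.grid[:2] + (BR_SLICES,)
    amp = 1.0 if cfg.br_percept_locked else 0.0
    responses = [
        (region, amp * region.amplitude_pct * _convolve_to_length(indicator[region.preferred], hrf))
        for region in cfg.regions
    ]
    vols = _assemble(cfg, design, responses, grid, BR_Z_OFFSET, rng)
    run = SimulatedRun(vols, design, truth, _region_masks(cfg, grid, BR_Z_OFFSET), z_offset=BR_Z_OFFSET)

    # behavioral log: map phase onsets (task seconds) to run seconds
    task_to_run = {}
    s = 0
    for vol in task_idx:
        for k in range(task_seconds_per_vol):
            task_to_run[s] = vol * design.tr + k
            s += 1
    events = []
    t = 0.0
    for percept, dur in phases:
        onset_s = min(int(np.ceil(t - 1e-9)), len(task_to_run) - 1)
        run_t = task_to_run[onset_s] + cfg.reaction_delay_s
        if not events or run_t > events[-1][0]:
            events.append((run_t, percept))
        t += dur
    return run, BehavioralLog(tuple(events))


def simulate_subject(cfg: SimConfig):
    """Simulate one subject: BNR run, rivalry phases, BR run and behavioral log."""
    bnr = simulate_bnr(cfg)
    design = br_design()
    n_task_s = sum(b.duration for b in design.blocks if b.condition != "rest")
    phases = simulate_rivalry_phases(cfg.phase_mean_s, cfg.phase_shape, n_task_s, cfg.seed + 2)
    br, log = simulate_br(cfg, phases, design)
    return bnr, br, log, phases
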