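"""ROI time-course preparation: the chain that turns raw voxel intensities
into the network's input matrix.

Order of operations per run:

1. cubic detrend of every ROI voxel and of the whole-brain mean (drift
   removal; the temporal mean is preserved so percent change stays defined);
2. rivalry run only: k-means (k=2) on each ROI's detrended voxel time
   courses, keeping the cluster that tracks the ROI mean — the voxels
   participating in the activation pattern;
3. average the retained voxels per ROI;
4. percent signal change of each ROI mean and of the whole-brain mean;
5. subtract the whole-brain percent change from each ROI (global nuisance);
6. shift by the hemodynamic delay so responses align with block labels;
7. drop rest-block time points, keeping them separately as the negative
   control signal;
8. quadratic detrend of the concatenated task (and rest) segments.

The localizer (BNR) branch additionally emits one-hot targets — row (1 0)
for face volumes, (0 1) for house volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .paradigm import BlockDesign, condition_labels

__all__ = [
    "RoiTimecourses",
    "PreparedInputs",
    "detrend_poly",
    "kmeans_select_voxels",
    "percent_signal_change",
    "global_subtract",
    "bold_shift",
    "split_task_rest",
    "prepare_inputs",
    "extract_timecourses",
]


@dataclass
class RoiTimecourses:
    """Raw per-voxel ROI time courses plus the whole-brain mean, one run."""

    roi_matrices: list      # per ROI: (n_voxels, T) raw intensities
    roi_names: list
    brain_mean: np.ndarray  # (T,)
    tr: float
    design: BlockDesign

    def __post_init__(self):
        T = self.design.n_volumes
        if len(self.brain_mean) != T or any(m.shape[1] != T for m in self.roi_matrices):
            raise ValueError("all time courses must have one sample per volume")


@dataclass
class PreparedInputs:
    """Network-ready matrices: task rows x ROI columns, plus the rest-block
    control matrix and (localizer only) one-hot targets."""

    task_matrix: np.ndarray        # (n_task, n_rois), percent-change residuals
    rest_matrix: np.ndarray        # (n_rest, n_rois)
    roi_names: list
    stage: str                     # 'BNR' or 'BR'
    target_matrix: np.ndarray | None = None   # (n_task, 2) one-hot, BNR only
    retained_voxels: dict = field(default_factory=dict)

    @property
    def n_rois(self) -> int:
        return self.task_matrix.shape[1]

    def subset(self, k: int) -> "PreparedInputs":
        """First k ROI columns (ROIs are ordered by peak t upstream)."""
        return PreparedInputs(
            task_matrix=self.task_matrix[:, :k],
            rest_matrix=self.rest_matrix[:, :k],
            roi_names=self.roi_names[:k],
            stage=self.stage,
            target_matrix=self.target_matrix,
            retained_voxels={n: v for n, v in self.retained_voxels.items() if n in self.roi_names[:k]},
        )


def detrend_poly(series: np.ndarray, degree: int, keep_mean: bool = False) -> np.ndarray:
    """Residuals of a least-squares polynomial fit over the time index.

    With ``keep_mean=True`` the series' temporal mean is added back, so only
    the drift shape is removed — required upstream of percent signal change.
    Works on 1-D series or (n_series, T) matrices.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    T = x.shape[1]
    if T <= degree + 1:
        raise ValueError(f"series of length {T} too short for degree-{degree} detrend")
    t = np.linspace(-1, 1, T)
    V = np.vander(t, degree + 1)
    coef, _, _, _ = np.linalg.lstsq(V, x.T, rcond=None)
    resid = x - (V @ coef).T
    if keep_mean:
        resid = resid + x.mean(axis=1, keepdims=True)
    return resid[0] if squeeze else resid


def kmeans_select_voxels(roi_matrix: np.ndarray, k: int = 2, seed: int = 0, n_init: int = 10):
    """Split an ROI's voxel time courses in two clusters and keep the coherent one.

    Lloyd's algorithm (``n_init`` restarts, best within-cluster sum of
    squares).  The retained cluster is the one whose centroid has the higher
    absolute Pearson correlation with the ROI's mean time course, i.e. the
    ensemble participating in the activation pattern; the other cluster is
    treated as noise and dropped.  Always retains at least one voxel.
    Returns (indices of retained voxels, fitted inertia).
    """
    X = np.asarray(roi_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 voxels")
    if np.allclose(X, X[0]):
        warnings.warn("all voxel time courses identical; retaining all", stacklevel=2)
        return np.arange(X.shape[0]), 0.0
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6)
    labels = km.fit_predict(X)
    mean_tc = X.mean(axis=0)
    best_lab, best_r = None, -np.inf
    for lab in range(k):
        centroid = km.cluster_centers_[lab]
        if np.std(centroid) == 0 or np.std(mean_tc) == 0:
            r = 0.0
        else:
            r = abs(np.corrcoef(centroid, mean_tc)[0, 1])
        if r > best_r:
            best_lab, best_r = lab, r
    retained = np.flatnonzero(labels == best_lab)
    if len(retained) == 0:  # pathological: fall back to everything
        retained = np.arange(X.shape[0])
    return retained, float(km.inertia_)


def percent_signal_change(series: np.ndarray) -> np.ndarray:
    """100 * (x - temporal mean) / temporal mean."""
    x = np.asarray(series, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    if np.any(np.abs(mu) < 1e-12):
        raise ValueError("percent signal change undefined for zero-mean series")
    return 100.0 * (x - mu) / mu


def global_subtract(roi_psc: np.ndarray, brain_psc: np.ndarray) -> np.ndarray:
    """Remove non-task-related global fluctuations: ROI minus whole-brain PSC."""
    a, b = np.asarray(roi_psc, dtype=float), np.asarray(brain_psc, dtype=float)
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("length mismatch between ROI and whole-brain series")
    return a - b


def bold_shift(series: np.ndarray, tr: float, delay_s: float) -> np.ndarray:
    """Undo the hemodynamic delay, rounded to whole samples.

    The BOLD response lags the stimulus by ``delay_s``, so the measured
    sample at ``t`` belongs with the stimulus label at ``t - delay``;
    advancing the series by ``s = round(delay_s / tr)`` samples
    (``out[t] = in[t + s]``) aligns response with labels.  The last ``s``
    samples replicate the final value (no zeros injected into
    percent-change units).  Length is preserved.
    """
    if delay_s < 0:
        raise ValueError("delay must be non-negative")
    x = np.asarray(series, dtype=float)
    s = int(round(delay_s / tr))
    if s >= x.shape[-1]:
        raise ValueError(f"shift of {s} samples exceeds series length {x.shape[-1]}")
    if s == 0:
        return x.copy()
    out = np.empty_like(x)
    out[..., :-s] = x[..., s:]
    out[..., -s:] = x[..., -1:]
    return out


def split_task_rest(series: np.ndarray, design: BlockDesign):
    """Partition a per-volume series into task and rest samples, order kept."""
    x = np.asarray(series, dtype=float)
    if x.shape[-1] != design.n_volumes:
        raise ValueError("series length does not match design")
    labels = condition_labels(design)
    rest = labels == "rest"
    return x[..., ~rest], x[..., rest]


def _one_hot_targets(design: BlockDesign) -> np.ndarray:
    labels = condition_labels(design)
    task = labels[labels != "rest"]
    targets = np.zeros((len(task), 2))
    targets[task == "face", 0] = 1.0
    targets[task == "house", 1] = 1.0
    return targets


def prepare_inputs(
    tcs: RoiTimecourses,
    stage: str,
    bold_delay_s: float = 6.0,
    kmeans_seed: int = 0,
) -> PreparedInputs:
    """Run the full preparation chain on one run's ROI time courses."""
    if stage not in ("BNR", "BR"):
        raise ValueError("stage must be 'BNR' or 'BR'")
    design = tcs.design
    brain = detrend_poly(tcs.brain_mean, 3, keep_mean=True)
    brain_psc = percent_signal_change(brain)

    cols_task, cols_rest = [], []
    retained_voxels = {}
    for name, roi_matrix in zip(tcs.roi_names, tcs.roi_matrices):
        vox = detrend_poly(roi_matrix, 3, keep_mean=True)
        if stage == "BR" and vox.shape[0] >= 2:
            idx, _ = kmeans_select_voxels(vox - vox.mean(axis=1, keepdims=True), seed=kmeans_seed)
        else:
            idx = np.arange(vox.shape[0])
        retained_voxels[name] = idx
        roi_mean = vox[idx].mean(axis=0)
        sig = global_subtract(percent_signal_change(roi_mean), brain_psc)
        sig = bold_shift(sig, design.tr, bold_delay_s)
        task, rest = split_task_rest(sig, design)
        cols_task.append(detrend_poly(task, 2))
        cols_rest.append(detrend_poly(rest, 2) if len(rest) else rest)

    task_matrix = np.column_stack(cols_task)
    rest_matrix = np.column_stack(cols_rest) if cols_rest and len(cols_rest[0]) else np.empty((0, len(cols_task)))
    targets = _one_hot_targets(design) if stage == "BNR" else None
    return PreparedInputs(
        task_matrix=task_matrix,
        rest_matrix=rest_matrix,
        roi_names=list(tcs.roi_names),
        stage=stage,
        target_matrix=targets,
        retained_voxels=retained_voxels,
    )


def extract_timecourses(volumes: np.ndarray, roiset, design: BlockDesign, z_offset: int = 0) -> RoiTimecourses:
    """Pull raw voxel time courses for each ROI plus the whole-brain mean.

    ROI voxel coordinates live on the localizer grid; ``z_offset`` maps them
    onto this run's slice range (the rivalry acquisition covers a subset of
    the localizer slices).
    """
    mats, names = [], []
    for i, roi in enumerate(roiset.rois):
        rows = []
        for (x, y, z) in roi.voxels:
            zz = z - z_offset
            if 0 <= zz < volumes.shape[2]:
                rows.append(volumes[x, y, zz, :])
        if not rows:
            raise ValueError(f"ROI {i} has no voxels inside this acquisition")
        mats.append(np.asarray(rows))
        names.append(f"roi{i}_{roi.contrast}")
    brain = volumes.reshape(-1, volumes.shape[-1]).mean(axis=0)
    return RoiTimecourses(roi_matrices=mats, roi_names=names, brain_mean=brain, tr=design.tr, design=design)
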