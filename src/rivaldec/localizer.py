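"""Single-subject GLM localizer and ROI selection.

The localizer run is smoothed, fitted voxelwise with an ordinary
least-squares GLM (face and house boxcars convolved with the canonical HRF,
plus intercept and linear drift), and thresholded on the two directional
t-contrasts face>house and house>face.  Family-wise error control is
Bonferroni over in-mask voxels; the fallback is Benjamini-Hochberg FDR.
Surviving voxels are clustered with 6-connectivity, clusters below the
minimum size are dropped, and at most three clusters per contrast — the
highest peak-t ones — become the regions of interest whose time courses
feed the decoder.  A subject yielding fewer than one face-contrast and two
house-contrast ROIs even at FDR is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .paradigm import BlockDesign, condition_labels
from .simgen import canonical_hrf

__all__ = [
    "GlmResult",
    "Roi",
    "RoiSet",
    "Exclusion",
    "smooth_gaussian",
    "fit_glm",
    "threshold_and_cluster",
    "select_rois",
    "localize",
    "package_mask",
]

FACE_GT_HOUSE = "face>house"
HOUSE_GT_FACE = "house>face"

#: thresholding defaults: voxelwise p<.05 corrected, clusters of >=5 voxels
ALPHA = 0.05
MIN_CLUSTER = 5


@dataclass
class GlmResult:
    beta: np.ndarray           # (x, y, z, n_regressors)
    sigma2: np.ndarray         # residual variance, (x, y, z)
    dof: int
    design_matrix: np.ndarray  # (T, n_regressors)
    regressor_names: tuple
    xtx_inv: np.ndarray

    def t_map(self, contrast) -> np.ndarray:
        """t statistic of contrast c: c'beta / sqrt(sigma2 * c'(X'X)^-1 c)."""
        c = np.asarray(contrast, dtype=float)
        eff = self.beta @ c
        var_scale = float(c @ self.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = eff / np.sqrt(self.sigma2 * var_scale)
        # numerically-zero residual variance (noiseless voxels) gives 0/0
        return np.where(self.sigma2 > 1e-16, t, 0.0)


@dataclass(frozen=True)
class Roi:
    contrast: str
    voxels: tuple           # tuple of (x, y, z) localizer-grid coordinates
    peak_t: float
    peak_coord: tuple

    @property
    def size(self) -> int:
        return len(self.voxels)

    def mask(self, grid) -> np.ndarray:
        m = np.zeros(grid, dtype=bool)
        for v in self.voxels:
            m[v] = True
        return m


@dataclass
class RoiSet:
    rois: list
    threshold_used: str  # 'FWE' or 'FDR'
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.rois)

    def top(self, k: int) -> "RoiSet":
        """The k highest-peak-t ROIs (across contrasts)."""
        order = sorted(self.rois, key=lambda r: -r.peak_t)[:k]
        return RoiSet(rois=order, threshold_used=self.threshold_used, metadata=dict(self.metadata))

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "threshold_used": self.threshold_used,
                "metadata": self.metadata,
                "rois": [
                    {
                        "contrast": r.contrast,
                        "voxels": [list(v) for v in r.voxels],
                        "peak_t": r.peak_t,
                        "peak_coord": list(r.peak_coord),
                    }
                    for r in self.rois
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RoiSet":
        import json

        d = json.loads(text)
        rois = [
            Roi(
                contrast=r["contrast"],
                voxels=tuple(tuple(v) for v in r["voxels"]),
                peak_t=r["peak_t"],
                peak_coord=tuple(r["peak_coord"]),
            )
            for r in d["rois"]
        ]
        return cls(rois=rois, threshold_used=d["threshold_used"], metadata=d.get("metadata", {}))

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "contrast": r.contrast,
                    "n_voxels": r.size,
                    "peak_t": r.peak_t,
                    "peak_x": r.peak_coord[0],
                    "peak_y": r.peak_coord[1],
                    "peak_z": r.peak_coord[2],
                }
                for r in self.rois
            ]
        )


@dataclass(frozen=True)
class Exclusion:
    """Subject-exclusion verdict: the localizer did not yield the minimum ROI set."""

    reason: str
    n_face: int
    n_house: int


def package_mask(grid, n_slices: int = 16, z_offset: int = 7) -> np.ndarray:
    """Inclusive mask restricting the localizer result to the slices covered
    by the rivalry acquisition."""
    m = np.zeros(grid, dtype=bool)
    m[:, :, z_offset : z_offset + n_slices] = True
    return m


def smooth_gaussian(volumes: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Per-volume isotropic Gaussian smoothing; sigma = FWHM / (2*sqrt(2 ln 2)).

    ``fwhm_mm = 0`` is the identity.  Boundaries use constant (nearest)
    extension so a constant image is unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return volumes
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    out = np.empty_like(volumes, dtype=float)
    for t in range(volumes.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(volumes[..., t], sigma=sigma_vox, mode="nearest")
    return out


def glm_design_matrix(design: BlockDesign, hrf=None):
    labels = condition_labels(design)
    hrf = canonical_hrf(design.tr) if hrf is None else hrf
    cols, names = [], []
    for cond in ("face", "house"):
        boxcar = (labels == cond).astype(float)
        cols.append(np.convolve(boxcar, hrf)[: design.n_volumes])
        names.append(cond)
    cols.append(np.ones(design.n_volumes))
    names.append("intercept")
    cols.append(np.linspace(-1, 1, design.n_volumes))
    names.append("drift")
    return np.column_stack(cols), tuple(names)


def fit_glm(volumes: np.ndarray, design: BlockDesign, hrf=None) -> GlmResult:
    """Voxelwise OLS of the run against [face HRF, house HRF, intercept, drift]."""
    if volumes.shape[-1] != design.n_volumes:
        raise ValueError(
            f"run has {volumes.shape[-1]} volumes but design expects {design.n_volumes}"
        )
    if design.n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    X, names = glm_design_matrix(design, hrf)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")
    grid = volumes.shape[:-1]
    Y = volumes.reshape(-1, design.n_volumes).T  # (T, V)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = design.n_volumes - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    return GlmResult(
        beta=beta.T.reshape(grid + (X.shape[1],)),
        sigma2=sigma2.reshape(grid),
        dof=dof,
        design_matrix=X,
        regressor_names=names,
        xtx_inv=xtx_inv,
    )


def _cluster(supra: np.ndarray, tmap: np.ndarray, min_cluster: int):
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labeled, n = ndimage.label(supra, structure=structure)
    clusters = []
    for i in range(1, n + 1):
        coords = np.argwhere(labeled == i)
        if len(coords) < min_cluster:
            continue
        ts = tmap[tuple(coords.T)]
        peak = int(np.argmax(ts))
        coord_list = coords.tolist()  # plain ints, JSON-safe downstream
        clusters.append(
            {
                "voxels": tuple(map(tuple, coord_list)),
                "peak_t": float(ts[peak]),
                "peak_coord": tuple(coord_list[peak]),
                "size": len(coords),
            }
        )
    # peak t descending; ties: larger cluster, then lexicographic peak coord
    clusters.sort(key=lambda c: (-c["peak_t"], -c["size"], c["peak_coord"]))
    return clusters


def threshold_and_cluster(
    tmap: np.ndarray,
    dof: int,
    method: str = "FWE",
    alpha: float = ALPHA,
    min_cluster: int = MIN_CLUSTER,
    mask: np.ndarray | None = None,
):
    """Threshold a one-sided t map with multiplicity correction, then cluster.

    FWE is Bonferroni over in-mask voxels; FDR is Benjamini-Hochberg.
    Surviving voxels are grouped by 6-connectivity and clusters smaller than
    ``min_cluster`` are discarded.  Returns clusters sorted by peak t.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    mask = np.ones(tmap.shape, dtype=bool) if mask is None else mask.astype(bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    pvals = sps.t.sf(tmap[mask], dof)  # one-sided: contrast direction is directional
    if method.upper() == "FWE":
        keep_flat = pvals < alpha / mask.sum()
    elif method.upper() == "FDR":
        m = len(pvals)
        order = np.argsort(pvals)
        ranked = pvals[order]
        below = ranked <= alpha * (np.arange(1, m + 1) / m)
        keep_flat = np.zeros(m, dtype=bool)
        if below.any():
            cutoff = np.max(np.flatnonzero(below))
            keep_flat[order[: cutoff + 1]] = True
    else:
        raise ValueError(f"unknown correction method {method!r}")
    supra = np.zeros(tmap.shape, dtype=bool)
    supra[mask] = keep_flat
    return _cluster(supra, tmap, min_cluster)


def _as_rois(clusters, contrast: str, k: int = 3):
    return [
        Roi(contrast=contrast, voxels=c["voxels"], peak_t=c["peak_t"], peak_coord=c["peak_coord"])
        for c in clusters[:k]
    ]


def select_rois(face_clusters, house_clusters, face_fdr=None, house_fdr=None):
    """Apply the ROI-count rule: need >=1 face-contrast and >=2 house-contrast
    clusters at FWE, else retry the supplied FDR clusters, else exclusion.
    At most 3 ROIs per contrast, highest peak t first.
    """
    if len(face_clusters) >= 1 and len(house_clusters) >= 2:
        rois = _as_rois(face_clusters, FACE_GT_HOUSE) + _as_rois(house_clusters, HOUSE_GT_FACE)
        return RoiSet(rois=rois, threshold_used="FWE")
    if face_fdr is not None or house_fdr is not None:
        face_fdr = face_fdr or []
        house_fdr = house_fdr or []
        if len(face_fdr) >= 1 and len(house_fdr) >= 2:
            rois = _as_rois(face_fdr, FACE_GT_HOUSE) + _as_rois(house_fdr, HOUSE_GT_FACE)
            return RoiSet(rois=rois, threshold_used="FDR")
        return Exclusion(
            reason="fewer than 1 face-contrast + 2 house-contrast clusters at FWE and FDR",
            n_face=len(face_fdr),
            n_house=len(house_fdr),
        )
    return Exclusion(
        reason="fewer than 1 face-contrast + 2 house-contrast clusters at FWE",
        n_face=len(face_clusters),
        n_house=len(house_clusters),
    )


def localize(
    volumes: np.ndarray,
    design: BlockDesign,
    fwhm_mm: float = 5.0,
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
    alpha: float = ALPHA,
    min_cluster: int = MIN_CLUSTER,
):
    """Full localizer: smooth, fit the GLM, threshold both contrasts and
    select ROIs (FWE first, FDR fallback).  Returns (RoiSet | Exclusion, GlmResult)."""
    mask = package_mask(volumes.shape[:-1]) if mask is None else mask
    smoothed = smooth_gaussian(volumes, fwhm_mm, voxel_size_mm)
    glm = fit_glm(smoothed, design)
    c_face = np.array([1.0, -1.0, 0.0, 0.0])
    t_face = glm.t_map(c_face)
    t_house = glm.t_map(-c_face)
    kw = dict(alpha=alpha, min_cluster=min_cluster, mask=mask)
    face_fwe = threshold_and_cluster(t_face, glm.dof, "FWE", **kw)
    house_fwe = threshold_and_cluster(t_house, glm.dof, "FWE", **kw)
    if len(face_fwe) >= 1 and len(house_fwe) >= 2:
        return select_rois(face_fwe, house_fwe), glm
    face_fdr = threshold_and_cluster(t_face, glm.dof, "FDR", **kw)
    house_fdr = threshold_and_cluster(t_house, glm.dof, "FDR", **kw)
    return select_rois(face_fwe, house_fwe, face_fdr, house_fdr), glm
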