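"""Post-preprocessing functional-connectivity feature math.

Implements the global-connectivity pipeline used to turn residual BOLD
time series into features: per-voxel mean-correlation maps computed with
the unit-norm trick, Fisher z-transformation, atlas-ROI averaging, the
whole-volume GCOR scalar, and the vectorization of the correlation matrix
of independent-component time-courses.

The unit-norm trick: after demeaning each voxel's series and scaling it to
unit Euclidean norm, the Pearson correlation of voxels *i* and *j* is the
dot product ``u_i . u_j``.  The mean correlation of voxel *i* with the
whole volume is then ``u_i . u_bar`` with ``u_bar`` the voxel-average of
the unit-norm rows, and the mean of the full M x M correlation matrix
(self-correlations included) is ``||u_bar||^2`` — which is the GCOR scalar
reported here.  Each per-voxel mean therefore includes the voxel's own
r = 1 term; the exclusive mean is ``(M*v - 1)/(M - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: correlations are clipped to +/- (1 - FISHER_CLIP) before atanh
FISHER_CLIP = 1e-7


class ConnectivityError(ValueError):
    pass


@dataclass(frozen=True)
class TimeSeriesVolume:
    """M voxels x T timepoints of residual time series."""

    values: np.ndarray
    voxel_ids: list[str]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ConnectivityError("values must be a voxels x timepoints matrix")
        m, t = self.values.shape
        if m != len(self.voxel_ids):
            raise ConnectivityError(f"{m} rows but {len(self.voxel_ids)} voxel ids")
        if t < 3:
            raise ConnectivityError(f"need at least 3 timepoints, got {t}")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConnectivityMap:
    """Per-voxel connectivity value, on correlation (``r``) or Fisher
    (``z``) scale."""

    values: np.ndarray
    voxel_ids: list[str]
    scale: str = "r"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.scale not in ("r", "z"):
            raise ConnectivityError(f"unknown scale {self.scale!r}")
        if self.values.ndim != 1 or self.values.size != len(self.voxel_ids):
            raise ConnectivityError("values must be one scalar per voxel")
        if self.scale == "r" and (np.abs(self.values) > 1 + 1e-12).any():
            raise ConnectivityError("r-scale values must lie in [-1, 1]")


@dataclass(frozen=True)
class RoiLabeling:
    """Voxel id -> ROI id map with a fixed ROI output order."""

    voxel_to_roi: dict[str, str]
    rois: list[str]


@dataclass(frozen=True)
class ComponentTimecourses:
    """T timepoints x K component time-courses (post dual regression)."""

    values: np.ndarray
    component_ids: list[str]

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ConnectivityError("values must be timepoints x components")
        if self.values.shape[1] != len(self.component_ids):
            raise ConnectivityError("component id count mismatch")
        if self.values.shape[1] < 2:
            raise ConnectivityError("need at least 2 components")


def _unit_rows(values: np.ndarray, ids: list[str]) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    if flat.any():
        voxel = ids[int(np.flatnonzero(flat)[0])]
        raise ConnectivityError(f"voxel {voxel!r} has a constant time series")
    return centered / norms[:, None]


def unit_normalize(ts: TimeSeriesVolume) -> TimeSeriesVolume:
    """Demean each voxel's series and scale it to unit Euclidean norm."""
    return TimeSeriesVolume(values=_unit_rows(ts.values, ts.voxel_ids),
                            voxel_ids=ts.voxel_ids)


def voxelwise_global_connectivity(ts: TimeSeriesVolume) -> ConnectivityMap:
    """Mean Pearson correlation of each voxel with the whole volume.

    Computed as ``u_i . u_bar`` on unit-norm rows, which equals the row
    mean of the full correlation matrix including the diagonal — O(M*T)
    instead of the O(M^2 * T) of explicit pairwise correlation.
    """
    if ts.n_voxels < 2:
        raise ConnectivityError("need at least 2 voxels")
    u = _unit_rows(ts.values, ts.voxel_ids)
    mean_r = u @ u.mean(axis=0)
    return ConnectivityMap(values=np.clip(mean_r, -1.0, 1.0),
                           voxel_ids=ts.voxel_ids, scale="r")


def fisher_z(cmap: ConnectivityMap) -> ConnectivityMap:
    """Variance-stabilize an r-scale map: z = atanh(r), |r| clipped to
    1 - 1e-7 so the transform stays finite."""
    if cmap.scale != "r":
        raise ConnectivityError("fisher_z requires an r-scale map")
    r = np.clip(cmap.values, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    return ConnectivityMap(values=np.arctanh(r), voxel_ids=cmap.voxel_ids,
                           scale="z")


def roi_average(cmap: ConnectivityMap, labeling: RoiLabeling) -> np.ndarray:
    """Arithmetic mean of map values within each ROI, in the order of
    ``labeling.rois``.  An ROI with no labeled voxel in the map is an error."""
    idx = {v: i for i, v in enumerate(cmap.voxel_ids)}
    out = np.empty(len(labeling.rois))
    for k, roi in enumerate(labeling.rois):
        members = [idx[v] for v, r in labeling.voxel_to_roi.items()
                   if r == roi and v in idx]
        unknown = [v for v, r in labeling.voxel_to_roi.items()
                   if r == roi and v not in idx]
        if unknown:
            raise ConnectivityError(
                f"ROI {roi!r} labels voxels absent from the map: {unknown}")
        if not members:
            raise ConnectivityError(f"ROI {roi!r} has no voxels")
        out[k] = cmap.values[members].mean()
    return out


def gcor(ts: TimeSeriesVolume, *, squared: bool = True) -> float:
    """Whole-volume global correlation.

    The default (``squared=True``) returns the squared Euclidean norm of
    the voxel-averaged unit-norm series, which equals the mean of all M^2
    pairwise Pearson correlations (self-correlations included) and lies in
    [0, 1].  ``squared=False`` returns the unsquared norm of the averaged
    series instead; it is not a mean correlation but is provided because
    the two readings of the scalar circulate in the literature.
    """
    if ts.n_voxels < 2:
        raise ConnectivityError("need at least 2 voxels")
    u = _unit_rows(ts.values, ts.voxel_ids)
    norm = float(np.linalg.norm(u.mean(axis=0)))
    return norm ** 2 if squared else norm


def component_connectivity(tc: ComponentTimecourses) -> np.ndarray:
    """Vectorize the strict upper triangle of the K x K Pearson correlation
    matrix of component time-courses, row-major; length K(K-1)/2.

    With the study's 19 retained components this yields the 171-element
    connectivity feature vector per subject.
    """
    x = tc.values
    flat = np.flatnonzero(x.std(axis=0) == 0)
    if flat.size:
        raise ConnectivityError(
            f"component {tc.component_ids[int(flat[0])]!r} is constant")
    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices_from(corr, k=1)
    return corr[iu]
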