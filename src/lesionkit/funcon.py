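"""Seed-based resting-state functional connectivity with confound removal.

The confound model regresses 16 nuisance time series out of every voxel:
6 motion parameters, the first eigenvariates of white matter and CSF,
and the first temporal derivative of each of those 8, the derivative
being the [-1 0 1] central-difference convolution. Residualized data
are then summarized over a seed (mean time course by default, first
eigenvariate optionally) and Pearson-correlated with every in-mask
voxel. Per-subject correlation maps combine into a group network as the
voxelwise median, and a network mask keeps voxels with r strictly above
a threshold (default 0.3), with the patient's lesion masked out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import MaskVolume, TimeSeriesVolume, Volume, assert_same_grid

__all__ = [
    "ConnectivityMap",
    "first_eigenvariate",
    "temporal_derivative",
    "build_confound_matrix",
    "regress_confounds",
    "seed_correlation_map",
    "median_map",
    "network_mask",
]

log = logging.getLogger(__name__)

MOTION_COLUMNS = tuple(f"motion_{i}" for i in range(1, 7))


@dataclass
class ConnectivityMap:
    """A voxelwise Pearson-r map for one seed; undefined voxels stored as 0."""

    r: Volume
    seed_name: str = "seed"

    def __post_init__(self) -> None:
        if np.abs(self.r.data).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


def first_eigenvariate(ts: np.ndarray) -> np.ndarray:
    """Dominant time course of a voxels x time matrix.

    The first right-singular direction of the column-centered matrix,
    scaled to unit variance, with its sign chosen so that it correlates
    non-negatively with the mean time course (sign-flip invariance).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[None, :]
    if ts.shape[0] < 1 or ts.shape[1] < 2:
        raise ValueError("need >= 1 voxel and >= 2 frames")
    centered = ts - ts.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("all-zero (constant) matrix has no eigenvariate")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    course = vt[0]
    sd = course.std()
    course = course / sd
    mean_course = centered.mean(axis=0)
    if np.dot(course, mean_course) < 0:
        course = -course
    return course


def temporal_derivative(series: np.ndarray) -> np.ndarray:
    """[-1 0 1] convolution: d(t) = x(t+1) - x(t-1), endpoints set to 0."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 frames for a temporal derivative")
    d = np.zeros_like(x)
    d[1:-1] = x[2:] - x[:-2]
    return d


def build_confound_matrix(
    motion: pd.DataFrame | np.ndarray,
    wm_ts: np.ndarray,
    csf_ts: np.ndarray,
) -> pd.DataFrame:
    """Assemble the 16-column confound matrix.

    Columns: 6 motion parameters, wm_eig, csf_eig, then the temporal
    derivative of each of those 8 (suffix ``_dt``).
    """
    if isinstance(motion, pd.DataFrame):
        motion_arr = motion.to_numpy(dtype=float)
    else:
        motion_arr = np.asarray(motion, dtype=float)
    if motion_arr.ndim != 2 or motion_arr.shape[1] != 6:
        raise ValueError(f"motion must be frames x 6, got {motion_arr.shape}")
    n_frames = motion_arr.shape[0]
    wm = first_eigenvariate(np.atleast_2d(wm_ts))
    csf = first_eigenvariate(np.atleast_2d(csf_ts))
    if wm.size != n_frames or csf.size != n_frames:
        raise ValueError("frame counts of motion, WM and CSF series disagree")
    cols: dict[str, np.ndarray] = {}
    for i, name in enumerate(MOTION_COLUMNS):
        cols[name] = motion_arr[:, i]
    cols["wm_eig"] = wm
    cols["csf_eig"] = csf
    for name in list(cols):
        cols[f"{name}_dt"] = temporal_derivative(cols[name])
    return pd.DataFrame(cols)


def _design_matrix(confounds: pd.DataFrame) -> np.ndarray:
    """Intercept + confound columns, with collinear columns dropped."""
    x = np.column_stack([np.ones(len(confounds))] + [confounds[c].to_numpy(dtype=float) for c in confounds.columns])
    # rank-revealing QR: drop columns that add nothing
    q, r, piv = _qr_pivot(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    keep_rank = int((diag > tol).sum())
    if keep_rank < x.shape[1]:
        dropped = sorted(piv[keep_rank:])
        names = ["intercept"] + list(confounds.columns)
        log.warning(
            "confound design is rank-deficient; dropping collinear columns %s",
            [names[i] for i in dropped],
        )
        keep = sorted(piv[:keep_rank])
        x = x[:, keep]
    return x


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def regress_confounds(
    ts4d: TimeSeriesVolume,
    confounds: pd.DataFrame,
    brain_mask: MaskVolume,
) -> TimeSeriesVolume:
    """OLS-residualize every in-mask voxel on [intercept | confounds].

    Residuals are orthogonal to every confound column by the normal
    equations; out-of-mask voxels are zeroed.
    """
    assert_same_grid(ts4d, brain_mask)
    if len(confounds) != ts4d.n_frames:
        raise ValueError(
            f"confound frames ({len(confounds)}) != data frames ({ts4d.n_frames})"
        )
    x = _design_matrix(confounds)
    mask = brain_mask.astype_bool()
    y = ts4d.data[mask].T.astype(float)  # frames x voxels
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = np.zeros_like(ts4d.data, dtype=float)
    out[mask] = resid.T
    return TimeSeriesVolume(out, ts4d.affine, tr_seconds=ts4d.tr_seconds)


def seed_correlation_map(
    ts4d: TimeSeriesVolume,
    seed: MaskVolume,
    brain_mask: MaskVolume,
    seed_summary: str = "mean",
) -> ConnectivityMap:
    """Correlate the seed's summary time course with every in-mask voxel.

    seed_summary is "mean" (default) or "eigenvariate". Voxels with zero
    variance get r = 0 with a logged count.
    """
    assert_same_grid(ts4d, seed)
    assert_same_grid(ts4d, brain_mask)
    seed_vox = seed.astype_bool()
    if not seed_vox.any():
        raise ValueError("seed mask is empty")
    seed_ts = ts4d.data[seed_vox].astype(float)  # voxels x time
    if seed_summary == "mean":
        summary = seed_ts.mean(axis=0)
    elif seed_summary == "eigenvariate":
        summary = first_eigenvariate(seed_ts)
    else:
        raise ValueError(f"unknown seed summary {seed_summary!r}")
    summary = summary - summary.mean()
    s_norm = np.linalg.norm(summary)
    if s_norm == 0:
        raise ValueError("seed summary time course has zero variance")
    summary = summary / s_norm

    mask = brain_mask.astype_bool()
    y = ts4d.data[mask].astype(float)  # voxels x time
    y = y - y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(y, axis=1)
    flat = norms == 0
    if flat.any():
        log.info("%d in-mask voxels have zero variance; their r is set to 0", int(flat.sum()))
    norms[flat] = 1.0
    r = (y @ summary) / norms
    r[flat] = 0.0
    r = np.clip(r, -1.0, 1.0)
    out = np.zeros(ts4d.data.shape[:3], dtype=float)
    out[mask] = r
    return ConnectivityMap(Volume(out, ts4d.affine))


def median_map(maps: list[ConnectivityMap]) -> ConnectivityMap:
    """Voxelwise median across subjects (mean of central pair when even)."""
    if len(maps) == 0:
        raise ValueError("need at least one connectivity map")
    first = maps[0].r
    for m in maps[1:]:
        assert_same_grid(first, m.r)
    stack = np.stack([m.r.data for m in maps], axis=0)
    med = np.median(stack, axis=0)
    return ConnectivityMap(Volume(med, first.affine), seed_name=maps[0].seed_name)


def network_mask(
    cmap: ConnectivityMap,
    r_threshold: float = 0.3,
    lesion: MaskVolume | None = None,
) -> MaskVolume:
    """Voxels with r strictly above threshold, minus the lesion if given."""
    m = cmap.r.data > r_threshold
    if lesion is not None:
        assert_same_grid(cmap.r, lesion)
        m = m & ~lesion.astype_bool()
    return MaskVolume(m.astype(np.uint8), cmap.r.affine)
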