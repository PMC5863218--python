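"""Voxelwise Shannon entropy of BOLD series and region-mean extraction.

Entropy of a voxel's time course is -sum(p * log p) over an equal-width
histogram spanning that voxel's own intensity range. Binning against
the voxel's own [min, max] makes the measure invariant to any affine
intensity transform of the series, and a constant series has entropy 0.
The default bin count follows the square-root rule, ceil(sqrt(T)).

region_mean extracts the mean of any scalar map (entropy, cortical
thickness, ...) inside a mask, optionally excluding lesioned voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imgio import MaskVolume, TimeSeriesVolume, Volume, assert_same_grid

__all__ = ["EntropyConfig", "voxel_entropy", "region_mean"]


@dataclass(frozen=True)
class EntropyConfig:
    """Histogram estimator settings for the entropy map.

    n_bins=None selects ceil(sqrt(T)) at run time; log_base is
    "natural" (nats) or "base2" (bits) — the choice rescales the map by
    a constant factor only.
    """

    n_bins: int | None = None
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.n_bins is not None and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.log_base not in ("natural", "base2"):
            raise ValueError(f"log_base must be 'natural' or 'base2', got {self.log_base!r}")

    def resolve_bins(self, n_frames: int) -> int:
        return self.n_bins if self.n_bins is not None else max(2, math.ceil(math.sqrt(n_frames)))


def voxel_entropy(
    ts4d: TimeSeriesVolume,
    brain_mask: MaskVolume,
    cfg: EntropyConfig = EntropyConfig(),
) -> Volume:
    """Shannon entropy -sum(p log p) of each in-mask voxel's series.

    p is the occupancy of equal-width bins over the voxel's own
    [min, max]; constant series and out-of-mask voxels map to 0. The
    result is bounded above by log(n_bins).
    """
    assert_same_grid(ts4d, brain_mask)
    n_bins = cfg.resolve_bins(ts4d.n_frames)
    mask = brain_mask.astype_bool()
    y = ts4d.data[mask].astype(float)  # voxels x time
    n_vox, t = y.shape
    out = np.zeros(ts4d.data.shape[:3], dtype=float)
    if n_vox == 0:
        return Volume(out, ts4d.affine)
    mins = y.min(axis=1, keepdims=True)
    maxs = y.max(axis=1, keepdims=True)
    rng = maxs - mins
    const = (rng == 0).ravel()
    rng[rng == 0] = 1.0  # avoid 0/0; constant voxels forced to 0 below
    idx = np.floor((y - mins) / rng * n_bins).astype(np.int64)
    np.clip(idx, 0, n_bins - 1, out=idx)
    flat = idx + np.arange(n_vox)[:, None] * n_bins
    counts = np.bincount(flat.ravel(), minlength=n_vox * n_bins).reshape(n_vox, n_bins)
    p = counts / t
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    if cfg.log_base == "base2":
        h = h / math.log(2.0)
    h[const] = 0.0
    out[mask] = h
    return Volume(out, ts4d.affine)


def region_mean(
    scalar_map: Volume,
    mask: MaskVolume,
    exclude: MaskVolume | None = None,
) -> float:
    """Mean of a scalar map over (mask minus exclude)."""
    assert_same_grid(scalar_map, mask)
    m = mask.astype_bool()
    if exclude is not None:
        assert_same_grid(scalar_map, exclude)
        m = m & ~exclude.astype_bool()
    if not m.any():
        raise ValueError("effective mask is empty after exclusion")
    return float(scalar_map.data[m].mean())
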