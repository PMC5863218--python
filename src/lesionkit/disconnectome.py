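"""Percentage-overlap disconnectome maps.

One lesion, seeded into the tractography of N healthy controls, yields N
binarized visitation maps. Summing them voxelwise and expressing the
count as a percentage of N gives the disconnectome map: the probability,
across controls, that the lesion disconnects each location. A voxel is
called disconnected when that probability reaches 50% (inclusive — the
map is read "from 50% to 100%").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imgio import MaskVolume, Volume, assert_same_grid

__all__ = ["DisconnectomeMap", "overlap_map", "disconnection_mask"]


@dataclass
class DisconnectomeMap:
    """Voxelwise disconnection percentages in [0, 100] for one lesion.

    Every value is a multiple of 100/n_controls by construction.
    """

    volume: Volume
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        d = self.volume.data
        if d.min() < 0 or d.max() > 100:
            raise ValueError("disconnectome values must lie in [0, 100]")
        counts = d * self.n_controls / 100.0
        if not np.allclose(counts, np.round(counts), atol=1e-6):
            raise ValueError("values must be multiples of 100/n_controls")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volume.data.shape


def overlap_map(visitation_maps: Sequence[MaskVolume]) -> DisconnectomeMap:
    """Combine binarized per-control visitation maps into percentages.

    voxel value = 100 x (number of maps visiting the voxel) / n_controls.
    Order-invariant and count-conserving: summing value x N / 100 over
    voxels recovers the total visited-voxel count across inputs.
    """
    if len(visitation_maps) == 0:
        raise ValueError("need at least one visitation map")
    first = visitation_maps[0]
    counts = np.zeros(first.data.shape, dtype=np.int64)
    for m in visitation_maps:
        if not isinstance(m, MaskVolume):
            raise TypeError("visitation maps must be MaskVolume (binary)")
        assert_same_grid(first, m)
        counts += m.data.astype(np.int64)
    n = len(visitation_maps)
    percent = 100.0 * counts / n
    return DisconnectomeMap(Volume(percent.astype(np.float64), first.affine), n)


def disconnection_mask(d: DisconnectomeMap, cutoff_percent: float = 50.0) -> MaskVolume:
    """Binary disconnection status: voxel value >= cutoff (inclusive)."""
    m = d.data >= cutoff_percent
    return MaskVolume(m.astype(np.uint8), d.affine)
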