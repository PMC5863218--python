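"""Enantiomorphic lesion filling.

A unilateral lesion in a left-right aligned template space is filled by
copying, voxel for voxel, the intensity of the mirrored location in the
intact contralateral hemisphere. Voxels whose mirror image is itself
lesioned (bilateral overlap) cannot be filled this way; they are left
untouched and reported in an "unfillable" mask rather than given
invented intensities — bilateral lesions need a different route that is
out of this package's scope.

The mirror is taken about the voxel grid's mid-plane on the left-right
axis (axis 0), so inputs must already sit in a symmetric template space.
"""

from __future__ import annotations

import numpy as np

from .imgio import MaskVolume, Volume, assert_same_grid

__all__ = ["mirror_index", "enantiomorphic_fill", "LR_AXIS"]

#: index axis treated as left-right. Template-space images in this
#: package store x (left-right) first.
LR_AXIS = 0


def mirror_index(idx, grid_shape) -> tuple[int, int, int]:
    """Reflect a voxel index about the mid-sagittal grid plane.

    (i, j, k) -> (S-1-i, j, k) where S is the left-right extent.
    """
    idx = tuple(int(v) for v in idx)
    shape = tuple(int(v) for v in grid_shape)
    if len(idx) != 3 or len(shape) != 3:
        raise ValueError("index and shape must have 3 components")
    for v, s in zip(idx, shape):
        if not 0 <= v < s:
            raise IndexError(f"index {idx} outside grid {shape}")
    out = list(idx)
    out[LR_AXIS] = shape[LR_AXIS] - 1 - idx[LR_AXIS]
    return tuple(out)


def enantiomorphic_fill(t1: Volume, lesion: MaskVolume) -> tuple[Volume, MaskVolume]:
    """Fill lesioned voxels with their mirrored contralateral intensities.

    Returns the filled image and the mask of unfillable voxels (lesion
    voxels whose mirror is also inside the lesion). Voxels outside the
    lesion are bit-identical to the input; the operation is idempotent
    for a fixed lesion.
    """
    assert_same_grid(t1, lesion)
    les = lesion.astype_bool()
    mirrored_data = np.flip(t1.data, axis=LR_AXIS)
    mirrored_les = np.flip(les, axis=LR_AXIS)
    fillable = les & ~mirrored_les
    unfillable = les & mirrored_les
    out = t1.data.copy()
    out[fillable] = mirrored_data[fillable]
    return (
        Volume(out, t1.affine),
        MaskVolume(unfillable.astype(np.uint8), t1.affine),
    )
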