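"""Atlas-based tract disconnection scoring.

Each tract of a probabilistic white-matter atlas gives, per voxel, the
probability of finding that tract there. A lesion is considered to
disconnect a tract when it hits at least one voxel where the tract's
probability exceeds 50% (strict, configurable). Alongside the binary
call, the proportion of the tract's supra-threshold support that falls
inside the lesion is reported as the natural continuous companion.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .imgio import MaskVolume, Volume, assert_same_grid

__all__ = ["tract_disconnection", "write_tract_report", "load_atlas_dir"]

log = logging.getLogger(__name__)

REPORT_COLUMNS = ["tract", "max_probability", "proportion_damaged", "disconnected"]


def _as_probability(name: str, vol: Volume) -> np.ndarray:
    """Coerce an atlas map to the [0, 1] probability scale.

    Maps stored as percentages (max > 1.5) are rescaled by 1/100 with a
    log message; genuinely out-of-range values are rejected.
    """
    data = np.asarray(vol.data, dtype=float)
    vmax = float(data.max()) if data.size else 0.0
    if vmax > 1.5:
        if vmax > 100.0 or data.min() < 0:
            raise ValueError(f"atlas {name!r}: values outside [0, 1] or [0, 100]")
        log.info("atlas %r looks percent-scaled (max %.3g); rescaling by 1/100", name, vmax)
        data = data / 100.0
    if data.min() < 0 or data.max() > 1.0 + 1e-9:
        raise ValueError(f"atlas {name!r}: probabilities outside [0, 1]")
    return np.clip(data, 0.0, 1.0)


def tract_disconnection(
    lesion: MaskVolume,
    atlas: Mapping[str, Volume],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every atlas tract against one lesion.

    Returns a DataFrame with one row per tract (sorted by tract name):
    max_probability (maximum atlas value over lesion voxels),
    proportion_damaged (lesioned fraction of the tract's supra-threshold
    support), and the binary disconnected call (max_probability strictly
    above threshold).
    """
    les = lesion.astype_bool()
    rows = []
    for name in sorted(atlas):
        vol = atlas[name]
        assert_same_grid(lesion, vol)
        prob = _as_probability(name, vol)
        max_p = float(prob[les].max()) if les.any() else 0.0
        support = prob > threshold
        n_support = int(support.sum())
        damaged = int((support & les).sum())
        prop = damaged / n_support if n_support else 0.0
        rows.append(
            {
                "tract": name,
                "max_probability": max_p,
                "proportion_damaged": prop,
                "disconnected": bool(max_p > threshold),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_tract_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a tract report to CSV (6-decimal floats, stable ordering)."""
    report.to_csv(path, index=False, float_format="%.6f")


def load_atlas_dir(atlas_dir: str | Path) -> dict[str, Volume]:
    """Read a directory of per-tract NIfTI maps; tract name = file stem."""
    from .imgio import read_volume

    atlas_dir = Path(atlas_dir)
    atlas: dict[str, Volume] = {}
    for p in sorted(atlas_dir.iterdir()):
        if p.name.endswith((".nii", ".nii.gz")):
            name = p.name[: -len(".nii.gz")] if p.name.endswith(".nii.gz") else p.stem
            vol = read_volume(p)
            if not isinstance(vol, Volume):
                raise ValueError(f"atlas map {p} is not 3-D")
            atlas[name] = vol
    return atlas
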