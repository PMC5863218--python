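"""Seeded synthetic inputs for the whole pipeline.

Everything the toolkit consumes can be generated from a seed on a small
desk-scale grid (default 24x24x24 voxels at 2 mm isotropic): a
left-right symmetric smooth template, tube-like tract-probability
atlases, spherical lesions, per-control visitation maps with
inter-control jitter, patient cohorts whose behavioural scores carry a
planted deficit tied to disconnection of a chosen region, and 4-D
resting-state series with a planted seed-target coupling plus confound
signals that are genuinely mixed into the data.

All generators are pure functions of their parameters and seed, and all
outputs share the template grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .anacom import Cohort, Control, Patient
from .disconnectome import DisconnectomeMap
from .imgio import MaskVolume, TimeSeriesVolume, Volume, assert_same_grid

__all__ = [
    "CohortSpec",
    "make_template",
    "make_tract_atlas",
    "make_lesion",
    "make_visitation_maps",
    "make_cohort",
    "make_rsfmri",
    "DEFAULT_SHAPE",
    "DEFAULT_VOXEL_SIZE",
]

DEFAULT_SHAPE = (24, 24, 24)
DEFAULT_VOXEL_SIZE = (2.0, 2.0, 2.0)

#: notional number of tractography controls behind synthetic patient
#: disconnectome maps; values are multiples of 100/this.
SYNTH_MAP_CONTROLS = 10


def _centered_affine(shape, voxel_size) -> np.ndarray:
    """Diagonal affine placing the world origin at the grid center."""
    affine = np.eye(4)
    vs = np.asarray(voxel_size, dtype=float)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -vs * (np.asarray(shape) - 1) / 2.0
    return affine


@dataclass
class CohortSpec:
    """Study design for a synthetic lesion cohort.

    effect_size is the score shift, in score_sd units, subtracted from
    patients whose disconnectome covers the deficit region;
    disconnection_rate is the probability a patient is disconnected
    there.
    """

    n_patients: int
    n_controls: int
    deficit_region: MaskVolume
    effect_size: float
    score_mean: float = 50.0
    score_sd: float = 10.0
    disconnection_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("patient and control counts must be >= 1")
        if not self.score_sd > 0:
            raise ValueError("score_sd must be positive")
        if not 0.0 <= self.disconnection_rate <= 1.0:
            raise ValueError("disconnection_rate must lie in [0, 1]")


def make_template(
    shape=DEFAULT_SHAPE,
    voxel_size=DEFAULT_VOXEL_SIZE,
    seed: int = 0,
) -> Volume:
    """A strictly left-right mirror-symmetric smooth intensity volume.

    Smoothed white noise averaged with its own left-right flip; the
    left-right (first) extent must be even so the mid-sagittal plane
    falls between voxels.
    """
    shape = tuple(int(s) for s in shape)
    if shape[0] % 2 != 0:
        raise ValueError("left-right extent must be even for a mid-plane mirror")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=2.0)
    sym = 0.5 * (smooth + np.flip(smooth, axis=0))
    # rescale to a T1-like positive intensity range
    sym = (sym - sym.min()) / (sym.max() - sym.min()) * 100.0 + 20.0
    return Volume(sym, _centered_affine(shape, voxel_size))


def make_tract_atlas(
    template: Volume,
    n_tracts: int,
    seed: int = 0,
    sigma_mm: float = 4.0,
) -> dict[str, Volume]:
    """Tube-like probability maps, one per tract, on the template grid.

    Each tract is a quadratic curve through the volume; probability
    decays as a Gaussian of the distance (in mm) to the curve's core
    voxels, peaking at 1 on the core.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    rng = np.random.default_rng(seed)
    shape = np.asarray(template.data.shape)
    vs = template.voxel_size
    atlas: dict[str, Volume] = {}
    for t in range(n_tracts):
        # endpoints on opposite faces of a random axis, bowed midpoint
        axis = int(rng.integers(0, 3))
        start = rng.uniform(0.2, 0.8, size=3) * (shape - 1)
        end = start.copy()
        start[axis], end[axis] = 1.0, shape[axis] - 2.0
        mid = 0.5 * (start + end) + rng.uniform(-0.2, 0.2, size=3) * (shape - 1)
        u = np.linspace(0.0, 1.0, 20 * int(shape.max()))[:, None]
        curve = (1 - u) ** 2 * start + 2 * u * (1 - u) * mid + u**2 * end
        core = np.zeros(template.data.shape, dtype=bool)
        ijk = np.round(curve).astype(int)
        keep = np.all((ijk >= 0) & (ijk < shape), axis=1)
        ijk = ijk[keep]
        core[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
        dist = distance_transform_edt(~core, sampling=vs)
        prob = np.exp(-(dist**2) / (2.0 * sigma_mm**2))
        prob[core] = 1.0
        atlas[f"tract_{t + 1:02d}"] = Volume(prob, template.affine)
    return atlas


def make_lesion(template: Volume, center, radius_mm: float) -> MaskVolume:
    """Spherical binary lesion: voxel centers within radius_mm of center."""
    center = np.asarray(center, dtype=float)
    shape = np.asarray(template.data.shape)
    if np.any(center < 0) or np.any(center >= shape):
        raise ValueError(f"lesion center {center} outside grid {tuple(shape)}")
    if not radius_mm > 0:
        raise ValueError("radius must be positive")
    vs = template.voxel_size
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, vs))
    mask = d2 <= radius_mm**2
    return MaskVolume(mask.astype(np.uint8), template.affine)


def make_visitation_maps(
    lesion: MaskVolume,
    atlas_tract: Volume,
    n_controls: int,
    jitter: float = 0.1,
    seed: int = 0,
) -> list[MaskVolume]:
    """Per-control binarized visitation maps for a lesion-seeded tract.

    Emulates lesion-seeded tractography: if the lesion misses the
    tract's core (probability > 0.5), every map is empty; otherwise each
    control's map is the tract tube thickened or thinned by a random
    per-control threshold shift of amplitude ``jitter`` (jitter 0 gives
    identical maps).
    """
    assert_same_grid(lesion, atlas_tract)
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    rng = np.random.default_rng(seed)
    touches = bool((lesion.astype_bool() & (atlas_tract.data > 0.5)).any())
    maps: list[MaskVolume] = []
    for _ in range(n_controls):
        if not touches:
            maps.append(MaskVolume(np.zeros(lesion.data.shape, np.uint8), lesion.affine))
            continue
        thr = float(np.clip(0.5 + jitter * rng.uniform(-1.0, 1.0), 0.05, 0.95))
        m = atlas_tract.data >= thr
        maps.append(MaskVolume(m.astype(np.uint8), lesion.affine))
    return maps


def _random_blob(
    rng: np.random.Generator,
    grid: Volume,
    avoid: np.ndarray | None,
    radius_vox_range=(1.5, 3.0),
    max_tries: int = 50,
) -> np.ndarray:
    """A small spherical voxel blob, optionally disjoint from ``avoid``."""
    shape = np.asarray(grid.data.shape)
    for _ in range(max_tries):
        center = rng.uniform(2, shape - 3)
        radius = rng.uniform(*radius_vox_range)
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        blob = d2 <= radius**2
        if avoid is None or not (blob & avoid).any():
            return blob
    return np.zeros(tuple(shape), dtype=bool)


#: size of the shared corridor library behind synthetic disconnectomes
N_CORRIDORS = 8
#: probability a patient's lesion disconnects any given corridor
CORRIDOR_RATE = 0.3


def _default_map_maker(
    spec: CohortSpec,
) -> Callable[[int, bool, np.random.Generator], DisconnectomeMap]:
    """Disconnectome maps assembled from a shared corridor library.

    Lesions disconnect white-matter corridors that are common across
    patients, so patient maps overlap heavily: each patient draws a
    random subset of a fixed library of small corridor blobs (each at a
    random percentage >= 50), and disconnected patients additionally
    cover the deficit region at 100%. Shared corridors produce the
    multi-patient membership patterns that AnaCOM2 clusters on.
    """
    region = spec.deficit_region.astype_bool()
    grid = spec.deficit_region
    lib_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 911]))
    corridors = [
        _random_blob(lib_rng, grid, avoid=region, radius_vox_range=(1.5, 3.5))
        for _ in range(N_CORRIDORS)
    ]

    def maker(i: int, disconnected: bool, rng: np.random.Generator) -> DisconnectomeMap:
        data = np.zeros(grid.data.shape, dtype=float)
        step = 100.0 / SYNTH_MAP_CONTROLS
        for blob in corridors:
            if rng.random() < CORRIDOR_RATE:
                level = step * rng.integers(5, SYNTH_MAP_CONTROLS + 1)
                np.maximum(data, np.where(blob, level, 0.0), out=data)
        if disconnected:
            data[region] = 100.0
        return DisconnectomeMap(Volume(data, grid.affine), SYNTH_MAP_CONTROLS)

    return maker


def make_cohort(
    spec: CohortSpec,
    visitation_source: Callable[[int, bool, np.random.Generator], DisconnectomeMap]
    | None = None,
) -> Cohort:
    """A patient + control cohort with a planted disconnection deficit.

    Scores are Normal(score_mean, score_sd); patients flagged
    disconnected (probability disconnection_rate) cover the deficit
    region at >= 50% and have effect_size x score_sd subtracted from
    their score. The statistics under test are rank-based, so the
    Gaussian generating family is a free choice that simplifies power
    calibration.
    """
    rng = np.random.default_rng(spec.seed)
    maker = visitation_source if visitation_source is not None else _default_map_maker(spec)
    disconnected_flags = rng.random(spec.n_patients) < spec.disconnection_rate
    patients: list[Patient] = []
    for i in range(spec.n_patients):
        score = rng.normal(spec.score_mean, spec.score_sd)
        if disconnected_flags[i]:
            score -= spec.effect_size * spec.score_sd
        pmap = maker(i, bool(disconnected_flags[i]), rng)
        patients.append(Patient(id=f"P{i + 1:03d}", score=float(score), map=pmap))
    controls = [
        Control(id=f"C{i + 1:03d}", score=float(rng.normal(spec.score_mean, spec.score_sd)))
        for i in range(spec.n_controls)
    ]
    return Cohort(patients=patients, controls=controls)


def make_rsfmri(
    template: Volume,
    seed_mask: MaskVolume,
    target_mask: MaskVolume,
    coupling: float,
    n_frames: int = 200,
    seed: int = 0,
    noise_sd: float = 0.1,
    confound_amplitude: float = 0.5,
    tr_seconds: float = 2.0,
) -> tuple[TimeSeriesVolume, pd.DataFrame]:
    """4-D series with a planted seed-target coupling plus confounds.

    A latent white-noise signal s(t) drives the seed voxels
    (s + noise_sd * eps) and the target voxels
    (coupling * s + sqrt(1 - coupling^2) * eta); everywhere else is
    independent unit noise. Six random-walk motion regressors and two
    smooth physiological series are mixed into every voxel with random
    spatial weights scaled by confound_amplitude, and returned in the
    confound table so regression can actually remove them.
    """
    assert_same_grid(template, seed_mask)
    assert_same_grid(template, target_mask)
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    s_vox = seed_mask.astype_bool()
    t_vox = target_mask.astype_bool()
    if (s_vox & t_vox).any():
        raise ValueError("seed and target masks must be disjoint")
    rng = np.random.default_rng(seed)
    shape = template.data.shape
    t = int(n_frames)
    s = rng.standard_normal(t)

    data = rng.standard_normal(shape + (t,))
    n_seed = int(s_vox.sum())
    n_target = int(t_vox.sum())
    data[s_vox] = s[None, :] + noise_sd * rng.standard_normal((n_seed, t))
    data[t_vox] = coupling * s[None, :] + np.sqrt(1.0 - coupling**2) * rng.standard_normal(
        (n_target, t)
    )

    # confounds genuinely added into every voxel
    motion = np.cumsum(0.05 * rng.standard_normal((t, 6)), axis=0)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    freq = rng.uniform(0.02, 0.08, size=2)
    times = np.arange(t) * tr_seconds
    phys = np.stack(
        [np.sin(2 * np.pi * freq[k] * times + phase[k]) for k in range(2)], axis=1
    )
    conf = np.concatenate([motion, phys], axis=1)  # t x 8
    weights = confound_amplitude * rng.standard_normal((int(np.prod(shape)), 8))
    data += (weights @ conf.T).reshape(shape + (t,))

    table = pd.DataFrame(
        conf,
        columns=[f"motion_{i}" for i in range(1, 7)] + ["phys_wm", "phys_csf"],
    )
    return TimeSeriesVolume(data, template.affine, tr_seconds=tr_seconds), table
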