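"""AnaCOM2: cluster-based disconnection-symptom mapping.

Instead of testing every voxel separately, voxels that are disconnected
in exactly the same set of patients are pooled into one cluster — by
construction all voxels of a cluster induce the same split of patient
scores, so one test per cluster suffices and the multiple-comparison
burden drops from thousands of voxels to a handful of clusters. For
each cluster larger than 8 mm^3 a Kruskal-Wallis test compares three
groups (patients disconnected at the cluster, patients spared, healthy
controls); the resulting p-values are Holm-corrected across clusters.
Clusters surviving at alpha then receive post hoc Mann-Whitney tests:
disconnected vs controls (Holm-corrected across the surviving clusters)
and disconnected vs spared (reported uncorrected). The output is a
statistical map carrying 1 - p in significant clusters.

Clusters are defined by the patient-membership pattern alone and need
not be spatially contiguous; a 26-connectivity relabelling is available
for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .disconnectome import DisconnectomeMap
from .imgio import MaskVolume, Volume, assert_same_grid
from .npstats import TestResult, holm_correction, kruskal_wallis, mann_whitney_u

__all__ = [
    "Patient",
    "Control",
    "Cohort",
    "ClusterStats",
    "DisconnectionMatrix",
    "disconnection_matrix",
    "form_clusters",
    "filter_clusters",
    "cluster_tests",
    "stat_map",
    "cluster_labels_map",
    "run_anacom",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_PERCENT = 50.0
DEFAULT_MIN_VOLUME_MM3 = 8.0
DEFAULT_ALPHA = 0.05


@dataclass
class Patient:
    id: str
    score: float
    map: DisconnectomeMap | MaskVolume


@dataclass
class Control:
    id: str
    score: float


@dataclass
class Cohort:
    """Patients (score + disconnectome or lesion map) and control scores."""

    patients: list[Patient]
    controls: list[Control]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients] + [c.id for c in self.controls]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        if self.patients:
            first = self._grid_of(self.patients[0])
            for p in self.patients[1:]:
                assert_same_grid(first, self._grid_of(p))

    @staticmethod
    def _grid_of(p: Patient) -> Volume:
        return p.map.volume if isinstance(p.map, DisconnectomeMap) else p.map

    def grid(self) -> Volume:
        if not self.patients:
            raise ValueError("cohort has no patients")
        return self._grid_of(self.patients[0])

    def patient_scores(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {p.id: p.score for p in self.patients}
        return np.array([lookup[i] for i in ids], dtype=float)

    def control_scores(self) -> np.ndarray:
        return np.array([c.score for c in self.controls], dtype=float)


@dataclass
class ClusterStats:
    """One cluster: its voxels, patient split, and test cascade results."""

    cluster_id: int
    voxel_indices: np.ndarray  # (n_voxels, 3) int array
    volume_mm3: float
    disconnected_ids: tuple[str, ...]
    spared_ids: tuple[str, ...]
    kw: TestResult | None = None
    kw_p_holm: float | None = None
    mw_disc_vs_controls: TestResult | None = None
    mw_p_holm: float | None = None
    mw_disc_vs_spared_uncorrected: TestResult | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])


@dataclass
class DisconnectionMatrix:
    """Patients x voxels boolean table over voxels disconnected in >= 1 patient."""

    matrix: np.ndarray  # (n_patients, n_voxels) bool
    voxel_indices: np.ndarray  # (n_voxels, 3) int
    patient_ids: tuple[str, ...]
    voxel_volume_mm3: float
    grid_shape: tuple[int, int, int]
    affine: np.ndarray


def _patient_binary(p: Patient, cutoff_percent: float) -> np.ndarray:
    if isinstance(p.map, DisconnectomeMap):
        return p.map.data >= cutoff_percent
    # binary lesion masks pass through unchanged (equivalent to a 100% map)
    return p.map.astype_bool()


def disconnection_matrix(
    cohort: Cohort, cutoff_percent: float = DEFAULT_CUTOFF_PERCENT
) -> DisconnectionMatrix:
    """Binarize every patient map at the cutoff and stack into a table.

    Columns (voxels) where no patient is disconnected are dropped; they
    carry no between-patient information.
    """
    grid = cohort.grid()
    stack = np.stack(
        [_patient_binary(p, cutoff_percent) for p in cohort.patients], axis=0
    )
    any_disc = stack.any(axis=0)
    idx = np.argwhere(any_disc)
    matrix = stack[:, any_disc]
    return DisconnectionMatrix(
        matrix=matrix,
        voxel_indices=idx,
        patient_ids=tuple(p.id for p in cohort.patients),
        voxel_volume_mm3=grid.voxel_volume_mm3,
        grid_shape=tuple(grid.data.shape),
        affine=grid.affine,
    )


def form_clusters(dm: DisconnectionMatrix) -> list[ClusterStats]:
    """Group voxels sharing an identical patient-membership column.

    Identical membership implies identical score split, so these voxels
    are statistically interchangeable. Clusters partition the matrix's
    voxels and need not be spatially contiguous.
    """
    if dm.matrix.size == 0:
        return []
    patterns, inverse = np.unique(dm.matrix.T, axis=0, return_inverse=True)
    ids = np.asarray(dm.patient_ids)
    clusters: list[ClusterStats] = []
    for k, pattern in enumerate(patterns):
        voxels = dm.voxel_indices[inverse == k]
        disc = tuple(ids[pattern])
        spared = tuple(ids[~pattern])
        clusters.append(
            ClusterStats(
                cluster_id=k,
                voxel_indices=voxels,
                volume_mm3=float(voxels.shape[0] * dm.voxel_volume_mm3),
                disconnected_ids=disc,
                spared_ids=spared,
            )
        )
    return clusters


def filter_clusters(
    clusters: Sequence[ClusterStats], min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3
) -> list[ClusterStats]:
    """Keep clusters strictly larger than the volume floor (default 8 mm^3)."""
    return [c for c in clusters if c.volume_mm3 > min_volume_mm3]


def cluster_tests(
    clusters: Sequence[ClusterStats],
    cohort: Cohort,
    alpha: float = DEFAULT_ALPHA,
) -> list[ClusterStats]:
    """Run the Kruskal-Wallis -> Holm -> Mann-Whitney cascade in place.

    Stage 1: per cluster, a 3-group Kruskal-Wallis on disconnected /
    spared / control scores (2-group when the spared set is empty, with
    a logged warning); Holm across all tested clusters. Stage 2: for
    clusters with Holm-adjusted KW p < alpha, Mann-Whitney disconnected
    vs controls, Holm-corrected across those clusters, plus disconnected
    vs spared reported uncorrected.
    """
    clusters = list(clusters)
    ctrl = cohort.control_scores()
    if ctrl.size == 0:
        raise ValueError("cohort has no controls")
    for c in clusters:
        if len(c.disconnected_ids) == 0:
            raise ValueError(f"cluster {c.cluster_id} has no disconnected patients")
        disc = cohort.patient_scores(c.disconnected_ids)
        spared = cohort.patient_scores(c.spared_ids)
        if spared.size == 0:
            log.warning(
                "cluster %d: all patients disconnected; Kruskal-Wallis degenerates "
                "to a 2-group (disconnected vs controls) rank test",
                c.cluster_id,
            )
            c.kw = kruskal_wallis([disc, ctrl])
        else:
            c.kw = kruskal_wallis([disc, spared, ctrl])
    kw_adj = holm_correction([c.kw.p_value for c in clusters]) if clusters else []
    for c, p in zip(clusters, kw_adj):
        c.kw_p_holm = float(p)

    significant = [c for c in clusters if c.kw_p_holm is not None and c.kw_p_holm < alpha]
    for c in significant:
        disc = cohort.patient_scores(c.disconnected_ids)
        c.mw_disc_vs_controls = mann_whitney_u(disc, ctrl, alternative="two_sided")
        if len(c.spared_ids) > 0:
            spared = cohort.patient_scores(c.spared_ids)
            c.mw_disc_vs_spared_uncorrected = mann_whitney_u(
                disc, spared, alternative="two_sided"
            )
    if significant:
        mw_adj = holm_correction([c.mw_disc_vs_controls.p_value for c in significant])
        for c, p in zip(significant, mw_adj):
            c.mw_p_holm = float(p)
    return clusters


def stat_map(
    clusters: Sequence[ClusterStats],
    grid: Volume,
    alpha: float = DEFAULT_ALPHA,
) -> Volume:
    """Paint 1 - p into significant clusters on the cohort grid.

    Uses the Holm-adjusted post hoc p where the post hoc ran, else the
    Holm-adjusted Kruskal-Wallis p; everything else is 0.
    """
    out = np.zeros(grid.data.shape, dtype=np.float64)
    shape = grid.data.shape
    for c in clusters:
        if c.kw_p_holm is None or c.kw_p_holm >= alpha:
            continue
        p = c.mw_p_holm if c.mw_p_holm is not None else c.kw_p_holm
        if c.voxel_indices.size and (
            c.voxel_indices.min() < 0 or np.any(c.voxel_indices.max(axis=0) >= shape)
        ):
            raise IndexError(f"cluster {c.cluster_id} references voxels outside the grid")
        i, j, k = c.voxel_indices.T
        out[i, j, k] = 1.0 - p
    return Volume(out, grid.affine)


def cluster_labels_map(clusters: Sequence[ClusterStats], grid: Volume) -> Volume:
    """Integer cluster-id map (cluster_id + 1; background 0), for reporting."""
    out = np.zeros(grid.data.shape, dtype=np.int32)
    for c in clusters:
        if c.voxel_indices.size:
            i, j, k = c.voxel_indices.T
            out[i, j, k] = c.cluster_id + 1
    return Volume(out, grid.affine)


def cluster_containing(clusters: Sequence[ClusterStats], index) -> ClusterStats | None:
    """The cluster whose voxel set contains the given (i, j, k) index, if any.

    Clusters partition the disconnected voxels, so at most one matches.
    """
    target = tuple(int(v) for v in index)
    for c in clusters:
        if c.voxel_indices.size and any(tuple(v) == target for v in c.voxel_indices):
            return c
    return None


def run_anacom(
    cohort: Cohort,
    cutoff_percent: float = DEFAULT_CUTOFF_PERCENT,
    min_volume_mm3: float = DEFAULT_MIN_VOLUME_MM3,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[ClusterStats], Volume]:
    """Full cascade: matrix -> clusters -> volume filter -> tests -> map."""
    dm = disconnection_matrix(cohort, cutoff_percent)
    clusters = filter_clusters(form_clusters(dm), min_volume_mm3)
    clusters = cluster_tests(clusters, cohort, alpha)
    smap = stat_map(clusters, cohort.grid(), alpha)
    return clusters, smap
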