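"""Lesion-to-disconnection mapping through healthy-control tractography.

A patient's binary lesion is intersected with each control tractogram:
every streamline passing through the lesion is marked as disconnected, the
voxels visited by the disconnected streamlines form a binary per-control
visitation volume, and averaging those volumes across controls yields a
voxel-wise probability of disconnection in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .space import PhantomSpace, grids_match


@dataclass
class LesionMask:
    """Binary lesion volume on a reference grid."""

    volume: np.ndarray
    affine: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume)
        vals = np.unique(vol)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("lesion volume must be binary (0/1)")
        if vol.ndim != 3:
            raise ValueError("lesion volume must be 3D")
        if not vol.any():
            raise ValueError("lesion mask has no nonzero voxel")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("lesion affine is not invertible")
        self.volume = vol.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def volume_mm3(self) -> float:
        voxel_vol = abs(np.linalg.det(self.affine[:3, :3]))
        return float(self.volume.sum()) * voxel_vol


@dataclass
class Tractogram:
    """Streamlines (polylines of world-mm points) for one control subject."""

    streamlines: list[np.ndarray]
    subject_id: str = ""

    def __post_init__(self) -> None:
        cleaned = []
        for i, sl in enumerate(self.streamlines):
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError(
                    f"streamline {i} of {self.subject_id or 'tractogram'} must "
                    f"be an (N>=2, 3) array"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite points")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class DisconnectionMap:
    """Voxel-wise disconnection probability for one patient."""

    volume: np.ndarray
    affine: np.ndarray
    n_controls: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume, dtype=float)
        if vol.min() < -1e-9 or vol.max() > 1 + 1e-9:
            raise ValueError("disconnection values must lie in [0, 1]")
        self.volume = vol


def rasterise_streamline(
    polyline: np.ndarray,
    space: PhantomSpace,
    step_fraction: float = 0.5,
) -> np.ndarray:
    """Voxels traversed by a polyline, as sorted unique flat indices.

    Each segment is walked at sub-voxel steps of ``step_fraction *
    voxel_size`` (default half a voxel) and the containing voxel collected
    at every sample; points outside the grid are skipped.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must have at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("polyline contains non-finite points")
    step = step_fraction * space.voxel_size
    seg_vec = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    samples = [pts]
    for k in np.nonzero(seg_len > 0)[0]:
        n = int(np.ceil(seg_len[k] / step))
        t = np.arange(1, n)[:, None] / n
        samples.append(pts[k] + t * seg_vec[k])
    all_pts = np.vstack(samples)
    vox = np.round(space.world_to_voxel(all_pts)).astype(np.int64)
    shape = np.array(space.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[inside]
    if vox.size == 0:
        return np.empty(0, dtype=np.int64)
    flat = np.ravel_multi_index(vox.T, space.shape)
    return np.unique(flat)


def rasterise_tractogram(
    tractogram: Tractogram,
    space: PhantomSpace,
    step_fraction: float = 0.5,
) -> list[np.ndarray]:
    """Per-streamline flat voxel indices; computed once and reused."""
    return [
        rasterise_streamline(sl, space, step_fraction)
        for sl in tractogram.streamlines
    ]


def _lesion_space(lesion: LesionMask) -> PhantomSpace:
    scale = np.linalg.norm(lesion.affine[:3, 0])
    space = PhantomSpace(
        shape=tuple(lesion.volume.shape),
        voxel_size=float(scale),
        origin=tuple(lesion.affine[:3, 3]),
    )
    if not np.allclose(space.affine, lesion.affine, atol=1e-6):
        raise ValueError("lesion affine is not an isotropic scaling+offset grid")
    return space


def streamlines_through_mask(
    tractogram: Tractogram,
    lesion: LesionMask,
    space: PhantomSpace | None = None,
    voxel_sets: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Streamlines whose voxel trace intersects the lesion."""
    if space is None:
        space = _lesion_space(lesion)
    elif not grids_match(space.affine, lesion.affine,
                         space.shape, lesion.volume.shape):
        raise ValueError("lesion and reference space are on different grids")
    lesion_flat = lesion.volume.ravel().astype(bool)
    if voxel_sets is None:
        voxel_sets = rasterise_tractogram(tractogram, space)
    return [
        sl
        for sl, vox in zip(tractogram.streamlines, voxel_sets)
        if vox.size and lesion_flat[vox].any()
    ]


def subject_disconnection_volume(
    affected: list[np.ndarray],
    space: PhantomSpace,
    voxel_sets: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Binary visitation volume of the disconnected streamlines."""
    flat = np.zeros(space.n_voxels, dtype=bool)
    if voxel_sets is None:
        voxel_sets = [rasterise_streamline(sl, space) for sl in affected]
    for vox in voxel_sets:
        flat[vox] = True
    return flat.reshape(space.shape).astype(np.uint8)


def disconnection_probability_map(
    lesion: LesionMask,
    tractograms: list[Tractogram],
    space: PhantomSpace | None = None,
    rasters: list[list[np.ndarray]] | None = None,
) -> DisconnectionMap:
    """Mean across controls of binary disconnection visitation.

    ``rasters`` may carry pre-computed per-streamline voxel indices (one
    list per control, aligned with ``tractograms``) so repeated calls over
    a patient cohort rasterise each control only once.
    """
    if not tractograms:
        raise ValueError("need at least one control tractogram")
    if space is None:
        space = _lesion_space(lesion)
    if rasters is None:
        rasters = [rasterise_tractogram(t, space) for t in tractograms]
    lesion_flat = lesion.volume.ravel().astype(bool)
    acc = np.zeros(space.n_voxels, dtype=np.float64)
    for voxel_sets in rasters:
        flat = np.zeros(space.n_voxels, dtype=bool)
        for vox in voxel_sets:
            if vox.size and lesion_flat[vox].any():
                flat[vox] = True
        acc += flat
    acc /= len(tractograms)
    return DisconnectionMap(
        volume=acc.reshape(space.shape),
        affine=space.affine.copy(),
        n_controls=len(tractograms),
        patient_id=lesion.patient_id,
    )


def cohort_disconnection_maps(
    lesions: list[LesionMask],
    tractograms: list[Tractogram],
    space: PhantomSpace,
    step_fraction: float = 0.5,
) -> list[DisconnectionMap]:
    """Disconnection maps for every patient, rasterising each control once."""
    rasters = [
        rasterise_tractogram(t, space, step_fraction) for t in tractograms
    ]
    return [
        disconnection_probability_map(les, tractograms, space, rasters)
        for les in lesions
    ]
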