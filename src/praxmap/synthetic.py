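"""Synthetic phantom cohorts with a planted disconnection-deficit effect.

The generator emulates the study design the pipeline targets: a group of
left-hemisphere stroke patients (one binary lesion each, in a common 2 mm
template grid), a set of healthy-control tractograms, and six praxis scores
per patient in percent.  One white-matter bundle is designated the *target*:
each patient's score on the linked task decreases linearly with the fraction
of target streamlines their lesion disconnects, plus Gaussian noise.  The
planted truth (per-patient disconnection fraction and the bundle's voxel
footprint) is returned so downstream statistics can be checked for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .space import PhantomSpace
from .disconnectome import (
    LesionMask,
    Tractogram,
    rasterise_tractogram,
    streamlines_through_mask,
)

TASK_NAMES = (
    "meaningless",
    "production",
    "recognition",
    "single_object",
    "multi_object",
    "figure_copy",
)

# Patient ages in the emulated cohort span the study's stated 29-79 range.
AGE_RANGE = (29.0, 79.0)
MONTHS_POST_STROKE_RANGE = (12, 62)
EDUCATION_RANGE = (10, 20)


@dataclass(frozen=True)
class BundleSpec:
    """A synthetic white-matter bundle.

    ``centreline`` is an ordered (K, 3) array of world-mm points; each
    streamline is the centreline displaced by a single Gaussian offset
    perpendicular to the bundle's chord (sd ``jitter_sd``), keeping
    streamlines coherent.  ``radius`` is the bundle's nominal envelope,
    used by the cohort layout when placing lesions.
    """

    name: str
    centreline: np.ndarray
    radius: float = 4.0
    n_streamlines: int = 60
    jitter_sd: float = 1.25

    def __post_init__(self) -> None:
        cl = np.asarray(self.centreline, dtype=float)
        if cl.ndim != 2 or cl.shape[0] < 2 or cl.shape[1] != 3:
            raise ValueError(f"bundle {self.name}: centreline needs >= 2 points")
        if not self.radius > 0:
            raise ValueError(f"bundle {self.name}: radius must be positive")
        if self.n_streamlines < 1:
            raise ValueError(f"bundle {self.name}: n_streamlines must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError(f"bundle {self.name}: jitter_sd must be >= 0")
        object.__setattr__(self, "centreline", cl)


def default_bundles(space: PhantomSpace) -> list[BundleSpec]:
    """Three bundles on the default 32 cubed, 2 mm phantom.

    One long horizontal target bundle, one crossing bundle in a lower
    plane, and one diagonal bundle in an upper plane, giving non-trivial
    overlap geometry without realistic anatomy.
    """
    lo, hi = space.world_bounds()
    span = hi - lo
    mid = lo + span / 2

    def w(fracs):
        return lo + np.asarray(fracs, dtype=float) * span

    return [
        BundleSpec(
            name="target",
            centreline=np.array([w([0.14, 0.5, 0.5]), w([0.88, 0.5, 0.5])]),
        ),
        BundleSpec(
            name="crossing",
            centreline=np.array([w([0.63, 0.14, 0.2]), w([0.63, 0.88, 0.2])]),
        ),
        BundleSpec(
            name="diagonal",
            centreline=np.array([w([0.2, 0.2, 0.8]), w([0.82, 0.82, 0.8])]),
        ),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    ``effect_size`` is the percent-score loss per unit mean disconnection of
    the target bundle; ``noise_sd`` the task noise in percent points.
    """

    n_patients: int = 29
    n_controls: int = 10
    bundles: tuple[BundleSpec, ...] = ()
    target_bundle: str = "target"
    linked_task: str = "meaningless"
    effect_size: float = 40.0
    noise_sd: float = 5.0
    score_baseline: float = 95.0
    lesion_radius_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("n_patients must be >= 3")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.bundles and self.target_bundle not in [b.name for b in self.bundles]:
            raise ValueError(
                f"target_bundle {self.target_bundle!r} not among bundles"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.score_baseline <= 100:
            raise ValueError("score_baseline must be in [0, 100]")
        if self.linked_task not in TASK_NAMES:
            raise ValueError(f"unknown linked task {self.linked_task!r}")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion_radius_range must be 0 < lo <= hi")
        object.__setattr__(self, "bundles", tuple(self.bundles))


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted ground truth."""

    space: PhantomSpace
    config: CohortConfig
    lesions: list[LesionMask]
    tractograms: list[Tractogram]
    behaviour: pd.DataFrame
    truth_fraction: np.ndarray
    truth_voxels: np.ndarray  # flat indices of the target bundle footprint


def _perpendicular_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(d, helper)
    v /= np.linalg.norm(v)
    w = np.cross(d, v)
    return v, w


def generate_tractogram(
    space: PhantomSpace,
    bundles: list[BundleSpec],
    seed: int,
    subject_id: str = "",
) -> Tractogram:
    """Sample one control subject's streamlines from the bundle specs.

    Streamlines are grouped in the listed bundle order (see
    :func:`bundle_slice`); every point is clamped to the grid's world
    bounding box.
    """
    lo, hi = space.world_bounds()
    rng = np.random.default_rng(seed)
    streamlines: list[np.ndarray] = []
    for bundle in bundles:
        cl = bundle.centreline
        if not np.all(space.contains_world(cl)):
            raise ValueError(
                f"bundle {bundle.name!r}: centreline leaves the phantom space"
            )
        chord = cl[-1] - cl[0]
        if np.linalg.norm(chord) == 0:
            chord = np.array([1.0, 0.0, 0.0])
        v, w = _perpendicular_basis(chord)
        offsets = rng.normal(0.0, bundle.jitter_sd, size=(bundle.n_streamlines, 2))
        for a, b in offsets:
            pts = cl + a * v + b * w
            pts = np.clip(pts, lo + 1e-6, hi - 1e-6)
            streamlines.append(pts)
    return Tractogram(streamlines=streamlines, subject_id=subject_id)


def bundle_slice(bundles: list[BundleSpec], name: str) -> slice:
    """Index range of one bundle's streamlines within a generated tractogram."""
    start = 0
    for bundle in bundles:
        if bundle.name == name:
            return slice(start, start + bundle.n_streamlines)
        start += bundle.n_streamlines
    raise KeyError(f"no bundle named {name!r}")


def generate_lesion(
    space: PhantomSpace,
    centre: np.ndarray,
    radius: float,
    patient_id: str = "",
) -> LesionMask:
    """Spherical binary lesion: voxel on iff its centre is within ``radius``."""
    if radius <= 0:
        raise ValueError(f"lesion radius must be positive, got {radius}")
    centre = np.asarray(centre, dtype=float)
    if not space.contains_world(centre[None])[0]:
        raise ValueError(f"lesion centre {centre} lies outside the space")
    idx = np.indices(space.shape).reshape(3, -1).T
    coords = space.voxel_to_world(idx)
    dist = np.linalg.norm(coords - centre, axis=1)
    vol = (dist <= radius).reshape(space.shape)
    if not vol.any():
        raise ValueError("lesion is empty: radius smaller than voxel spacing")
    return LesionMask(
        volume=vol.astype(np.uint8), affine=space.affine.copy(),
        patient_id=patient_id,
    )


def simulate_behaviour(
    truth_fraction: np.ndarray,
    config: CohortConfig,
    seed: int,
    lesion_volumes_mm3: np.ndarray | None = None,
) -> pd.DataFrame:
    """Behavioural table with the planted score-disconnection effect.

    The linked task follows ``baseline - effect_size * fraction + noise``;
    the other five tasks are baseline plus noise.  All scores are clipped
    to [0, 100].  Nuisance covariates (age, lesion volume) and demographics
    are drawn from the emulated study's stated ranges.
    """
    frac = np.asarray(truth_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("truth fractions must lie in [0, 1]")
    n = frac.size
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i + 1:02d}" for i in range(n)]),
    }
    for task in TASK_NAMES:
        base = np.full(n, config.score_baseline)
        if task == config.linked_task:
            base = base - config.effect_size * frac
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
        rows[task] = np.clip(base + noise, 0.0, 100.0)
    rows["age"] = np.round(rng.uniform(*AGE_RANGE, size=n), 1)
    rows["education_years"] = rng.integers(
        EDUCATION_RANGE[0], EDUCATION_RANGE[1] + 1, size=n
    )
    rows["months_post_stroke"] = rng.integers(
        MONTHS_POST_STROKE_RANGE[0], MONTHS_POST_STROKE_RANGE[1] + 1, size=n
    )
    rows["gender"] = rng.choice(["M", "F"], size=n)
    rows["hand_used"] = rng.choice(["left", "right"], size=n)
    if lesion_volumes_mm3 is None:
        lesion_volumes_mm3 = np.zeros(n)
    rows["lesion_volume_mm3"] = np.asarray(lesion_volumes_mm3, dtype=float)
    return pd.DataFrame(rows)


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-condition defaults on the standard phantom."""
    space = PhantomSpace()
    params = dict(bundles=tuple(default_bundles(space)), seed=seed)
    params.update(overrides)
    return CohortConfig(**params)


def _lesion_layout(
    space: PhantomSpace, config: CohortConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Lesion centres and radii implementing the planted-effect design.

    Patient 1 is the clearly impaired case: a large lesion centred on the
    target bundle, disconnecting essentially all of it.  Roughly two thirds
    of the remaining patients carry lesions whose surface sits at a graded
    clearance (0 to 10 mm) from the target axis, producing a smooth spread
    of mild-to-moderate disconnection fractions -- mirroring a cohort where
    most patients score near ceiling and a single patient falls below the
    task cut-off.  The rest lie on the distractor bundles and leave the
    target untouched.
    """
    bundles = {b.name: b for b in config.bundles}
    target = bundles[config.target_bundle]
    others = [b for b in config.bundles if b.name != config.target_bundle]
    lo, hi = space.world_bounds()
    r_lo, r_hi = config.lesion_radius_range
    cl = target.centreline
    chord = cl[-1] - cl[0]
    v, w = _perpendicular_basis(chord)

    placements: list[tuple[np.ndarray, float]] = []
    mid = cl[0] + 0.5 * chord
    placements.append((mid, r_hi))

    n_rest = config.n_patients - 1
    n_graded = int(round(n_rest * 2 / 3))
    clearances = np.linspace(0.0, 10.0, n_graded)
    for gap in clearances:
        radius = rng.uniform(r_lo, r_hi)
        d = radius + gap  # lesion surface sits `gap` mm short of the axis
        t = rng.uniform(0.2, 0.8)
        angle = rng.uniform(0, 2 * np.pi)
        centre = cl[0] + t * chord + d * (np.cos(angle) * v + np.sin(angle) * w)
        centre = np.clip(centre, lo + 1.0, hi - 1.0)
        placements.append((centre, radius))
    for _ in range(n_rest - n_graded):
        bundle = others[rng.integers(len(others))] if others else target
        bcl = bundle.centreline
        bchord = bcl[-1] - bcl[0]
        bv, bw = _perpendicular_basis(bchord)
        t = rng.uniform(0.2, 0.8)
        d = rng.uniform(0.0, 4.0)
        angle = rng.uniform(0, 2 * np.pi)
        centre = bcl[0] + t * bchord + d * (np.cos(angle) * bv + np.sin(angle) * bw)
        centre = np.clip(centre, lo + r_lo, hi - r_lo)
        placements.append((centre, rng.uniform(r_lo, r_hi)))
    return placements


def generate_cohort(
    config: CohortConfig | None = None,
    space: PhantomSpace | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Full synthetic cohort: tractograms, lesions, behaviour, truth.

    A single global seed fans out to independent child seeds for the
    tractograms, the lesion layout and the behavioural noise, so cohorts
    are bit-reproducible.
    """
    if space is None:
        space = PhantomSpace()
    if config is None:
        config = default_config(seed=0 if seed is None else seed)
    elif seed is not None:
        raise ValueError("pass the seed inside CohortConfig or alone, not both")
    if not config.bundles:
        config = CohortConfig(
            **{**config.__dict__, "bundles": tuple(default_bundles(space))}
        )

    ss = np.random.SeedSequence(config.seed)
    tract_ss, layout_ss, behav_ss = ss.spawn(3)
    tract_seeds = tract_ss.generate_state(config.n_controls)

    tractograms = [
        generate_tractogram(space, list(config.bundles), int(s), f"ctrl{i:02d}")
        for i, s in enumerate(tract_seeds)
    ]

    layout_rng = np.random.default_rng(layout_ss)
    placements = _lesion_layout(space, config, layout_rng)
    lesions = [
        generate_lesion(space, centre, radius, patient_id=f"P{i + 1:02d}")
        for i, (centre, radius) in enumerate(placements)
    ]

    tslice = bundle_slice(list(config.bundles), config.target_bundle)
    rasters = [rasterise_tractogram(t, space) for t in tractograms]
    truth_vox = (
        np.unique(np.concatenate(
            [np.concatenate(r[tslice]) for r in rasters]
        ))
        if config.n_controls
        else np.empty(0, dtype=np.int64)
    )
    n_target = tslice.stop - tslice.start
    truth_fraction = np.zeros(config.n_patients)
    for i, lesion in enumerate(lesions):
        hit = 0
        for tract, r in zip(tractograms, rasters):
            sub = Tractogram(tract.streamlines[tslice], tract.subject_id)
            hit += len(
                streamlines_through_mask(sub, lesion, space, r[tslice])
            )
        truth_fraction[i] = hit / (n_target * config.n_controls)

    behaviour = simulate_behaviour(
        truth_fraction,
        config,
        seed=int(behav_ss.generate_state(1)[0]),
        lesion_volumes_mm3=np.array([l.volume_mm3 for l in lesions]),
    )
    return SyntheticCohort(
        space=space,
        config=config,
        lesions=lesions,
        tractograms=tractograms,
        behaviour=behaviour,
        truth_fraction=truth_fraction,
        truth_voxels=truth_vox,
    )
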