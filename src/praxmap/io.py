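"""Readers/writers for NIfTI volumes, TRK/TCK tractograms, tables and
configuration, plus the umbrella pipeline driver.

NIfTI affines are the single source of spatial truth; streamlines cross the
API in world millimetres regardless of the on-disk voxel convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .space import PhantomSpace
from .disconnectome import (
    LesionMask,
    Tractogram,
    cohort_disconnection_maps,
)
from .behaviour import TASK_COLUMNS, PRAXIS_TASKS, below_cutoff_count
from .glm import group_glm, threshold_map
from .singlecase import voxelwise_single_case
from .synthetic import CohortConfig, default_config, generate_cohort

log = logging.getLogger("praxmap")

BEHAVIOUR_COLUMNS = [
    "patient_id", *TASK_COLUMNS, "age", "education_years",
    "months_post_stroke", "gender", "hand_used", "lesion_volume_mm3",
]


def read_lesion(path: str | Path) -> LesionMask:
    """Load a binary lesion mask, binarising at 0.5 with a warning."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: lesion must be 3D, got {data.ndim}D")
    affine = img.affine
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    if not np.all(np.isin(np.unique(data), (0, 1))):
        warnings.warn(f"{path}: non-binary values; binarising at > 0.5",
                      stacklevel=2)
        data = (data > 0.5).astype(np.uint8)
    return LesionMask(volume=data.astype(np.uint8), affine=affine,
                      patient_id=Path(path).name.split(".")[0])


def write_lesion(lesion: LesionMask, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(lesion.volume.astype(np.uint8), lesion.affine),
             str(path))
    return path


def write_volume(volume: np.ndarray, affine: np.ndarray,
                 path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))
    return path


def read_tractogram(path: str | Path) -> Tractogram:
    """Load TRK/TCK streamlines as world-mm polylines."""
    path = Path(path)
    try:
        obj = nib.streamlines.load(str(path))
    except Exception as exc:  # corrupt header or unknown format
        raise ValueError(f"cannot read tractogram {path}: {exc}") from exc
    streamlines = [np.asarray(sl, dtype=float) for sl in obj.streamlines]
    if not streamlines:
        warnings.warn(f"{path}: tractogram contains no streamlines",
                      stacklevel=2)
        return Tractogram(streamlines=[], subject_id=path.name.split(".")[0])
    return Tractogram(streamlines=streamlines,
                      subject_id=path.name.split(".")[0])


def write_tractogram(
    tractogram: Tractogram, path: str | Path, space: PhantomSpace | None = None
) -> Path:
    """Write streamlines as TRK (header carries the grid) or TCK."""
    path = Path(path)
    nib_tg = nib.streamlines.Tractogram(
        tractogram.streamlines, affine_to_rasmm=np.eye(4)
    )
    if path.suffix.lower() == ".trk":
        header = {}
        if space is not None:
            header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = (
                space.affine.astype(np.float32)
            )
            header[nib.streamlines.trk.Field.VOXEL_SIZES] = (
                np.array([space.voxel_size] * 3, dtype=np.float32)
            )
            header[nib.streamlines.trk.Field.DIMENSIONS] = (
                np.array(space.shape, dtype=np.int16)
            )
        nib.streamlines.save(nib_tg, str(path), header=header)
    elif path.suffix.lower() == ".tck":
        nib.streamlines.save(nib_tg, str(path))
    else:
        raise ValueError(f"unsupported tractogram format: {path.suffix}")
    return path


def read_behaviour_table(path: str | Path) -> pd.DataFrame:
    """Behavioural CSV with the documented column names."""
    table = pd.read_csv(path)
    missing = [c for c in BEHAVIOUR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"behavioural table {path} lacks column(s) {missing}")
    for task in TASK_COLUMNS:
        col = table[task]
        if col.isna().any():
            raise ValueError(f"missing {task} scores in {path}")
        if (col < 0).any() or (col > 100).any():
            raise ValueError(f"{task} scores outside [0, 100] in {path}")
    return table


def write_behaviour_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Parameters of a full simulate-to-statistics run."""

    out_dir: str = "praxmap_run"
    seed: int = 0
    n_patients: int = 29
    n_controls: int = 10
    effect_size: float = 40.0
    noise_sd: float = 5.0
    score_baseline: float = 95.0
    linked_task: str = "meaningless"
    permutations: int = 1000
    alpha: float = 0.05
    q: float = 0.05
    iterations: int = 10_000
    min_patients: int = 2
    step_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _sidecar(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Chain simulate -> disconnect -> group GLM -> single case.

    Every artefact directory receives a JSON provenance sidecar with the
    config hash, seed and package version; reruns with the same config are
    identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "praxmap_version": __version__,
    }
    artefacts: dict[str, Path] = {}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        cohort_cfg = default_config(
            seed=config.seed,
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            effect_size=config.effect_size,
            noise_sd=config.noise_sd,
            score_baseline=config.score_baseline,
            linked_task=config.linked_task,
        )
        cohort = generate_cohort(cohort_cfg)
        lesion_dir = out / "lesions"
        tract_dir = out / "tracts"
        lesion_dir.mkdir(exist_ok=True)
        tract_dir.mkdir(exist_ok=True)
        for lesion in cohort.lesions:
            write_lesion(lesion, lesion_dir / f"{lesion.patient_id}.nii.gz")
        for tract in cohort.tractograms:
            write_tractogram(tract, tract_dir / f"{tract.subject_id}.trk",
                             cohort.space)
        behaviour_path = out / "behaviour.csv"
        write_behaviour_table(cohort.behaviour, behaviour_path)
        artefacts.update(lesions=lesion_dir, tracts=tract_dir,
                         behaviour=behaviour_path)

        stage = "disconnect"
        log.info("stage %s", stage)
        maps = cohort_disconnection_maps(
            cohort.lesions, cohort.tractograms, cohort.space,
            step_fraction=config.step_fraction,
        )
        map_dir = out / "disconnectomes"
        map_dir.mkdir(exist_ok=True)
        for m in maps:
            write_volume(m.volume, m.affine,
                         map_dir / f"{m.patient_id}_disconnectome.nii.gz")
        artefacts["disconnectomes"] = map_dir

        stage = "group-glm"
        log.info("stage %s", stage)
        result = group_glm(
            maps, cohort.behaviour, config.linked_task,
            B=config.permutations, seed=config.seed,
            min_patients=config.min_patients,
        )
        glm_dir = out / "group_glm"
        glm_dir.mkdir(exist_ok=True)
        write_volume(np.nan_to_num(result.t_map), result.affine,
                     glm_dir / "t_map.nii.gz")
        write_volume(np.nan_to_num(result.p_uncorr, nan=1.0), result.affine,
                     glm_dir / "p_uncorr.nii.gz")
        write_volume(np.nan_to_num(result.p_fwe, nan=1.0), result.affine,
                     glm_dir / "p_fwe.nii.gz")
        sig = threshold_map(result, config.alpha)
        write_volume(sig.astype(np.float32), result.affine,
                     glm_dir / "significant_fwe.nii.gz")
        _sidecar(glm_dir / "glm.json", {
            **provenance,
            "task": config.linked_task,
            "B": result.B,
            "alpha": config.alpha,
            "mask_voxels": int(result.mask.sum()),
            "n_significant_fwe": int(sig.sum()),
        })
        artefacts["group_glm"] = glm_dir

        stage = "single-case"
        log.info("stage %s", stage)
        scores = cohort.behaviour[config.linked_task].to_numpy()
        cutoff = PRAXIS_TASKS[config.linked_task].cutoff_percent
        n_below, who = below_cutoff_count(
            scores, cutoff, cohort.behaviour["patient_id"].tolist()
        )
        sc_dir = out / "single_case"
        sc_dir.mkdir(exist_ok=True)
        cases = who or [
            cohort.behaviour["patient_id"].iloc[int(np.argmin(scores))]
        ]
        for case_id in cases:
            idx = cohort.behaviour.index[
                cohort.behaviour["patient_id"] == case_id
            ][0]
            case_map = maps[idx]
            refs = [m for j, m in enumerate(maps) if j != idx]
            sc = voxelwise_single_case(
                case_map, refs, result.mask,
                iterations=config.iterations, seed=config.seed,
                q=config.q,
            )
            write_volume(np.nan_to_num(sc.p_map, nan=1.0), sc.affine,
                         sc_dir / f"{case_id}_p.nii.gz")
            write_volume(np.nan_to_num(sc.q_map, nan=1.0), sc.affine,
                         sc_dir / f"{case_id}_q.nii.gz")
            write_volume(sc.significant.astype(np.float32), sc.affine,
                         sc_dir / f"{case_id}_significant.nii.gz")
            _sidecar(sc_dir / f"{case_id}.json", {
                **provenance,
                "case": case_id,
                "iterations": config.iterations,
                "q": config.q,
                "direction": "greater",
                "n_significant": int(sc.significant.sum()),
            })
        artefacts["single_case"] = sc_dir
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _sidecar(out / "provenance.json", provenance)
    artefacts["provenance"] = out / "provenance.json"
    return artefacts
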