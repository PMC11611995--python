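"""Voxel-wise regression of disconnection maps on praxis scores.

Each in-mask voxel's disconnection probabilities (one value per patient)
are regressed on the z-scored task score with age and lesion volume as
nuisance covariates.  Inference is by Freedman-Lane permutation: residuals
of the nuisance-only model are relabelled (the same relabelling at every
voxel, preserving the spatial dependence), the full model is refitted, and
the null distributions of the voxel t statistic and of its maximum over
voxels give uncorrected and family-wise-error-corrected p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .behaviour import zscore_column
from .disconnectome import DisconnectionMap
from .space import grids_match


@dataclass
class DesignMatrix:
    """Patients x columns design with one contrast column under test."""

    X: np.ndarray
    columns: list[str]
    contrast_index: int

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        n, k = X.shape
        if np.linalg.matrix_rank(X) < k:
            raise ValueError("design matrix is rank deficient")
        if n <= k:
            raise ValueError(f"need more patients ({n}) than columns ({k})")
        if not 0 <= self.contrast_index < k:
            raise ValueError("contrast_index outside design columns")
        self.X = X

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        c[self.contrast_index] = 1.0
        return c


def build_design(
    table: pd.DataFrame,
    task: str,
    nuisances: tuple[str, ...] = ("age", "lesion_volume_mm3"),
) -> DesignMatrix:
    """Intercept + z-scored task score + nuisance covariates."""
    missing = [c for c in (task, *nuisances) if c not in table.columns]
    if missing:
        raise KeyError(f"behavioural table lacks column(s): {missing}")
    z = zscore_column(table[task].to_numpy())
    cols = [np.ones(len(table)), z]
    names = ["intercept", f"z_{task}"]
    for nuis in nuisances:
        cols.append(table[nuis].to_numpy(dtype=float))
        names.append(nuis)
    return DesignMatrix(X=np.column_stack(cols), columns=names, contrast_index=1)


@dataclass
class PermutationResult:
    """Observed t map with permutation p-values on a voxel grid."""

    t_map: np.ndarray
    p_uncorr: np.ndarray
    p_fwe: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    B: int
    seed: int | None
    exhaustive: bool = False


def build_analysis_mask(
    maps: list[DisconnectionMap], min_patients: int = 2
) -> np.ndarray:
    """Voxels disconnected in >= min_patients patients with variance > 0."""
    if not maps:
        raise ValueError("no disconnection maps supplied")
    aff, shape = maps[0].affine, maps[0].volume.shape
    for m in maps[1:]:
        if not grids_match(aff, m.affine, shape, m.volume.shape):
            raise ValueError("disconnection maps are on different grids")
    stack = np.stack([m.volume for m in maps])
    mask = ((stack > 0).sum(axis=0) >= min_patients) & (stack.var(axis=0) > 0)
    if not mask.any():
        raise ValueError(
            "analysis mask is empty; lower min_patients or check the maps"
        )
    return mask


def _t_stats(
    Y: np.ndarray, pinv_X: np.ndarray, X: np.ndarray, c_var: float,
    contrast_index: int, df: int,
) -> np.ndarray:
    """Vectorised OLS t statistics for one contrast; Y is voxels x patients."""
    beta = Y @ pinv_X.T  # voxels x k
    resid = Y - beta @ X.T
    rss = np.einsum("vi,vi->v", resid, resid)
    sigma2 = np.maximum(rss / df, np.finfo(float).tiny)
    se = np.sqrt(sigma2 * c_var)
    return beta[:, contrast_index] / se


def fit_glm_voxel(y: np.ndarray, design: DesignMatrix) -> float:
    """OLS t statistic for the contrast at a single voxel."""
    y = np.asarray(y, dtype=float)[None, :]
    X = design.X
    df = X.shape[0] - X.shape[1]
    pinv_X = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    c = design.contrast
    c_var = float(c @ xtx_inv @ c)
    return float(_t_stats(y, pinv_X, X, c_var, design.contrast_index, df)[0])


def freedman_lane(
    y_matrix: np.ndarray,
    design: DesignMatrix,
    B: int = 1000,
    seed: int | None = None,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> PermutationResult:
    """Freedman-Lane permutation inference over all in-mask voxels.

    ``y_matrix`` is voxels x patients (already masked).  The observed
    relabelling is always counted, so the smallest attainable p is
    1/(B+1).  When B meets or exceeds n! the n! relabellings are
    enumerated exactly instead (p = count / n!).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    Y = np.asarray(y_matrix, dtype=float)
    X = design.X
    n, k = X.shape
    if Y.shape[1] != n:
        raise ValueError("y_matrix patients axis does not match the design")
    df = n - k
    pinv_X = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    c = design.contrast
    c_var = float(c @ xtx_inv @ c)

    # reduced (nuisance-only) model
    keep = [i for i in range(k) if i != design.contrast_index]
    Z = X[:, keep]
    fitted = Y @ (Z @ np.linalg.pinv(Z)).T
    resid = Y - fitted

    t_obs = _t_stats(Y, pinv_X, X, c_var, design.contrast_index, df)
    abs_obs = np.abs(t_obs)

    n_fact = math.factorial(n)
    exhaustive = B >= n_fact
    if exhaustive:
        import warnings

        warnings.warn(
            f"B={B} >= n!={n_fact}; enumerating all relabellings exactly",
            stacklevel=2,
        )
        perms = [np.array(p) for p in permutations(range(n))]
        count = np.zeros(Y.shape[0])
        count_max = np.zeros(Y.shape[0])
        for perm in perms:
            Yp = fitted + resid[:, perm]
            t_b = np.abs(
                _t_stats(Yp, pinv_X, X, c_var, design.contrast_index, df)
            )
            count += t_b >= abs_obs - 1e-12
            count_max += t_b.max() >= abs_obs - 1e-12
        p_uncorr = count / n_fact
        p_fwe = count_max / n_fact
        B_eff = n_fact
    else:
        rng = np.random.default_rng(seed)
        count = np.ones(Y.shape[0])  # observed relabelling
        count_max = np.ones(Y.shape[0])
        for _ in range(B):
            perm = rng.permutation(n)
            Yp = fitted + resid[:, perm]
            t_b = np.abs(
                _t_stats(Yp, pinv_X, X, c_var, design.contrast_index, df)
            )
            count += t_b >= abs_obs
            count_max += t_b.max() >= abs_obs
        p_uncorr = count / (B + 1)
        p_fwe = count_max / (B + 1)
        B_eff = B

    if mask is not None:
        t_vol = np.full(mask.shape, np.nan)
        pu_vol = np.full(mask.shape, np.nan)
        pf_vol = np.full(mask.shape, np.nan)
        t_vol[mask] = t_obs
        pu_vol[mask] = p_uncorr
        pf_vol[mask] = p_fwe
    else:
        t_vol, pu_vol, pf_vol = t_obs, p_uncorr, p_fwe
        mask = np.ones_like(t_obs, dtype=bool)
    return PermutationResult(
        t_map=t_vol,
        p_uncorr=pu_vol,
        p_fwe=pf_vol,
        mask=mask,
        affine=np.eye(4) if affine is None else affine,
        B=B_eff,
        seed=seed,
        exhaustive=exhaustive,
    )


def threshold_map(
    result: PermutationResult, alpha: float = 0.05, corrected: bool = True
) -> np.ndarray:
    """Binary significance volume: p < alpha on the chosen p map."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = result.p_fwe if corrected else result.p_uncorr
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(p, nan=np.inf) < alpha


def group_glm(
    maps: list[DisconnectionMap],
    table: pd.DataFrame,
    task: str,
    B: int = 5000,
    seed: int | None = None,
    min_patients: int = 2,
    nuisances: tuple[str, ...] = ("age", "lesion_volume_mm3"),
) -> PermutationResult:
    """End-to-end voxel-wise regression for one task."""
    if len(maps) != len(table):
        raise ValueError("one disconnection map per behavioural row required")
    design = build_design(table, task, nuisances)
    mask = build_analysis_mask(maps, min_patients)
    Y = np.stack([m.volume[mask] for m in maps], axis=1)  # voxels x patients
    return freedman_lane(
        Y, design, B=B, seed=seed, mask=mask, affine=maps[0].affine
    )
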