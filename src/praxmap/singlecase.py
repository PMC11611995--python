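"""Single-case inference: one patient against a small reference group.

The frequentist Crawford-Howell test treats the reference sample's mean and
standard deviation as estimates, not parameters:

    t = (x* - m) / (s * sqrt((n + 1) / n)),   df = n - 1.

Its Bayesian analogue (the Crawford-Garthwaite test of deficit with the
non-informative prior) samples the reference population variance from a
scaled inverse chi-square posterior, the mean from its conditional normal
posterior, and averages the case's normal tail probability across draws;
in expectation it equals the frequentist one-sided p exactly.  Applied
voxel-wise to disconnection maps with Benjamini-Hochberg FDR, it flags
voxels where the case is more disconnected than the rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .disconnectome import DisconnectionMap
from .space import grids_match


@dataclass(frozen=True)
class ControlSummary:
    """Reference-sample size, mean and sample (n-1) standard deviation."""

    n: int
    m: float
    s: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("reference sample needs n >= 2")
        if self.s < 0:
            raise ValueError("standard deviation cannot be negative")

    @classmethod
    def from_sample(cls, values) -> "ControlSummary":
        x = np.asarray(values, dtype=float)
        return cls(n=x.size, m=float(x.mean()), s=float(x.std(ddof=1)))


def crawford_howell_t(
    case_value: float, controls: ControlSummary
) -> tuple[float, int, float]:
    """Crawford-Howell t, degrees of freedom and upper-tail one-sided p."""
    if controls.s == 0:
        raise ValueError("degenerate reference: zero standard deviation")
    t = (case_value - controls.m) / (
        controls.s * np.sqrt((controls.n + 1) / controls.n)
    )
    df = controls.n - 1
    p_upper = float(stats.t.sf(t, df))
    return float(t), df, p_upper


def bayesian_test_deficit(
    case_value: float,
    controls: ControlSummary,
    iterations: int = 10_000,
    seed: int | None = None,
    alternative: str = "less",
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo Bayesian test of deficit (point estimate, credible interval).

    Per draw: psi ~ (n-1) s^2 / chi2(n-1); mu ~ Normal(m, psi/n); the tail
    probability Phi((x* - mu)/sqrt(psi)) estimates how abnormal the case
    is.  ``alternative='less'`` (the classical deficit direction) averages
    the lower tail; ``'greater'`` averages the upper tail, the direction
    used for excess disconnection.
    """
    if controls.s == 0:
        raise ValueError("degenerate reference: zero standard deviation")
    if iterations < 1000:
        raise ValueError("iterations must be >= 1000 for a stable estimate")
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible inference")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    rng = np.random.default_rng(seed)
    n, m, s = controls.n, controls.m, controls.s
    psi = (n - 1) * s**2 / rng.chisquare(n - 1, size=iterations)
    mu = rng.normal(m, np.sqrt(psi / n))
    z = (case_value - mu) / np.sqrt(psi)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite posterior draws")
    tail = stats.norm.cdf(z) if alternative == "less" else stats.norm.sf(z)
    lo, hi = np.percentile(tail, ci)
    return float(tail.mean()), (float(lo), float(hi))


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected bool array, adjusted values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_adj


@dataclass
class SingleCaseResult:
    """Voxel-wise single-case maps for one patient."""

    p_map: np.ndarray
    q_map: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mask: np.ndarray          # voxels actually tested
    zero_variance: np.ndarray  # tested voxels that hit the degenerate rule
    affine: np.ndarray
    iterations: int
    seed: int
    q_level: float
    case_id: str = ""

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.q_map, nan=np.inf) < self.q_level


def voxelwise_single_case(
    case_map: DisconnectionMap,
    reference_maps: list[DisconnectionMap],
    mask: np.ndarray,
    iterations: int = 10_000,
    seed: int | None = None,
    q: float = 0.05,
    alternative: str = "greater",
    chunk: int = 256,
) -> SingleCaseResult:
    """Bayesian single-case test at every in-mask voxel, with BH FDR.

    Degenerate voxels where the references have zero variance are handled
    as follows: a case equal to the constant reference value is excluded
    from testing; a case discrepant in the tested direction gets the
    minimum attainable p of 1/(iterations+1); a discrepancy the other way
    gets 1 - 1/(iterations+1).  Both flagged in ``zero_variance``.
    """
    if len(reference_maps) < 3:
        raise ValueError("need at least 3 reference maps")
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible inference")
    for ref in reference_maps:
        if ref is case_map or (
            ref.patient_id and ref.patient_id == case_map.patient_id
        ):
            raise ValueError(
                f"case {case_map.patient_id!r} appears in the reference list"
            )
        if not grids_match(case_map.affine, ref.affine,
                           case_map.volume.shape, ref.volume.shape):
            raise ValueError("case and reference maps are on different grids")
    mask = np.asarray(mask, dtype=bool)
    refs = np.stack([r.volume[mask] for r in reference_maps])  # n_ref x V
    case = case_map.volume[mask]
    n = refs.shape[0]
    m = refs.mean(axis=0)
    s = refs.std(axis=0, ddof=1)

    V = case.size
    p = np.full(V, np.nan)
    ci_lo = np.full(V, np.nan)
    ci_hi = np.full(V, np.nan)
    zero_var = np.zeros(V, dtype=bool)
    p_min = 1.0 / (iterations + 1)

    degenerate = s == 0
    same = degenerate & (case == m)
    if alternative == "greater":
        discrepant_hit = degenerate & (case > m)
        discrepant_opp = degenerate & (case < m)
    else:
        discrepant_hit = degenerate & (case < m)
        discrepant_opp = degenerate & (case > m)
    p[discrepant_hit] = p_min
    p[discrepant_opp] = 1.0 - p_min
    zero_var[discrepant_hit | discrepant_opp] = True

    test_idx = np.nonzero(~degenerate)[0]
    ss = np.random.SeedSequence(seed)
    for start in range(0, test_idx.size, chunk):
        idx = test_idx[start:start + chunk]
        rng = np.random.default_rng(ss.spawn(1)[0])
        psi = (n - 1) * s[idx] ** 2 / rng.chisquare(
            n - 1, size=(iterations, idx.size)
        )
        mu = rng.normal(m[idx], np.sqrt(psi / n))
        z = (case[idx] - mu) / np.sqrt(psi)
        tail = stats.norm.cdf(z) if alternative == "less" else stats.norm.sf(z)
        p[idx] = tail.mean(axis=0)
        ci_lo[idx] = np.percentile(tail, 2.5, axis=0)
        ci_hi[idx] = np.percentile(tail, 97.5, axis=0)

    tested = ~same
    p_tested = np.clip(p[tested], p_min, 1.0)
    _, q_adj = fdr_bh(p_tested, q=q)
    q_vals = np.full(V, np.nan)
    q_vals[tested] = q_adj
    p[tested] = p_tested

    def to_volume(flat, fill=np.nan, dtype=float):
        vol = np.full(mask.shape, fill, dtype=dtype)
        vol[mask] = flat
        return vol

    tested_mask = np.zeros(mask.shape, dtype=bool)
    tested_mask[mask] = tested
    zv_mask = np.zeros(mask.shape, dtype=bool)
    zv_mask[mask] = zero_var
    return SingleCaseResult(
        p_map=to_volume(p),
        q_map=to_volume(q_vals),
        ci_low=to_volume(ci_lo),
        ci_high=to_volume(ci_hi),
        mask=tested_mask,
        zero_variance=zv_mask,
        affine=case_map.affine,
        iterations=iterations,
        seed=seed,
        q_level=q,
        case_id=case_map.patient_id,
    )
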