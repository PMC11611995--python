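# Methods

This note documents the models, algorithms, parameter choices and
numerical conventions implemented in `praxmap`. Everything here describes
the package itself; all quantities are computable offline from the code
and the packaged data.

## 1. Spatial conventions

All computation happens on a `PhantomSpace`: an isotropic voxel grid with
a diagonal voxel-to-world affine.

| parameter | default | rationale |
|---|---|---|
| grid shape | 32 × 32 × 32 | large enough for three well-separated bundles and 10 mm lesions, small enough that a full cohort analysis runs in seconds |
| voxel size | 2 mm | typical resolution of normalised lesion masks |
| origin | (0, 0, 0) mm | voxel (i, j, k) has world centre (2i, 2j, 2k) mm; world extent [−1, 63] mm per axis |

Voxel indices are 0-based and internal only; every user-facing coordinate
is world mm. NIfTI affines are the single source of spatial truth: two
volumes interoperate only if their affines and shapes match
(`grids_match`, absolute tolerance 10⁻⁶).

## 2. Synthetic cohort generator

The generator plants a known lesion–behaviour effect so that the whole
inferential chain can be validated against ground truth.

### Bundles and tractograms

Three straight bundles (`default_bundles`):

- **target** — along x at the grid centre plane (y = z = fraction 0.5),
  spanning x fractions 0.14–0.88;
- **crossing** — along y at x fraction 0.63, z fraction 0.2;
- **diagonal** — from fraction (0.2, 0.2, 0.8) to (0.82, 0.82, 0.8).

The distractors are placed ≥ 19 mm from the target axis so that even the
largest default lesion (radius 10 mm) centred on a distractor cannot graze
the target bundle.

Each control subject's tractogram contains, per bundle, `n_streamlines`
(default 60) copies of the centreline displaced by a **per-streamline
constant** perpendicular offset `a·v + b·w` with `a, b ~ N(0, jitter_sd²)`
and `(v, w)` an orthonormal basis perpendicular to the bundle direction.
`jitter_sd` defaults to 1.25 mm: a bundle envelope compact relative to the
2 mm voxel, wide enough that the 10 controls differ, narrow enough that a
lesion on the bundle axis disconnects most of it. Streamlines are clipped
to the world bounds; a centreline leaving the grid is an error naming the
bundle.

### Lesions and the planted effect

Lesions are spheres: a voxel is lesioned when its **centre** lies within
the radius (radii drawn uniformly from 4–10 mm). The cohort layout
(`_lesion_layout`) is:

- patient 0: the impaired case — radius 10 mm, centred on the target
  bundle midpoint (truth fraction ≈ 1);
- about two thirds of the remaining patients: lesion centres at distance
  `d = radius + gap` from the target axis with clearances
  `gap = linspace(0, 10)` mm, producing a graded range of partial
  disconnection;
- the rest: lesions on the distractor bundles (no target disconnection).

This layout emulates a realistic clinical score distribution: one clearly
impaired case, a graded mid-range, and a majority near ceiling.

**Ground truth**: `truth_fraction[i]` is the fraction of target
streamlines hit by patient i's lesion, averaged over controls;
`truth_voxels` is the union of rasterised target-bundle voxels across all
controls (the support a perfect recovery would return).

### Behaviour

Six praxis tasks (percent scores, published cutoffs):

| task | items × points | cutoff (%) |
|---|---|---|
| meaningless (gesture imitation) | 10 × 2 | 75 |
| production (gesture production) | 6 × 2 | 75 |
| recognition (gesture recognition) | 6 × 1 | 83 |
| single_object (single-object use) | 6 × 2 | 85 |
| multi_object (multi-object use) | 6 × 2 | 85 |
| figure_copy (figure copying) | 47 × 1 | 83 |

The linked task (default `meaningless`) is
`clip(score_baseline − effect_size · truth_fraction + ε, 0, 100)` with
`score_baseline = 95`, `effect_size = 40`, noise `ε ~ N(0, 5²)`; the other
tasks are baseline plus noise. Impairment is a **strict** `score < cutoff`
comparison (a score exactly at the cutoff is not impaired). Demographics
are drawn uniformly from ranges typical of stroke cohorts (age 29–79,
education 10–20 y, 12–62 months post-stroke).

All randomness flows from one integer seed through
`np.random.SeedSequence(seed).spawn(3)` (tractograms / lesion layout /
behaviour), so cohorts are bit-reproducible.

### Packaged reference table

`load_reference_table()` returns a 29-patient behavioural table (six task
percentages, demographics, lesion volume) used by the scoring utilities
and acceptance checks. Its impairment counts under the cutoffs above are:
meaningless 1, production 2, recognition 2, single-object use 3,
multi-object use 7, figure copying 7; 14 patients used the right hand and
15 the left.

## 3. Disconnectome engine

For one patient:

1. **Rasterise** every control streamline once: each polyline segment is
   walked at sub-voxel steps (`step_fraction` × voxel size, default 0.5)
   and each sample point is assigned to the voxel containing it
   (nearest-centre rounding). The result is a sorted set of unique flat
   voxel indices. Point sampling is *sound* (every reported voxel truly
   intersects the polyline — verified in the tests against an exact
   segment/box slab oracle) and asymptotically complete; halving the step
   only adds boundary-grazing voxels.
2. A streamline is **disconnected** when its voxel set intersects the
   lesion (binary masks only; probabilistic inputs are binarised at 0.5
   with a warning).
3. The per-control **visitation volume** is the binary union of the voxel
   sets of all disconnected streamlines — the whole streamline is marked,
   not just the lesioned part.
4. The **disconnection probability map** is the mean of the visitation
   volumes across controls; values are therefore multiples of
   1/n_controls in [0, 1] and monotone non-decreasing under lesion growth.

`cohort_disconnection_maps` rasterises each control exactly once and
reuses the voxel sets for all patients.

## 4. Group-level inference

The design per task is `[intercept, z(score), age, lesion volume]` with
the z-scored task score as the tested covariate (contrast column) and the
others as nuisances. Voxels enter the analysis mask when at least
`min_patients` (default 2) patients have nonzero disconnection *and* the
across-patient variance is positive.

**Freedman–Lane permutation.** The reduced (nuisance-only) model is fitted
once; its residuals are permuted with a **common relabelling across all
voxels** per iteration (preserving the spatial dependence needed for
max-statistic FWE control) and added back to the reduced-model fit. For
each of `B` relabellings the full-model t statistic of the contrast is
recomputed (vectorised across voxels);

- uncorrected p = (1 + #{|t_b| ≥ |t_obs|}) / (B + 1) — the observed
  labelling counts as one relabelling, so the smallest attainable p is
  1/(B+1) and the test is exact at any B;
- FWE p compares each voxel's |t_obs| with the permutation distribution of
  the **maximum** |t| over the mask.

When the number of distinct permutations `n!` does not exceed `B`, the
implementation warns and **enumerates all n! relabellings exactly**
(identity included, p = count/n!, tie tolerance 10⁻¹²). Tests verify exact
agreement with a statsmodels-based enumeration oracle at n = 4, nominal
type-I error calibration under a true null (empirical rate within the
95% binomial interval of α = 0.05 over 500 replicates), invariance to
affine rescaling of nuisance covariates, and p_fwe ≥ p_uncorr everywhere.
At the recovery problem size (29 patients, ≈2000 mask voxels), B = 5000
runs in ≈1.5 s; B below ≈5000 leaves visible Monte-Carlo wobble in which
borderline clusters survive FWE thresholding.

## 5. Single-case inference

**Crawford–Howell t.** For a case value x* against a reference sample with
size n, mean m and (n−1)-denominator SD s:

    t = (x* − m) / (s · √((n + 1)/n)),  df = n − 1,

treating m and s as estimates rather than parameters.

**Bayesian test of deficit.** Per Monte-Carlo draw: population variance
ψ ~ (n−1)s²/χ²(n−1), population mean μ ~ N(m, ψ/n), tail
Φ((x* − μ)/√ψ) (lower tail for deficit, upper tail for excess
disconnection). The point estimate is the mean tail across draws and the
95% credible interval its 2.5/97.5 percentiles. In expectation the
estimate equals the frequentist one-sided Crawford–Howell p **exactly**;
the acceptance test verifies agreement at 200 000 draws across 20 random
case/reference pairs within Monte-Carlo error (Šidák-adjusted 3-SE family
bound). A seed is mandatory; iterations < 1000 are rejected.

**Voxel-wise application.** The case map is compared with ≥ 3 reference
maps at every analysis-mask voxel (upper tail: more disconnected than the
cohort), chunked 256 voxels at a time with independent `SeedSequence`
spawns per chunk. Zero-variance reference voxels are handled explicitly:

- case equal to the constant reference value → voxel excluded from
  testing (NaN, outside the tested mask);
- case discrepant in the tested direction → p = 1/(iterations+1), the
  smallest attainable Monte-Carlo p, flagged in `zero_variance`;
- discrepant the other way → p = 1 − 1/(iterations+1), flagged.

All tested p values are clipped to [1/(iterations+1), 1] before FDR so no
voxel claims more precision than the Monte-Carlo resolution supports.

**FDR.** Benjamini–Hochberg step-up over the tested voxels
(statsmodels `multipletests`, verified in the tests against a brute-force
step-up enumeration on all set sizes ≤ 10); a voxel is significant when
its adjusted q < 0.05.

## 6. Behavioural scoring utilities

`score_task` converts item-level rater sheets to percent scores
(100 · Σ points / max total) with errors naming the offending patient,
task and item; `average_coders` averages two raters' percentages;
`cohens_kappa` implements the marginal-product chance-agreement formula
(degenerate tables with expected agreement 1 return κ = 1 for perfect and
0 otherwise; cross-checked against scikit-learn in the tests);
`below_cutoff_count` applies the strict cutoff rule and returns the
impaired patients by ID.

## 7. Pipeline, formats, provenance

`run_pipeline` / `praxmap run` chain simulate → disconnect → group GLM →
single case (cases = all patients below the linked-task cutoff, or the
worst scorer if none). Outputs: NIfTI volumes (float32), TRK/TCK
tractograms, CSV behaviour, JSON sidecars. Every sidecar embeds a 12-hex
SHA-256 digest of the canonicalised run configuration, so artefacts from
different configurations cannot be confused; re-running the same
configuration is bit-identical (verified by checksum in the tests). YAML
configs reject unknown keys.

## 8. Limitations

- The phantom is deliberately minimal: straight bundles, spherical
  lesions, linear lesion–behaviour coupling. It validates the inferential
  machinery, not anatomical realism; real tractograms and lesion masks
  can be supplied through the same TRK/TCK/NIfTI interfaces.
- Rasterisation is point-sampling at half-voxel steps: boundary-grazing
  voxels may be missed (never spuriously added). Decrease
  `step_fraction` for stricter completeness at linear cost.
- The disconnectome treats any lesion–streamline intersection as complete
  disconnection of the whole streamline — no partial damage model.
- Max-statistic FWE control assumes exchangeability of the reduced-model
  residuals; heavy heteroscedasticity across patients would violate it.
- Voxel-wise single-case tests inherit the small-n behaviour of the
  Crawford–Howell test: with 28 references the smallest achievable
  uncorrected p is bounded away from 0, so FDR survival requires sizeable
  discrepancies.
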