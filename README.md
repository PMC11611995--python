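# praxmap

Voxel-wise mapping of white-matter **disconnection** underlying praxis
deficits (limb apraxia) after left-hemisphere stroke — with a fully
synthetic, self-contained phantom so every analysis runs offline on a
laptop in seconds.

## The scientific problem

Skilled voluntary movement (tool use, gesture imitation, pantomime) can be
impaired after stroke even when elementary motor function is intact. A
long-standing question is whether such praxis deficits are better explained
by the grey matter a lesion destroys or by the white-matter connections it
interrupts. The *indirect disconnectome* approach answers this without
diffusion imaging of the patients themselves: a patient's binary lesion
mask is intersected with normative tractography from healthy controls, and
every streamline passing through the lesion is marked as disconnected. The
voxels visited by disconnected streamlines, averaged across controls, give
a voxel-wise **probability of disconnection** in [0, 1]. Two complementary
inferences then link disconnection to behaviour:

1. **Group level** — a voxel-wise general linear model relates each
   patient's praxis score (with age and lesion volume as nuisance
   covariates) to disconnection probability, with non-parametric
   Freedman–Lane permutation inference and max-statistic family-wise error
   (FWE) control.
2. **Single case** — each patient is compared with the remaining cohort at
   every voxel using the Bayesian single-case test of deficit (the
   Monte-Carlo analogue of the Crawford–Howell t-test), with
   Benjamini–Hochberg false-discovery-rate (FDR) control.

`praxmap` implements this full pipeline: a synthetic cohort generator
(phantom tractograms with a *planted*, recoverable lesion–behaviour
effect), the disconnectome engine, both inference routes, behavioural
scoring utilities with published cutoffs, and NIfTI / TRK / TCK / CSV /
YAML interfaces.

## Core model

- **Phantom space**: 32×32×32 voxels at 2 mm isotropic resolution.
- **Tractograms**: three straight bundles (a target, a crossing bundle and
  a diagonal distractor); each control subject gets an independent jittered
  copy (per-streamline Gaussian perpendicular offset, SD 1.25 mm).
- **Lesions**: spherical binary masks. One patient's lesion is centred on
  the target bundle (the impaired case); the others sit at graded
  clearances from it or on distractor bundles.
- **Behaviour**: six praxis tasks scored as percentages. The task linked to
  the planted effect decreases linearly with the fraction of target
  streamlines the lesion disconnects, plus Gaussian noise.
- **Disconnection map**: for each control, a streamline is disconnected if
  its voxel trace intersects the lesion; the binary visitation volume of
  disconnected streamlines is averaged across controls, so map values are
  multiples of 1/n_controls.
- **Inference**: Freedman–Lane permutes reduced-model residuals with a
  common relabelling across voxels (exact enumeration when the sample is
  small enough); the Bayesian test of deficit samples the reference
  population variance from a scaled inverse chi-square posterior and the
  mean from its conditional normal, and in expectation equals the
  Crawford–Howell one-sided p exactly.

Details, parameter rationales and numerical conventions are in
[docs/methods.md](docs/methods.md).

## Run the tests

```bash
python -m pytest tests/ -q
```

The suite (~150 tests, ≈25 s) includes property-based tests (hypothesis,
derandomised), independent oracles (statsmodels OLS, exhaustive permutation
enumeration, brute-force Benjamini–Hochberg, exact segment/voxel geometry)
and one acceptance test per headline claim in `tests/test_acceptance.py`.

## Worked example

```python
import numpy as np
import praxmap as pm

# 1. simulate a stroke cohort on the packaged 32x32x32 phantom (2 mm voxels)
cohort = pm.generate_cohort(pm.default_config(seed=0))
print(f"{len(cohort.lesions)} patients, {len(cohort.tractograms)} controls")

# 2. lesion -> disconnection probability maps through the control tractograms
maps = pm.cohort_disconnection_maps(cohort.lesions, cohort.tractograms,
                                    cohort.space)
print("map value range:", maps[0].volume.min(), "-", maps[0].volume.max())

# 3. group-level permutation GLM (Freedman-Lane, max-statistic FWE)
res = pm.group_glm(maps, cohort.behaviour, "meaningless", B=5000, seed=11)
sig = pm.threshold_map(res, 0.05)
print(f"FWE-significant voxels: {sig.sum()}, "
      f"peak |t| = {np.nanmax(np.abs(res.t_map[sig])):.2f}")

# 4. single-case inference for the worst-scoring patient
scores = cohort.behaviour["meaningless"]
case = int(np.argmin(scores))
print(f"case: patient {case}, score {scores.iloc[case]:.1f} (cutoff 75.0)")
mask = pm.build_analysis_mask(maps, min_patients=2)
refs = [m for j, m in enumerate(maps) if j != case]
sc = pm.voxelwise_single_case(maps[case], refs, mask,
                              iterations=10_000, seed=12)
print(f"FDR-surviving voxels: {sc.significant.sum()}")

# 5. the classical single-value test behind step 4
t, df, p = pm.crawford_howell_t(
    8.0, pm.ControlSummary.from_sample([10., 12., 14.])
)
print(f"Crawford-Howell: t = {t:.3f}, df = {df}, "
      f"one-sided p (deficit) = {1-p:.4f}")
```

Output:

```text
29 patients, 10 controls
map value range: 0.0 - 1.0
FWE-significant voxels: 175, peak |t| = 5.73
case: patient 0, score 59.6 (cutoff 75.0)
FDR-surviving voxels: 350
Crawford-Howell: t = -1.732, df = 2, one-sided p (deficit) = 0.1127
```

Both routes recover the planted target bundle: the significant sets overlap
the true bundle voxels with Dice ≈ 0.6 (group GLM) and ≈ 0.6–0.9 (single
case) across seeds.

### Command line

Every stage is also a CLI subcommand operating on standard file formats
(NIfTI lesions/maps, TRK/TCK tractograms, CSV behaviour, YAML config):

```bash
$ printf 'seed: 1\nn_patients: 10\nn_controls: 3\npermutations: 200\niterations: 2000\n' > demo.yaml
$ praxmap run --config demo.yaml --out demo
INFO stage simulate
INFO stage disconnect
INFO stage group-glm
INFO stage single-case
lesions: demo/lesions
tracts: demo/tracts
behaviour: demo/behaviour.csv
disconnectomes: demo/disconnectomes
group_glm: demo/group_glm
single_case: demo/single_case
provenance: demo/provenance.json
```

`praxmap simulate`, `praxmap disconnect`, `praxmap group-glm`,
`praxmap single-case` and `praxmap behaviour summary` run the stages
individually; see `praxmap <cmd> --help`.

## Behavioural reference table

The package ships a 29-patient praxis assessment table
(`pm.load_reference_table()`) with six task scores (percent correct),
published impairment cutoffs (`pm.PRAXIS_TASKS`), demographics and lesion
volumes, used by the scoring utilities and the acceptance checks:

```python
>>> table = pm.load_reference_table()
>>> pm.below_cutoff_count(table["meaningless"], 75.0,
...                       table["patient_id"].tolist())
(1, ['S2'])
```

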