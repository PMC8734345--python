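# kbplan

Knowledge-based automated radiotherapy planning for brain tumours, on
synthetic head phantoms.

Manual inverse planning for brain radiotherapy is an iterative,
operator-dependent search for an acceptable dose distribution. `kbplan`
implements the automated alternative end to end: it learns the
relationship between per-voxel image/geometry features and delivered dose
from an atlas of prior criterion-passing plans, predicts a dose
distribution for a new case, and converts the prediction into a
deliverable plan by inverse optimization — then evaluates the result the
way a clinic would, with DVH metrics, a criterion table and paired
statistics. It is aimed at researchers studying knowledge-based planning
(KBP) pipelines who need a fully reproducible, patient-data-free testbed.

## The method

For a prescription of 54 Gy in 30 fractions (5400 cGy):

* **Atlas regression forests (ARF).** Each atlas case trains its own
  random forest mapping voxel features — intensity, Gaussian pyramid,
  local texture, signed distances to PTV/brainstem/chiasm/body, normalised
  PTV-centred coordinates — to that case's dose. For a new case the k = 3
  anatomically most similar atlases (by a PTV/OAR geometry descriptor) are
  evaluated and softmax-weighted into a per-voxel mean u and spread s.
* **CRF spatial refinement.** The prediction minimises
  `E(d) = Σ_v w_v (d_v − u_v)² + λ Σ_{(v,v′)} a_{vv′} (d_v − d_{v′})²`
  with confidence weights `w_v = 1/(s_v²+ε)` and intensity-edge-aware
  coupling `a = exp(−ΔI²/2σ²)` — a Gaussian CRF whose minimiser is a
  sparse SPD linear solve.
* **Dose mimicking.** Nonnegative beamlet weights x for 9 coplanar beams
  (5 mm beamlets, exponential depth attenuation) minimise
  `Σ_v c_v (Ax − d_pred)_v² + γ‖Lx‖²` under monotone FISTA, with target
  and serial-OAR voxels up-weighted and beamlet-lattice smoothness
  penalised.
* **Evaluation.** Dmax (single hottest voxel), Dmean, and Dx by exact
  order statistics; a 14-row criterion table (e.g. PTV D95 > 5130 cGy =
  95% of prescription, Dmax < 5670 cGy = 105%, lens Dmax < 750 cGy) with
  strict inequalities; paired automated-vs-manual comparison with
  two-sided paired t-tests, reporting differences as automated − manual
  (negative = better sparing).

Because real patient data cannot ship with the package, a phantom module
generates reproducible head phantoms (ellipsoidal head, 20+ labelled
structures, seeded noise) with an analytic, criterion-passing reference
dose that is a deterministic function of geometry — so prediction accuracy
has a known target. See `docs/methods.md` for the full model description.

## Worked example

```python
from kbplan import RunConfig, build_atlas, generate_phantom, plan_case, train_model
from kbplan.phantom import atlas_configs

cohort = atlas_configs(11, seed=1, grid_shape=(32, 32, 32),
                       voxel_spacing=(6.0, 6.0, 6.0))
library = build_atlas(cohort[:10])            # criterion-filtered atlas
model = train_model(library, RunConfig(seed=1))

image, structures = generate_phantom(cohort[10])   # held-out case
outputs = plan_case(image, structures, model, RunConfig(seed=1))
report = outputs.criteria_report
print(f"criteria met: {report.n_met}/{report.n_assessed}")
print(report.table[["structure", "metric", "threshold_cGy", "value_cGy", "met"]]
      .head(5).to_string(index=False))
```

prints

```
criteria met: 14/14
structure metric  threshold_cGy   value_cGy  met
     GTVp    D99         5130.0 5277.203995 True
CTVp_5400    D98         5130.0 5231.082918 True
PTVp_5400    D95         5130.0 5195.793823 True
PTVp_5400   Dmax         5670.0 5373.112557 True
Brainstem   Dmax         5400.0 2261.813584 True
```

i.e. the plan delivered for the held-out phantom covers the PTV (D95 =
5196 cGy, above the 5130 cGy goal), stays under the 5670 cGy hotspot limit,
and keeps the brainstem far below its 5400 cGy tolerance. The same
workflow is scriptable from the shell:

```
kbplan generate-atlas atlas/ --n-cases 10 --grid 32 --spacing 6 --seed 1
kbplan train atlas/ model/ --seed 1
kbplan plan atlas/case000_seed*/ model/ plan/ --seed 1
kbplan evaluate plan/delivered_dose.nii.gz atlas/case000_seed*/
kbplan compare ml_doses/ manual_doses/ cases/
```

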