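# Methods

`kbplan` re-creates a knowledge-based automated radiotherapy-planning
workflow for brain tumours treated with a homogeneous 54 Gy / 30-fraction
prescription, and makes every stage testable without patient data by pairing
it with a synthetic head-phantom generator whose "clinical" reference dose
is a known, deterministic function of geometry.

## The planning model

The pipeline follows the standard knowledge-based planning (KBP) pattern:

1. **Atlas.** A library of previously "treated" cases — image, structure
   set, and reference dose — filtered by a criterion table so only
   criterion-passing plans teach the model.
2. **Per-voxel features.** For every voxel inside the body contour
   (`External`): raw intensity; a Gaussian scale pyramid at 2/4/8 mm; local
   mean and variance in a 5³ window; gradient magnitude; signed Euclidean
   distances (mm, negative inside) to `PTVp_5400`, `Brainstem`, `Chiasm`
   and `External`; and PTV-centred coordinates normalised by the head's
   equivalent-sphere radius. Distances are spacing-aware so grids of
   different resolution are comparable; anatomically absent structures
   contribute a +1000 mm sentinel so feature columns are case-invariant.
3. **Atlas regression forests (ARFs).** One random-forest regressor per
   atlas case, mapping that case's feature rows to its reference dose
   (50 trees, depth 12). Per-case forests, rather than one pooled forest,
   preserve the atlas structure and let similar cases dominate. Each
   forest's RNG seed derives from the case id (CRC-32 XOR the global seed)
   so results are invariant to atlas ordering.
4. **Atlas selection.** A geometry descriptor — PTV equivalent radius, PTV
   centroid offset from the head centroid, and PTV-to-brainstem /
   PTV-to-chiasm centroid distances, all in head-radius units — ranks atlas
   cases by (negative) Euclidean descriptor distance; the top k = 3 are
   used, weighted by a unit-temperature softmax of their scores.
5. **CRF refinement.** The weighted forest mean u and spread s feed a
   Gaussian conditional random field

   E(d) = Σ_v w_v (d_v − u_v)² + λ Σ_{(v,v′)∈N} a_{vv′} (d_v − d_{v′})²,

   with confidence weights w_v = 1/(s_v² + ε), ε = 1 cGy², 6-connected
   neighbourhoods, and appearance weights
   a = exp(−ΔI²/2σ²), σ = 50 HU-like units, which stop smoothing across
   intensity edges. With quadratic potentials the minimiser solves the
   sparse SPD system (W + λL_a) d = W u; we use Jacobi-preconditioned
   conjugate gradients started at u, which makes the recorded energy
   non-increasing per iteration (CG minimises the quadratic over a growing
   Krylov subspace). λ defaults to 2×10⁻⁶ cGy⁻², sized so the pairwise term
   matters where forests disagree by a few hundred cGy and is negligible
   where they agree.
6. **Prescription calibration.** The refined prediction is rescaled so its
   PTV D95 equals 0.95 × prescription × 1.015. Predictions inherit the
   atlas normalisation (D95 ≈ 95% of prescription) with case-to-case noise
   of ±1%, so without this step the delivered plan meets the strict
   coverage criterion only by chance. Calibrating the *input* of dose
   mimicking to the prescription is standard KBP practice and is distinct
   from renormalising the optimised plan afterwards, which this package
   deliberately does not do.
7. **Dose mimicking.** Delivery is modelled as 9 equispaced coplanar
   parallel-ray beams (a single-arc surrogate) with 5 mm beamlets;
   the influence matrix uses exponential depth attenuation
   (μ = 0.005 mm⁻¹). The plan solves

   min_{x ≥ 0} Σ_v c_v (Ax − d_pred)_v² + γ‖Lx‖²,

   with voxel weights c_v = 30 on the PTV, 5 on serial OARs (brainstem,
   chiasm, optic nerves, cord), 1 elsewhere; L penalises differences
   between neighbouring beamlets (γ = 10⁻³). "Technical delivery
   constraints" thus reduce to weight nonnegativity plus fluence
   smoothness; MLC sequencing and arc timing are out of scope. The solver
   is monotone FISTA (accelerated projected gradient with a monotonicity
   safeguard and a power-iteration Lipschitz step), terminating when the
   relative objective change stays below 10⁻⁶ for three iterations, capped
   at 2000 iterations. The PTV weight of 30 (rather than a smaller value)
   is needed because with 5 mm beamlets on 6 mm voxels a weakly weighted
   rim trades coverage for OAR sparing in the least-squares compromise.
8. **Evaluation.** Dmax is the single hottest voxel; Dmean the arithmetic
   mean; Dx the largest dose received by at least x% of voxels, by exact
   order statistics (no DVH interpolation). Criteria are strict
   inequalities — a value exactly at threshold fails. The paired comparison
   reports, per structure, the per-case difference (automated − manual),
   its mean/median/extremes, and a two-sided paired t-test; absent
   structures reduce n for that row rather than being imputed; no
   multiple-testing correction is applied (a reporting choice). Doses are
   cGy internally; Gy appears only in formatted output.

## The phantom generator

The generator emulates the *conditions* of a mixed brain-tumour cohort:
supratentorial vs infratentorial sites (≈47/53), midline/left/right
laterality (≈47/19/34), spherical GTVs of 9–14 mm radius (8–10.5 mm
infratentorially — the posterior fossa is cramped and larger tumours there
cannot meet both coverage and the brainstem limit), CTV = GTV + 5 mm,
PTV = CTV + 3 mm, and a fixed head geometry: an ellipsoidal `External`
with a bone shell, brain, paired eyes/lenses/optic nerves/cochleae/
hippocampi/temporal lobes/parotids, and midline
brainstem/chiasm/cord/pituitary/hypothalamus. Image intensities are
piecewise-constant tissue classes plus Gaussian noise (SD 10 by default),
so texture features have signal. An OAR whose volume is more than half
replaced by tumour is recorded as *absent* (not empty), mirroring
reduced-n reporting in clinical cohorts.

Margin expansions are Euclidean and isotropic in mm, thresholding the
distance transform at margin + half the smallest voxel pitch (a
surface-based convention): with a centre-to-centre threshold a 3 mm margin
adds nothing on a 6 mm grid, which would collapse GTV = CTV = PTV and make
the target-coverage criteria mutually unsatisfiable. Dilation accuracy is
therefore one voxel, and a zero margin is exactly the identity.

### The reference dose engine

The "clinical" dose is an analytic superposition of 9 equispaced coplanar
parallel-ray beams aimed at the PTV centroid, offset so one beam enters
anteriorly — this makes the beam set mirror-symmetric about the sagittal
plane, so midline phantoms receive left/right symmetric doses. Each beam
has:

* a conformal aperture: the PTV's beam's-eye-view projection expanded by a
  6 mm flash margin with a 1.5 mm Gaussian penumbra (the flash must cover
  the voxelised PTV's corner voxels, whose isolated projections would
  otherwise be heavily penumbra-shaded);
* a 6% conformal boost over the CTV projection, so target interiors are
  deliberately hotter than the PTV rim — coverage statistics (D95) then
  anchor on the rim while GTV D99 / CTV D98 clear their thresholds;
* a depth compensator equalising each ray's dose at the isocentre plane
  (a wedge/compensator surrogate that flattens the PTV);
* lens shielding by beam-angle avoidance: a beam whose lens shadow crosses
  the CTV projection is dropped entirely (at least 3 beams are always
  kept). Partially attenuating such rays instead would carve a cold streak
  through midline infratentorial targets.

Depths are ray-marched at half-voxel steps with nearest-voxel lookups —
deterministic and reproducible by an independent per-voxel loop. The
summed dose is renormalised so PTV D95 = 0.95 × prescription with a +10⁻⁶
relative headroom: the criterion "D95 > 5130 cGy" is a strict inequality,
and exact equality would make the atlas quality filter a floating-point
coin flip. Dose is exactly zero outside `External`.

With these choices every generated phantom in the default cohort passes
all 14 default criteria at 32³/6 mm, 48³/4 mm and 64³/3 mm — verified over
all site/laterality/radius combinations — so the atlas quality filter
passes by construction, as the training-set contract requires.

### What the phantoms do and do not show

The phantoms share one head geometry and an analytic, noise-free dose
model; they exercise the pipeline's machinery (feature geometry, atlas
similarity, forest regression, CRF spatial coupling, mimicking, metrics)
but not inter-patient anatomical variation, heterogeneity corrections,
scatter, or contouring noise. Recovery results on phantoms are therefore a
*correctness* check of the implementation, not evidence of clinical
performance.

## Problem sizes and numerical choices

Self-validation (`kbplan.validation.run_recovery_study`, also what
`scripts/acceptance.py` runs) uses a 10-case atlas of 32³ phantoms at 6 mm
spacing with one held-out case — the smallest grid on which the nested
margins resolve — chosen as a desk-scale experiment that completes in
about half a minute. Typical results: predicted-vs-reference MAE of 1–3%
of prescription inside `External`, delivered PTV D95 of 5190–5220 cGy, and
14/14 criteria met. Tests use the same scale, with 1×1×n chains, 8³–10³
boxes and hand-built instances for oracle comparisons (dense linear solves,
bound-constrained QP via L-BFGS-B, exhaustive order statistics, exact
sign-flip enumeration).

Degenerate inputs are defined, not crashed on: empty masks yield an
absent-structure signal (`None` metrics, not-assessed criterion rows);
all-zero paired differences give t = 0, p = 1; zero variance with nonzero
mean gives t = ±∞, p = 0; λ = 0 makes the CRF the identity; a zero
prediction yields zero beamlet weights. Known limitations: parallel-ray
(divergence-free) beam geometry; no DICOM; single prescription level;
structure vocabulary fixed to the brain-RT set; the CRF is quadratic
(continuous dose), not a discrete-label model.
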