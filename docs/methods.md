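# Methods

## Coordinate frame and sign conventions

All geometry is computed in millimetres in a sagittal plane with x positive
toward the patient's anterior and y positive superior. Input files may be
in pixels; a per-image `mm_per_unit` factor is applied on ingest, so every
downstream computation sees mm. Angles are counterclockwise-positive in
this frame, which makes extension (a lordotic contribution) positive for
ARA/RRA/KA and anterior translation positive for ST/TR. Radiographic
conventions differ between practices (some report lordosis as negative);
the convention here is fixed and documented rather than configurable, and a
consumer needing the opposite sign can negate at report time. All angles
are reported in (−180°, 180°]; anatomical values sit far from the branch
point, so no unwrapping is ever needed.

## The measurement constructions

* **Posterior tangent** of a vertebra: the directed line from the
  posterior-inferior to the posterior-superior body corner. ARA is the
  signed angle from the C7 tangent to the C2 tangent; each RRA is the same
  construction for adjacent vertebrae. Because every tangent angle is
  measured in the one shared frame, ARA = ΣRRA is an algebraic identity,
  enforced to 1e-9° on every measurement vector.
* **Segmental Cobb angle (KA)**: the signed angle between the two endplate
  lines facing each disc — the inferior endplate (pi→ai) of the upper
  vertebra against the superior endplate (ps→as) of the lower. The segmental
  Cobb reading admits several line pairings; the facing-endplate pairing is
  the standard one and has the useful property that for parallelogram
  bodies (zero endplate wedge) KA equals RRA at the same level, which the
  tests exploit as an exact identity.
* **Segmental translation (ST)**: the signed perpendicular distance from
  the upper vertebra's posterior-inferior corner to the lower vertebra's
  infinite posterior tangent line (positive anterior). A horizontal-offset
  construction would change under global patient rotation; the
  perpendicular-to-tangent construction is rigid-motion invariant, which is
  the property a segmental instability measure should have.
* **Atlas plane angle (C1H)**: the angle of the line from the posterior
  laminar midpoint to the anterior tubercle versus true horizontal. The
  digitization scheme also records a posterior-dens midpoint on C1; no
  standard measurement consumes it, so it is stored and validated but
  enters no variable.
* **TR**: x(C2 ps) − x(C7 pi), the conventional anterior head-translation
  offset. Unlike the other distance measure it is deliberately referenced
  to the image horizontal, so it is translation-invariant but not
  rotation-invariant.

Degenerate geometry (coincident defining corners) marks the affected
variable missing with a logged warning instead of failing the image, since
clinical batches should degrade per-variable, not per-study. A corner quad
whose polygon area is below 1e-9 mm² is rejected at parse time.

## Agreement statistics

For matched image pairs (t1ⱼ, t2ⱼ) with errors eⱼ = t1ⱼ − t2ⱼ:

* RMSE = √(mean e²); error SD is the (n−1) sample standard deviation; both
  the mean absolute and the mean signed error are reported (published
  tables of this kind typically print a positive "mean error", which is the
  mean absolute error; the signed mean is kept alongside because it carries
  the bias information). Some published error-SD columns are not consistent
  with any conventional definition given their printed means and RMSEs;
  this package reports the conventional sample SD only.
* ICC(2,1) — two-way random effects, absolute agreement, single measures —
  is computed from the two-way ANOVA mean squares with k = 2 raters,
  MSR/MSC/MSE, with the residual sum of squares accumulated directly from
  the residual matrix rather than by subtraction of totals (the subtraction
  form loses all significant digits precisely in the near-perfect-agreement
  regime this package must resolve exactly). The 95% CI is the standard
  F-based interval with Satterthwaite degrees of freedom. The consistency
  form ICC(3,1) is available; it ignores a constant between-trial offset,
  which the absolute form penalizes. The implementation is cross-checked
  against pingouin's in the test suite.
* R² is the squared Pearson correlation, identical to the coefficient of
  determination of the simple OLS fit of one trial on the other and hence
  symmetric in its arguments.
* Identical input series short-circuit to exactly ICC = 1.0 and R² = 1.0:
  perfect agreement is a definitional fact, and floating-point round-off in
  the general formulas would otherwise report 1 − 1e-16 for a deterministic
  annotator compared with itself.
* R² bands: super-clean ≥ 0.90, clean [0.75, 0.90), semi-clean
  [0.50, 0.75), unreliable < 0.50; half-open on the left-closed boundary so
  a printed 0.90 is super-clean. Effect-size grades: none/very-weak < 0.3,
  weak [0.3, 0.5), moderate [0.5, 0.7), strong [0.7, 1), perfect = 1.
* Pairs with a missing value on either side are dropped per variable (not
  listwise) and the exclusion count is logged. No multiple-testing
  machinery is included: the analysis is descriptive, with no hypothesis
  tests.

## The synthetic cohort

The generator parametrizes the spine directly by posterior-tangent angles:
the C7 tangent angle is the base tilt, and each level above adds its
configured fraction of the total curve α, so ARA = α and RRA = α·w exactly
— parameter recovery is an equality test, not an approximation. Bodies are
stacked bottom-up from C7's posterior-inferior corner at the origin; disc
gaps advance along the mean tangent direction between adjacent levels;
optional per-level translations shift a body along the anterior normal
(listhesis), and optional endplate wedges rotate the anterior corners about
the posterior ones, giving KA = RRA + δ_inf(upper) − δ_sup(lower) exactly.
The ground-truth ST implied by this construction is
−g·sin(Δ/2) + s·cos(Δ/2) for disc gap g, injected offset s and segmental
angle Δ, recorded analytically per image; in a straight-spine configuration
ST = s exactly. An atlas line of configurable span sits above C2 at angle η
to the horizontal, so C1H = η plus any global rotation.

Default anatomy (all configurable): body heights 18 mm for C2 and 11 mm
for C3–C7, depths 16 mm, 5 mm disc gaps, atlas span 45 mm seated 12 mm
above the C2 endplate. Cohort distributions: α ~ N(20°, 10°) (a lordotic
population with wide between-patient spread), base tilt ~ N(0°, 5°), atlas
angle ~ N(18°, 6°), equal segment shares by default with an optional
Dirichlet spread, optional Gaussian listhesis and wedge dispersions
(defaults 0: a structurally clean cohort), and a mild global pose jitter
(rotation SD 2°, translation SD 20 mm). These are plausibility choices for
an adult cervical population; no distributional summaries of a real cohort
back them, which is exactly why the generator records exact truth instead
of aiming at population realism.

Annotator noise is isotropic Gaussian per landmark and per trial. The
default σ = 0.16 mm was fixed by propagation: a tangent over a body of
height h perturbed at both endpoints has angular error SD √2·σ/h, so the
ARA test–retest difference across two trials has
SD = 2σ·√(1/h₂² + 1/h₇²) ≈ 12.2σ degrees ≈ 2.0° at σ = 0.16 — the error
scale reported for trained raters on this protocol. The deterministic
annotator applies one fixed perturbation per image (default: none, i.e. it
returns truth) and replicates it on every re-measurement, so comparing it
with itself is an exact identity experiment by construction. Randomness is
fully labelled: a master seed plus (rater, image) indices feed
`numpy.random.default_rng`, so a given configuration reproduces every file
byte-for-byte; run manifests carry the seed and a config hash but no
timestamp, keeping output directories bit-reproducible.

### What the simulation does and does not show

Passing tests on synthetic cohorts establish that the geometry is exact,
the statistics are correctly implemented, and the pipeline is deterministic
end to end. They do not establish human-rater error structure: real
annotation errors are anisotropic (worse along degenerated endplates),
correlated between neighbouring landmarks, and image-quality dependent,
none of which the isotropic model captures (a per-landmark σ map is the
only concession). Published construct-validity numbers against expert
raters on real radiographs cannot be reproduced from simulation and are
not targeted; where such printed values are used at all (the R² band
classification), they are inputs, not outputs. One visible consequence of
the clean default cohort: segmental translations have almost no
between-patient variance when listhesis dispersion is off, so their ICCs
are low even though their RMSEs (~0.4 mm) are small — ICC is a
variance-ratio statistic, and the simulation makes that dependence
explicit rather than hiding it.

## Numerical choices

* Angle kernel: `atan2(cross, dot)` of unit vectors; −180° is folded to
  +180°.
* Quad degeneracy: shoelace area with a 1e-9 mm² threshold; tangent and
  endplate constructions additionally reject coincident corners.
* File round-trips preserve coordinates to better than 1e-9 mm in both JSON
  and CSV (full shortest-round-trip float printing).
* ICC estimates and CI bounds are clamped to [−1, 1]; zero subject *and*
  residual variance raises an undefined-statistic error rather than
  returning a number.
* Problem sizes in the test and acceptance runs — 254-image cohorts,
  1000-set geometric property sweeps, 200 Monte-Carlo ICC replicates —
  were chosen to match the repeated-measures design being emulated and
  complete in seconds.

## Known limitations

* Starts at landmark coordinates: no image processing or automatic
  landmark detection.
* Two raters/trials only; no >2-rater designs, no Bland–Altman output.
* The pixel-to-mm calibration procedure of clinical software is abstracted
  into a single per-image scale factor.
* Neutral lateral posture only; flexion/extension poses are out of scope.
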