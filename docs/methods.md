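# Methods

## The procedure

`sensekit` implements a one-at-a-time (OAT) sensitivity analysis for
varus/valgus FE knee simulations. One modelling parameter is moved off its
calibrated baseline at a time; for each perturbed configuration a varus and a
valgus simulation are (re)run; four outcome parameters are extracted and
compared against the baseline run; per-parameter aggregates are binned onto a
qualitative 0–3 influence scale. The package covers everything downstream of
the FE solve, plus a synthetic stand-in for the solve itself.

### Design enumeration

The design comprises 101 perturbed configurations per model:

| category              | axes                                                                    | plans |
|-----------------------|-------------------------------------------------------------------------|-------|
| ligament/meniscus     | prestretch ±0.1 step 0.025 (8 × 4 ligaments); Young's modulus ±100 MPa step 25 (8 × 4); attachment node sets (3 × 4); horn stiffness {5, 10, 20} N/mm per spring | 79 |
| cartilage contact     | Augmented Lagrangian on; penalty factor {0.5, 2, 5, 10}; auto-penalty on; two-pass off; search radius 1 | 8 |
| simulation control    | Quasi-Newton {BFGS, Broyden} (with max_ups = 10); displacement tolerance 0.001 | 3 |
| rigid cylindrical joint | force penalty {5,000, 20,000} N/mm; moment penalty {5,000, 10,000, 20,000} Nmm/rad; gap and angular tolerance sweeps | 11 |

Enumeration is deterministic (category → axis name → ligament → value) and
plan identifiers are stable strings, so manifests are reproducible
byte-for-byte. Single-value settings (Augmented Lagrangian, auto-penalty,
two-pass, search radius, displacement tolerance, Quasi-Newton method) are
categorical axes; a perturbed Young's modulus that would be non-positive is a
hard configuration error rather than a clamp, since clamping would silently
change the design. Meniscus horn stiffness applies uniformly to all 18
springs of a horn attachment, so the total per-horn stiffness spanned by the
design is 18–360 N/mm (parallel springs).

**Attachment halving.** The perturbed attachment condition replaces the full
tied-contact node set (set 1) with its anatomical half (set 2): the most
proximal half at the femoral end, the most distal half at the tibia/fibula
end, by projection onto the proximal-pointing axis. For odd counts the half
rounds up (`|set2| = ceil(|set1|/2)`) — the convention is not dictated by the
construction, and round-up is the deterministic choice closest to "half";
projection ties break by node id for cross-platform reproducibility. Three
perturbed combinations are run per ligament — (set1, set2), (set2, set2),
(set2, set1) — the fourth combination, (set1, set1), being the baseline.

**Loading schedule.** Time runs 0–3 in phases: prestretch application,
rotation to the experimental flexion angle (with an extra −20 N axial settle
phase for the oks-family schedule; the sign convention of that settle load is
schedule metadata only), rotation to 0° flexion, application of 0.5 body
weight of axial load (0.5 · mass · 9.81 N, rounded to 0.01 N — "model
specific" is read as half the specimen's weight), then a linear varus/valgus
moment ramp from 0 at t = 2.0 to ±40,000 Nmm at t = 3.0. Hence t = 2.25
corresponds to 10,000 Nmm of applied moment — the convergence threshold the
analysis uses.

### Outcome extraction and comparison

* **Convergence**: `100·|t_int − t_orig| / t_orig` on last converged time
  steps. The signed value is retained as a diagnostic column; the rated
  metric is the magnitude.
* **Exclusion rule**: a run whose last converged step is ≤ 2.25 is excluded
  from the kinematics/pressure/location comparisons (its early stop *is* its
  convergence outcome, so it still enters the convergence mean). A baseline
  that fails this is a group-level error.
* **Analysis time**: pressure and location are evaluated at one time step
  per parameter of interest — the *latest* step present in the converged
  kinematics of the baseline and every retained run, required to exceed
  2.25. Taking the latest common step maximises the applied moment and
  therefore the discriminative power of the comparison.
* **Valgus RMSE**: computed on the perturbed run's converged steps, clipped
  to the baseline's converged span, with the baseline valgus angle linearly
  interpolated (never extrapolated). Differencing is restricted to the
  moment window (t ≥ 2.0): the settling phases are identical across group
  members by construction and would only dilute the RMSE. All six DOF are
  stored; only the valgus/varus rotation is rated.
* **Peak contact pressure**: faces with pressure strictly > 0 form the
  contact set; the top `ceil(0.1·n_contact)` by pressure (minimum one face)
  are averaged, unweighted, for both the peak value and its mean-centroid
  location. `ceil` avoids empty top sets on sparse contact; ties at the
  cutoff are resolved by face id so the result is order-independent. Sides
  are compared separately and the two percentages/distances averaged; a side
  with no baseline contact is dropped from the average and flagged.
* **Aggregation**: arithmetic mean per metric over the non-excluded runs of
  one parameter of interest, varus and valgus kept separate, with the
  excluded count reported.

### Rating

Each aggregated metric is binned onto {0, 0.5, 1, 1.5, 2, 2.5, 3}. `x = 0`
scores 0; the remaining bins are lower-exclusive/upper-inclusive with bounds

| score | convergence % | valgus RMSE (deg) | pressure % | location (mm) |
|-------|---------------|-------------------|------------|----------------|
| 0.5   | ≤ 1           | ≤ 0.2             | ≤ 1        | ≤ 0.2          |
| 1     | ≤ 5           | ≤ 0.5             | ≤ 5        | ≤ 0.5          |
| 1.5   | ≤ 10          | ≤ 0.9             | ≤ 10       | ≤ 1.25         |
| 2     | ≤ 20          | ≤ 1.4             | ≤ 20       | ≤ 2.5          |
| 2.5   | ≤ 40          | ≤ 2               | ≤ 40       | ≤ 4            |
| 3     | > 40          | > 2               | > 40       | > 4            |

shipped as a versioned YAML config and user-overridable. Operationally,
"exact zero" is `|x| < 1e-12` in the metric's unit, to absorb float noise in
analytically-zero metrics. The order of operations is fixed: aggregate each
direction's quantitative metrics, bin each direction, then average the two
scores — which is what produces quarter-point combined ratings such as 0.75.
When only one direction yields a metric at all, the single-direction score is
reported with a `partial` flag rather than imputing the other direction.

## The synthetic generator

`synth` emulates the *shape and statistical structure* of post-processed FE
output, not knee mechanics. Its defaults define the test conditions:

* **Surface**: two disjoint elliptical face patches (medial/lateral tibial
  plateau), semi-axes 12 × 8 mm centred ±22 mm off the midline, 120 faces
  each by default, centroids sampled uniformly per patch (seeded).
* **Kinematics**: valgus rotation `θ(t) = c·k·M(t)` with compliance
  `k = 1e-4` deg/Nmm by default (4° at the full 40,000 Nmm — a realistic
  frontal-plane response) and `M(t)` the schedule's moment ramp; uniform
  time step 0.05 over 0–3, truncated at the injected convergence time `T`.
* **Pressure**: a Gaussian bump of amplitude 3 MPa (physiological
  tibiofemoral contact pressure scale) and width ρ = 0.4 × the patch minor
  radius, scaled by `s` and shifted by `d`. A face is "in contact" only
  where the *unit* bump shape exceeds a fixed support fraction (0.35 of its
  maximum; roughly a fifth of each patch, a regime where the top-10 % subset
  is meaningful); other faces carry exactly zero pressure. Making the
  support rule scale-invariant is deliberate: it keeps the contact set
  independent of `s`, so the pipeline must recover `100·|s−1|` *exactly* at
  zero noise — a sharp correctness check rather than a loose one.
* **Noise**: additive Gaussian, truncated at zero for pressures (kinematics
  σ in degrees, pressure σ in MPa; defaults 0 — the FE process being
  emulated is deterministic). The noisy-recovery checks use σ = 0.05 MPa
  (< 2 % of the bump amplitude), a small measurement-scale jitter chosen so
  noise exercises tolerance handling without the top-decile selection
  becoming the dominant effect.
* **Determinism**: each run draws from a generator seeded by (study seed,
  plan id, direction), so studies are byte-identical across reruns and
  independent of generation order.

What passing the recovery tests shows: the extraction, comparison,
aggregation and rating operators are correct on fields with the assumed
structure (one smooth pressure concentration per compartment, compliance-like
kinematic response, truncation-style convergence failure). What it does not
show: behaviour on real FE fields with multi-modal contact, element-scale
pressure spikes, mesh distortion, or coupled kinematic/contact changes — the
generator perturbs these channels independently, real parameter changes do
not.

## Numerical choices

* Times are compared after rounding to 1e-6 when intersecting converged
  grids; bundle floats are written with `%.9g` so writes are byte-stable.
* Problem sizes: the default synthetic study uses 120 faces per patch and a
  0.05 time step; the test suite drops to 24–60 faces for full-study
  (204-bundle) scenarios, which leaves every closed-form recovery property
  intact since none depends on face count. The noisy-recovery check uses
  100 seeds at 120 faces and asserts the mean error stays within 2
  Monte-Carlo standard errors.
* Location-shift recovery tolerance is one mean face spacing
  `sqrt(patch_area / n_faces)` (≈ 1.6 mm at 120 faces): the top-decile mean
  centroid cannot localise below the sampling resolution of the face cloud.

## Known limitations

* The interchange format is the package's own neutral CSV/JSON bundle; an
  importer for solver-native binary formats (e.g. FEBio plot files) is an
  extension point, not implemented.
* Contact pressure units are N/mm² (MPa) throughout; sources that print
  contact pressure in "N/mm" are read as N/mm².
* Cross-model location comparisons are never performed (coordinates live in
  each model's own frame), matching the within-model design of the analysis.
* Whether the RMSE grid should be the perturbed run's native steps (as
  implemented) or a resampled union grid is a genuine ambiguity of the
  procedure; the native-steps reading matches the stated "over all converged
  time steps of the simulation of interest".
* No statistical inference is attached to the scores: the rating scale is a
  reporting device, and a different binning would change the qualitative
  conclusions.
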