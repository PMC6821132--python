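# Methods

## The clearance-kinetics model

A population of `S` cells loses members over an `n`-day death period. At
any single histological snapshot a fraction `D` of the scored population
(visible dying cells / (live + visible dying)) appears dead or dying, and
each corpse remains visible for a clearance time `V` hours before removal.
Treating `D` and `V` as constants — averages over the death period — every
corpse visible now will be gone within `V` hours, so the population sheds
`D·(24/V)` of itself per day and

    N_T = S · (1 − D·24/V)^n,     V = 24·D / (1 − (N_T/S)^(1/n)).

Assumptions worth stating explicitly:

* **Constancy.** `D` and `V` do not vary across the window. No
  time-varying variant is provided; callers who suspect drift should fit
  sub-windows separately.
* **No gain terms.** Migration and proliferation are outside the window by
  construction (the window is chosen to start after immigration completes).
* **Denominator of D.** Visible dying / (live + visible dying). At the
  rates involved here (< 2%) the live-only alternative is
  indistinguishable.
* **Units.** `V` is always hours, `n` always days; the constant 24
  converts. `n` is accepted as any positive real although typical use is
  integer days.

Degenerate regimes raise typed errors rather than returning numbers:
`D·24/V ≥ 1` (the population would vanish within a day; geometric model
inapplicable), `N_T = S` (no decline, `V` undefined), `D = 0` with a
decline (no finite `V` exists).

### Daily-loss projection and the no-clearance band

`loss_projection` tabulates `N_k = S(1−d)^k`; `cumulative_loss` multiplies
the *mean* daily loss over the full modelled window by `k` days. This
linearized extrapolation — not the geometric partial sum over the first `k`
days — is the deliberate default because it is the procedure used to
estimate corpses accumulating when clearance is abolished (e.g. in
phagocyte-free tissue); the geometric partial sum is available behind
`geometric=True`. `corpse_density_band` repeats the calculation at the
lower, mean and upper bound of a confidence interval on `D` and divides by
tissue area, giving a (low, mid, high) expected-density band. `k` defaults
to 6 days.

`estimate_visible_fraction` builds that interval as a two-sided Student-t
interval on the per-animal fractions — the natural choice for the small
per-group sample sizes of animal studies. The lower bound may be negative
for noisy small samples; `corpse_density_band` requires a non-negative
lower bound since a negative death rate has no meaning there.

## The synthetic-data generators

### Death-and-clearance simulator

`simulate_death_process` is the generative process the closed-form model
summarizes: each live cell dies independently with per-day probability `d`,
and each corpse stays visible for `V` hours (fixed, the default) or for an
exponential lifetime with mean `V` (provided because real lifetime
dispersion is unknown). Numerical choices:

* discrete time, default step 0.1 h; per-step survival is `(1−d)^(Δt/24)`
  so the daily survival is exactly `1−d` for any step size;
* the census is taken once per simulated day at mid-day (configurable),
  avoiding the phase bias of sampling exactly at day boundaries; census
  times are snapped onto the step grid so the conservation identity
  `live + visible + cleared = S0` is exact at every snapshot;
* the step must not exceed `V`, or corpses could appear and clear unseen.

Under quasi-steady state (corpse production balancing clearance, reached
after the first `V` hours) the snapshot fraction satisfies `D ≈ d·V/24`,
which is why an instantaneous census and a per-day aggregate coincide at
these rates. `recover_clearance_time` closes the loop: from a snapshot
series alone it takes `S` and `N_T` as the first and last live counts, `D`
as the mean observed fraction, `n` as the elapsed days between them
(mid-day censuses make the live-count ratio exactly `(1−d)^elapsed` in
expectation), and solves for `V`. Over 20 replicates at `S0 = 10^5` the
median recovered `V` lands within ~5% of truth for both lifetime models;
the residual positive bias (a few percent) comes from the fraction
denominator and the finite first-snapshot burn-in and is well inside the
10% band the recovery check uses.

### Point patterns and scenes

* `generate_retina`: inhomogeneous Poisson pattern on a disc, intensity
  linear in eccentricity between a center and an edge density (the real
  center-to-periphery gradient is visible but not parameterized anywhere,
  so linearity is the simplest faithful choice). Sampled by thinning at
  the max intensity; the realized count is recorded as ground truth.
* `generate_mosaic`: dart-throwing hard-core process; radius 0 degenerates
  to a binomial (completely random) pattern. Raises a packing error when
  the attempt budget is exhausted rather than looping forever.
* `generate_quant_scene`: rasterized scene of disjoint soma disks per cell
  class, a marker mask (lysosome-like puncta inside phagocyte somata, or
  an arbor-like network of 3-px strokes grown to a target area fraction),
  debris puncta placed *fully inside* a soma of their assigned class (or
  in clear background for "unassigned"), and per-soma circumference-contact
  fractions. All truths are recorded from the construction itself (pixel
  counts, placement counts), so noiseless quantification must reproduce
  them exactly.

What the generators deliberately do not emulate: optical blur, intensity
noise beyond the thresholding tests, 3-D structure, cell migration or
proliferation, and biological variation in soma shape. Passing tests
therefore demonstrate correctness of the estimators and rules on data that
satisfy the model assumptions — not robustness to segmentation error or to
violations such as time-varying death rates.

## Stereology

Field-of-view densities from three eccentricity bands are combined as
`Σ w_r · mean(densities_r)` with area weights central 11%, middle 33%,
peripheral 56%, then multiplied by measured tissue area. Tissue area is
always an explicit input (it varies with age and is measured separately).
Landmark-based field placement is operationalized as ring eccentricities
0.15R / 0.5R / 0.9R (configurable), with 3 non-overlapping square fields
per ring at randomized angles, rejecting placements that protrude outside
the disc. On homogeneous synthetic retinas the estimator is unbiased to
within 2% averaged over 50 replicates at the default field size (0.25 mm
squares on a 2 mm disc, ~60 cells per field).

## Spatial quantification

* **Voronoi regularity index** = mean/SD of interior Voronoi domain areas.
  Boundary handling: domains that are unbounded or whose vertices extend
  past the analysis window are censored by the field edge and are excluded;
  at least 10 interior domains are required. A perfect lattice has SD = 0
  (up to double-precision rounding, detected as SD ≤ 10⁻⁹·mean) and is
  flagged degenerate instead of returning a diverging number. The index is
  scale-free. Random (binomial) patterns at n = 300 score ≈ 1.9; hard-core
  patterns score strictly higher in every paired replicate.
* **Engulfment classification**: contact fraction 0 → none; (0, 0.5) →
  touched; [0.5, 1−ε) → partially enveloped; ≥ 1−ε → fully enveloped, with
  ε = 0.005 absorbing rasterized contact measurement. Labels are mutually
  exclusive and monotone in the fraction.
* **Lysosome index** = marker pixels / cell count; fields with zero cells
  are rejected (they are discarded in practice). Series are compared on a
  0–100 scale by dividing by the series maximum — idempotent and
  order-preserving.
* **Coverage** = 100 · positive/total pixels, exactly complementary to the
  negative-space percentage.
* **Thresholding** uses the published Li and Triangle histogram methods;
  no size or circularity filters are applied by default (the standard
  particle-analysis settings impose none), though both are available.
* **Debris localization**: a punctum belongs to a class only if its entire
  pixel footprint is enclosed by that class's mask — the conservative
  reading of "enclosed on all sides" — with a centroid-membership
  alternative behind an option. Masks must be disjoint; fractions
  (including "unassigned") sum to 1.
* **Litter normalization**: measurements divided by the mean of the
  designated control group within each litter block.

Coordinate convention throughout: row-major, 0-based masks with
pixel-center semantics; physical units enter only through an optional
pixel-size factor.

## Problem sizes

Stochastic checks use 20 replicate simulations at `S0 = 10^5` for
clearance-time recovery, 50 synthetic retinas for the stereology
calibration, 50 paired mosaics (n = 300) for the regularity comparison,
and 200 Monte-Carlo patterns for the random-mosaic reference band — sizes
at which the Monte-Carlo error is several times smaller than the tolerance
being checked, while the full suite runs in seconds.

## Known limitations

* The model is single-window: no chaining of age-indexed windows with
  different rates.
* No curve fitting (exponential/quadratic decline fits) and no hypothesis
  testing are included; use standard statistics packages on the emitted
  tables.
* Scene generation is 2-D; enclosure judged from confocal stacks in real
  data is approximated by 2-D footprint containment.
* The simulator draws deaths independently per cell; spatial correlation
  of death (e.g. clustered engulfment) is not modelled.
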