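# astroclear

Tools for asking whether an observed rate of visible cell death can explain
an observed population decline, built around the developmental loss of mouse
retinal astrocytes — a population that shrinks more than 3-fold between
postnatal days 5 and 14 — together with the stereological counting and
image-quantification procedures used to measure that loss.

The audience is developmental neurobiologists and biostatisticians who have
snapshot histology (a fraction of cells that look dead or dying at one
moment) plus endpoint cell counts, and want to know what corpse-clearance
time would reconcile the two.

## The model

Each dying cell is histologically visible for a clearance time *V* (hours)
before it is removed. If a fraction *D* of the scored population is visibly
dead or dying in any one snapshot, and *D* and *V* are constant across an
*n*-day death period starting from *S* cells, the expected endpoint count is

    N_T = S · (1 − D · 24/V)^n

because *D·24/V* is the per-day loss fraction. When *S*, *N_T* and *D* are
all measured, the relation inverts to the clearance time each corpse would
need to have for the marked process to account for the whole decline:

    V = 24·D / (1 − (N_T/S)^(1/n))

A solved *V* of minutes is biologically implausible (published clearance
times for apoptotic CNS corpses are ~1–3 hours; engulfed whole cells are
degraded in ~45 minutes) and means the marked death process is too rare to
explain the decline; a solved *V* in the plausible range means it suffices.

The package provides:

* `clearance_kinetics` — the closed-form model, its inversion, daily-loss
  projections, and propagation of a confidence interval on *D* into a band
  of expected never-cleared-corpse densities;
* `synthetic_data` — seeded generators: a stochastic death-and-clearance
  simulator observed by daily snapshots, retinal point patterns with a
  center-to-periphery density gradient, hard-core vs random planar mosaics,
  and label-mask scenes with exact ground truths;
* `stereology` — total cell number from field-of-view densities sampled at
  three eccentricities, area-weighted 11% / 33% / 56%
  (central / middle / peripheral);
* `spatial_quant` — Voronoi domain regularity index (mean/SD of interior
  domain areas), engulfment classification from soma-circumference contact,
  lysosome index, arbor-network coverage, Li/Triangle auto-thresholding,
  and engulfed-debris localization under a full-enclosure criterion;
* `cli` / `io` — an `astroclear` console command over the same functions,
  CSV/TIFF readers and writers, and provenance sidecars.

## Worked example

```python
>>> from astroclear import solve_clearance_time, predict_final_count
>>> # validation: rat retinal ganglion cells, 200,000 -> 117,000 over 10 days
>>> # at a 0.5375% snapshot pyknotic fraction
>>> solve_clearance_time(S=200_000, N_T=117_000, D=0.005375, n=10)
2.4713003415181686
>>> # astrocytes: can the observed apoptotic fraction explain the decline?
>>> 60 * solve_clearance_time(S=26_987, N_T=6_513, D=0.000583, n=9)
5.745886317167599
>>> # ... only if corpses vanish in ~6 minutes. The engulfment rate, though:
>>> 60 * solve_clearance_time(S=26_987, N_T=6_513, D=0.00556, n=9)
54.79569102527423
```

The first call returns 2.47 hours — squarely in the published 1–3 hour
range for apoptotic neuron clearance, validating the model. The second
shows apoptosis is far too rare to explain the astrocyte loss (no corpse is
cleared in six minutes), while the third shows the microglial-engulfment
rate needs only a ~55-minute clearance time, close to measured engulfment
durations — so engulfment suffices where apoptosis cannot.

The same numbers from the shell:

```
$ astroclear solve-v --s 200000 --nt 117000 --d 0.005375 --n 10
V = 2.47 hours (148.3 minutes)
```

The numbered scripts under `analysis/` run the full set of analyses
(model permutations, simulation-based clearance-time recovery, stereology
calibration, mosaic regularity, scene quantification) and write their
tables under `results/`.

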