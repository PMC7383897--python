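# Methods

This note records the models behind `spiralsort`, the parameters that
matter, what the synthetic data do and do not emulate, and the design
choices made where the design was genuinely open.

## The process being modelled

The end-product of in vitro erythropoiesis is a mixture of enucleated
cells (target), nucleated cells and free nuclei, plus sub-cellular
debris. Purification is modelled in two stages: (1) inertial focusing in
a spiral microchannel with a 170 × 30 µm rectangular cross-section, six
loops and four balanced outlets, where each class settles at a lateral
equilibrium position set by the balance of shear-gradient, wall and
deformability-induced lift with Dean drag; (2) dead-end filtration of
the best outlet through a 3 µm track-etched membrane.

The focusing stage is deliberately **phenomenological**: no lift forces
are computed. The package carries a table of measured position
distributions — mean ± SD per (class, flow rate), µm from the outer
wall — and treats positions as normal draws from it. Combinations that
were never measured (nucleated cells at 0.8 ml/min, nuclei at
0.2 ml/min) are explicitly absent and any attempt to use them raises an
error; the model never interpolates or extrapolates across flow rates.

Key entries of the shipped model at 1 ml/min: enucleated 36 ± 21 µm,
nucleated 103 ± 32 µm, nuclei 154 ± 18 µm. The outward shift of the
enucleated class at high flow rate (from 131 ± 23 µm at 0.6 ml/min) is
the deformability signature the separation exploits.

## ROC construction and flow-rate selection

Separation potential between the target and a contaminant class is the
ROC over lateral-position cut-offs: sweeping x across all observed
positions, TPR(x) is the fraction of target cells at or below x and
FPR(x) the contaminant fraction. Lower position (closer to the outer
wall) is the positive direction; this orientation is fixed and
reproduces all quoted AUCs. The trapezoid AUC over (FPR, TPR) equals the
Mann–Whitney probability P(target < contaminant) up to tie handling.

Two routes exist and are kept independent: the empirical curve
(`roc_curve`, authored here) and the closed-form Gaussian oracle
`gaussian_auc` = Φ(Δµ/√(σ₁²+σ₂²)); tests require agreement within 0.005
at n = 10⁵. AUCs are computed on **untruncated** normals — truncating to
the channel changes them by < 0.01 and the quoted values match the
untruncated closed form — while the sorting simulation truncates to
[0, 170] µm, the physical support.

`select_flow_rate` simulates both class pairs per candidate and keeps
the flow rate maximizing the *minimum* available AUC; ties break toward
the higher rate (throughput preference). With the shipped table this
selects 1 ml/min over {0.2 … 1.0}.

## Outlet binning and metrics

The channel width is quartered at 0/42.5/85/127.5/170 µm into outlets A
(outer wall) through D. Binning is half-open [eᵢ, eᵢ₊₁) with the last
bin closed; a position of exactly 42.5 µm goes to B. The metrics are
defined on concentrations, but under the equal laminar four-way volume
split counts and concentrations give identical efficiencies and
purities, so both are computed from counts exactly; volumes enter only
the enrichment ratio (full capture in a quarter volume ⇒ ratio 4).

## Gating

Gating is a fixed-order partition: area ≤ 15 µm² (inclusive) → debris;
else DNA signal < threshold → enucleated; else area ≥ size cut →
nucleated, otherwise nucleus. The DNA threshold defaults to the 0.995
quantile of an unstained control's background signal, fitted per
experiment rather than fixed in arbitrary units. The nucleated/nucleus
size cut has no dictated value; the default is the midpoint of the
preset's two mean areas, overridable in `GateConfig`. CD235a is carried
on every event but unused by the default strategy; optional rectangular
(area × DNA) gates, validated pairwise disjoint, can override the
threshold logic per class. Composition summaries are reported after
debris exclusion (configurable by operating on the labelled table).

## Synthetic populations

Donor presets define class fractions and per-class distributions for
area, deformability and the two fluorescence channels. Families are
normal truncated at zero (area, deformability) and log-normal
(fluorescence, parameterized by median and log-SD); only means ± SD and
qualitative contours constrain them, so the families are a documented
modelling choice and configurable per preset.

Absolute sizes per donor are not available; area parameters were instead
solved from the Gaussian AUC closed form so the presets reproduce the
documented pairwise overlaps: donor I enucleated-vs-nuclei AUC 0.68,
donor III enucleated-vs-nuclei 0.95 and enucleated-vs-nucleated 0.56.
Deformability (dimensionless deformation index, scale ~0–0.1) always
orders nuclei < nucleated < enucleated — the invariant that holds across
donors and is enforced at preset validation — while donor II's
enucleated cells are smaller and stiffer than donors I/III's (fractions
10/60/30, vs 30/45/25 and 35/40/25; enucleated cells are 10–35 % of the
start material). Size orderings are *not* enforced, because they
genuinely differ by donor (donor II's enucleated cells are the smallest
subset). A non-donor `separable` preset with widely spaced classes
exercises the gating logic at known ground truth. Debris is generated as
an extra 5 % (default) of events with area uniform on [1, 15] µm².

Seeding: one root seed per operation, expanded through
`numpy.random.SeedSequence.spawn` into independent per-class streams;
identical (preset, n, seed) reproduces tables byte-for-byte through CSV.

What the generator does **not** emulate: differentiation kinetics,
cytometer measurement physics (no FSC/SSC, no image-derived deformation),
spectral spillover, doublets, or donor-to-donor covariance beyond the
preset means. Passing tests therefore demonstrate correctness of the
pipeline's logic under the stated statistical structure, not performance
on real cytometry files.

## Channel design numbers

Dh = 2HW/(H+W) (51 µm at default geometry), U = Q/(WH), Re = ρUDh/µ,
De = Re·√(Dh/R), α = 6WH·VF/(πa²) with VF = c·πa³/6 when a concentration
is supplied. Units are µm and ml/min at the interface, SI internally,
with conversions centralized in one module.

Two documented quirks:

* The reference design table lists velocities to two significant
  figures and Reynolds numbers derived from them, but no single rounding
  rule reproduces its full column (its printed 1.9 m/s at 0.6 ml/min is
  not the 2-s.f. rounding of the exact 1.96 m/s). `operating_table`
  uses standard round-to-2-s.f. velocities — reproducing Re = 33 and 168
  at the operating extremes — and also reports unrounded values.
* Evaluating α literally at a = 5 µm and 3–4 × 10⁶ cells/ml gives
  0.077–0.102, not the 0.153–0.255 sometimes quoted for the same
  conditions (a factor ≈ 2, as if the diameter entered the volume
  fraction twice). The implementation is the literal formula; either
  way α ≪ 1 and single-stream focusing is unchallenged.
* The curvature radius R is not specified; De is reported only when R
  is configured (R ≈ 2.22 mm reproduces De ≈ 5 at Re = 33).

## Imaging

The renderer draws dark disks on a light background (8-bit; background
220, cytoplasm 150, nuclear stain 60 by default): enucleated cells as
uniform disks, nucleated cells with a concentric darker core (diameter
ratio 0.55), nuclei as small dark disks, plus optional Gaussian noise
and a per-class area inflation factor mimicking how deformable cells
spread on the slide and appear larger than in suspension.

Detection is global thresholding (Otsu by default, fixed value optional)
after a light Gaussian smooth (σ = 1 px, disableable) that keeps shot
noise from shattering into spurious components, followed by connected
components and a min-area filter (15 µm²). Classification uses two
features: area and the fraction of object pixels below the nuclear
cutoff (default 110, midway between the cytoplasm and nuclear levels).
Small dark objects (≤ 35 µm² default) are nuclei; larger objects are
nucleated when the dark fraction reaches 0.1, else enucleated. These
cutoffs reconstruct a "threshold, outline, three classes" analysis; no
watershed splitting of touching cells and no colour deconvolution.

Lateral positions come from the same detector: centroid column minus the
outer-wall column, times the µm/px scale (affine in the wall coordinate,
which tests verify). Detections mapping outside [0, 170] µm are flagged
and excluded. Because cells are only ever observed inside the channel,
the naive sample mean of in-channel positions is truncation-biased
(≈ +2.3 µm for the 36 ± 21 µm class); `fit_position_model` therefore
offers a truncated-normal maximum-likelihood fit (Nelder–Mead on (µ,
log σ)) that recovers the underlying parameters without bias, and the
ground-truth recovery tests use it at the realistic n = 200 events.

## Membrane filtration and batch accounting

The filter is a static per-class Bernoulli passage — no fouling or
time dependence. Passage probabilities are **calibrations, not
measurements**: 0.40 (enucleated) and 0.004 (nucleated, nuclei) were
chosen once so that the documented aggregate outcome emerges from a
~70/25/5 outlet-A feed: filtrate purity ≈ 99.6 % with a 60 % enucleated
loss (inside the reported 50–70 % band) and near-total removal of
nucleated cells and nuclei. Both an expected-value mode (deterministic)
and a binomial mode (converging to it as n grows) are provided. Batch
accounting: 10 ml batches, 1.5 ml primed dead volume discarded, 5 %
sedimentation/dilution variation ⇒ recovery = (1 − dead/batch)(1 − 0.05).

The Gaussian position model reproduces the pairwise AUCs but, with the
1 ml/min parameters, puts only ~62 % of enucleated mass in outlet A —
real presorted populations evidently have skewed position distributions
that capture > 90 %. The model is therefore validated on AUCs, which it
matches; outlet capture fractions are treated as calibratable outputs,
and no attempt is made to guess the true distribution shape.

## Problem sizes and numerics

Distributional checks run at n = 10⁵ draws (AUC tolerance 0.005 against
the closed form; 3-SE parameter recovery), imaging ground-truth tests at
20-object fields and 200 in-channel events, and the end-to-end pipeline
examples at 10⁴–10⁵ events — sizes chosen to hold Monte-Carlo error well
below every asserted tolerance while keeping a full run in seconds.
Boundary conventions (debris inclusive at 15 µm²; DNA+ at signal ≥
threshold; outlet bins half-open, last closed) are fixed and covered by
tests. Degenerate inputs behave conservatively: zero-SD distributions
collapse to their location, empty images yield empty object lists,
empty outlets and all-zero classes are reported as absent rather than
raising.

## Known limitations

* No mechanistic physics: positions for unmeasured flow rates or other
  geometries cannot be predicted.
* Filter passage defaults encode one observed operating point; other
  membranes/feeds require recalibration.
* Gaussian position distributions understate outlet-A capture (above).
* The imaging rules assume well-separated, roughly circular objects on
  a uniform background.
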