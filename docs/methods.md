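# Methods

This note documents the models, conventions, and defaults behind
`opmplace`, in the order the pipeline runs.

## Task geometry

The arena is a square of side 40 cm with the origin at the SW corner
(x East, y North). Candidate object sites are the four quadrant centers
(10, 10), (30, 10), (10, 30), (30, 30). On T2 two identical objects
(base diameter 4.5 cm) occupy two quadrant centers; on T3 one object moves to
an adjacent quadrant, a displacement of exactly `side/2` = 20 cm. The
visit-detection zone around each object is the base plus a 1-cm proximity
band, giving the standard 6.5-cm zone diameter; the zone is recomputed from
the base diameter so non-default objects scale correctly.

## Synthetic sessions

The generator emulates one recording day: T1 (900 s), T2 (300 s), T3
(300 s), separated by 600-s delays. Randomness uses one named stream per
component (trajectory, unit assignment, per-unit per-trial spiking), all
derived from the session seed, so changing the number of units never
perturbs the trajectories and a fixed seed reproduces the session byte for
byte.

**Locomotion** is a persistent random walk sampled at 30 frames/s: speed is
an Ornstein–Uhlenbeck process (mean 8 cm/s, stationary s.d. 4 cm/s,
relaxation 1 s, clipped at 0), heading diffuses with 1.8 rad/√s of angular
noise, is steered toward the interior within 3 cm of a wall, and reflects
specularly at walls. These numbers were chosen once as plausible for mouse
open-field exploration — smooth, arena-covering tracks with occasional
pauses — and are knobs, not calibrated claims; no locomotion statistic of a
real dataset is being fitted. An optional object bias steers the heading
toward the nearest object inside a 12-cm radius and slows the animal inside
the zone (off by default, so behavior and spiking analyses stay
independently testable).

**Tuning** is an isotropic Gaussian bump:
`λ(x) = b + (a − b)·exp(−d²/2σ²)` with σ drawn uniformly from 3–5 cm and
baseline b = 0.05 Hz. Peak rates are drawn lognormal to reproduce the
active/inactive bimodality of real populations: active units from
lognormal(ln 8, 0.4) with a 4-Hz floor, inactive units from
lognormal(ln 1, 0.4) capped at 2.5 Hz. Spikes come from Lewis–Shedler
thinning of a homogeneous Poisson process at the tuning maximum, with the
rate evaluated at the temporally nearest frame; the time-rescaling test in
the suite confirms the realized trains are consistent with the intended
inhomogeneous Poisson law.

**Dynamics classes.** Each unit draws a T1→T2 class from a configurable
marginal distribution over {stable, unstable, emerging, vanishing,
inactive}; the T2→T3 class is drawn from its own marginal *restricted to
classes consistent with the unit's activity state at the end of T2* and
renormalised (a unit that vanished over T1→T2 can only be emerging or
inactive over T2→T3). Unstable units displace their tuning center by
8–14 cm: in a random direction for T1→T2, and along the object's move
vector for T2→T3 if the T2 center lies within 15 cm of the moving object,
against it otherwise (the "near-follows / far-opposes" rule). Centers are
clipped to a 5-cm margin so fields are only mildly wall-truncated; the
residual truncation bias on COM recovery is below ~1 cm.

**Condition effect.** The drug condition (CPP, an NMDA-receptor
antagonist) is modelled as a per-unit tuning perturbation applied to all
trials: field width × 1.8, peak attenuated to 0.75 of its excursion above
baseline, and center pulled 30% of the way toward the arena center. Saline
(SAL) is the identity. These defaults produce the qualitative signature of
interest — larger fields, lower spatial information, centrally clustered
COMs — without targeting any particular published effect size.

## Rate maps

Binning is half-open (`[i·2, (i+1)·2)` cm, last bin closed) with the SW
origin, stated once so pixel identities are reproducible across
implementations. Each frame contributes one frame period (1/30 s) of dwell
to its pixel; each spike is assigned to the pixel of the temporally nearest
frame, ties to the earlier frame (the 33-ms frame period is far below
behavioral timescales, so the choice is immaterial but must be fixed).
Pixels with dwell < 0.1 s are excluded *before* smoothing; smoothing is a
truncated Gaussian (radius 2 bins, σ = 1 bin; a 3×3 variant is available
via `radius_bins=1`) with weights renormalised over the valid support, so
excluded pixels neither contribute to nor receive values. All downstream
metrics (SI, fields, COM, similarity) use the smoothed map; similarity on
raw maps is a config option. Between-trial metrics are restricted to pixels
valid in both trials.

## Metrics and classification conventions

* SI is returned both as an information rate (bits/s) and per spike
  (rate ÷ F); bits/spike is the headline value. The 0·log 0 := 0 convention
  applies, and SI of a silent unit is an error, not zero.
* Field detection uses 4-connectivity (a literal reading of edge-sharing),
  an inclusive ≥ 10%-of-peak threshold, and an inclusive ≥ 8-pixel minimum;
  suprathreshold components not containing the peak are discarded.
* COM defaults to field-restricted when a field exists, falling back to the
  full map, with the scope recorded per row — robust to background pixels
  while staying defined for diffuse units.
* All class boundaries are inclusive as stated: active ⇔ peak ≥ 3 Hz,
  unstable ⇔ COM shift ≥ 7 cm, pyramidal ⇔ spike width ≥ 250 µs (plus a
  refractory gap in the autocorrelogram; the package consumes these as
  metadata and does not compute autocorrelograms).
* The vector index is the magnitude of the *vector* difference between the
  object move vector and the COM displacement vector. The alternative
  reading (difference of lengths) would be zero for any 20-cm field
  displacement regardless of direction, which contradicts the defining
  property that a null index means the field moved along the object's
  vector.
* The two-object preference ratio is returned in both conventions — the
  quotient R/(L+R) and the discrimination index (R−L)/(L+R) — with the
  discrimination form as headline, since only it can take the negative
  values that group means of this quantity are reported in.

## Statistics

Both samples must pass Shapiro–Wilk at α = 0.05 for the t-branch;
otherwise the configured nonparametric test runs (default KS for
continuous metric distributions, Mann–Whitney available for small-n
comparisons). Descriptives always match the test family (mean ± s.e.m. vs
median ± IQR) and are recomputed from the raw samples. The chi-square
statistic is computed without continuity correction, matching the textbook
Σ(O−E)²/E; classes with zero total count are dropped, and a table left with
fewer than two classes is an error with guidance to merge. A one-way ANOVA
wrapper exists solely for multi-group behavior summaries. No
multiple-testing correction is applied; the run log records how many tests
were run. The suite verifies the gated procedure's empirical type-I error
stays in [0.03, 0.07] over 2000 null repetitions at n = 30 per group.

## Problem sizes and numerical choices

The validation suites use 20 × 20 maps with random masks (100–200 maps per
oracle comparison, tolerance 1e-10 relative for smoothing, 1e-9 for SI and
COM), 900-s trajectories for parameter-recovery checks, 200-unit cohorts
for class-frequency recovery (judged against exact binomial 99% intervals),
and an 80-unit unstable-rich cohort for the object-vector correlation.
These sizes give tight recovery (median center error ~0.35 cm, max
~1.7 cm; Spearman ≥ 0.95 on peak-rate ranks) while keeping a full run of
suite plus acceptance script under a minute on one core.

Degenerate inputs are contracts, not silent defaults: an all-low-occupancy
trajectory, a silent unit's SI, a zero-rate COM scope, and an empty cohort
all raise with distinct messages; a missing field or an all-zero map in
field detection returns `None` (absence of a field is a result, not an
error); a constant map makes the similarity score not-a-value with a
reason code.

## What the generator does not emulate

No theta modulation, phase precession, bursting, or LFP; no multi-field
cells (one Gaussian bump per unit per trial); no spike-sorting artifacts or
cluster contamination; no head-direction or speed modulation of firing; no
session-to-session electrode drift; object bias is a crude attraction, not
investigatory bout structure. Passing the recovery suites therefore shows
the analysis chain is correct and well-calibrated on data obeying its
assumptions — it does not certify performance on real tetrode recordings,
where the above factors add variance the generator does not model.
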