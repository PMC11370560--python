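# Methods

This note records the models, conventions and numerical choices behind
`sipflow`, in the package's own words: what each stage assumes, which knobs
matter, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one reasonable option existed.

## Stream integration

Two acquisition channels share one clock: RFID antenna reads
(`t_sec, antenna, tag`; nominally 100 Hz while an animal sits at a station)
and volumetric drinking-monitor rows (`t_sec, station, volume_ul`; 1 Hz).
Timestamps are seconds from experiment start, and the experiment is taken to
start at lights-on, so zeitgeber time is `(t / 3600) mod 24` and day index
is `1 + floor(t / 86400)`.

* **Visit bouts.** A bout is a maximal run of reads of one `(tag, antenna)`
  pair whose successive gaps are ≤ `max_gap` (default **1.0 s**, chosen to
  bridge read dropout at the nominal 100 Hz rate while splitting genuinely
  separate visits).  Reads of other animals or stations interleaved in time
  do not break a bout.  Both bout endpoints are observed reads, so bout
  containment uses the closed interval `[t_start, t_end]`; every other
  binning in the package is half-open `[start, end)`.
* **Drink attribution.** A drink at station *s*, time *t* goes to the animal
  whose bout at *s* contains *t*; failing that, to the bout whose boundary
  is nearest within `tolerance` (default **2.0 s** — drinks can register a
  moment after the last read of a bout); failing that it is `UNASSIGNED`
  and only counted.  Ties break deterministically toward the earlier bout
  start.  Drinks inside overlapping bouts of two animals are physically
  unexpected; they resolve containment-first / earliest-start and are
  tallied in an `n_overlap` data-quality counter.  Attribution conserves
  volume exactly: assigned plus unassigned volume equals the input stream's
  total.

## Intake, occupancy, preference

Normalised intake is **ml/kg** = `volume_ul / body_weight_g`, using the
single roster body weight (no weight time-course is modelled).  Aggregations
are zero-filled over the full animal × substance/dose × bin grid, so group
means average over all animals and day×ZT heat-map matrices are dense;
"total" is the sum over all days, not a daily mean.  Occupancy splits each
bout exactly at hour boundaries (seconds are conserved under any further
splitting of bouts); the visit count goes to the bin containing the bout
start.

Preference is the classical two-bottle-choice volume ratio
`V_substance / (V_substance + V_water)` with both water stations and both
doses pooled, and dose preference `V_high / (V_high + V_low)`
(high = 10% ethanol, 20 µg/ml fentanyl).  Body weight cancels, so volume and
normalised-intake definitions coincide.  A zero denominator yields an
*undefined* index (NaN, `defined=False`), excluded pairwise from group
tests; imputing 0.5 would manufacture indifference.

## Polysubstance windows

Windows are fixed, non-overlapping 60-minute bins aligned to lights-on
(half-open; an event exactly on a boundary belongs to the later window).
Sliding windows would double-count events, whereas tallies over discrete
windows form a proper distribution for the nested-pie rings and their χ²
comparisons.  Collapsed mode uses {water, ethanol, fentanyl} (7 non-empty
combinations); dose-resolved mode uses the five substance/dose categories,
for which the combinatorial universe is 2⁵ − 1 = **31** — the package
enumerates all 31 and never renumbers.  Zero-count categories are retained
in every distribution so tables across groups stay conformable; columns
that are zero in *all* groups are dropped before the χ² (their expected
counts are undefined), with df computed on the kept table.  No Yates
correction and no minimum-expected-count rule are applied: sparse categories
are part of the data.

## Behavioural phenotyping

The 12 open-field / elevated-zero-maze parameters mix units (m, m/s, s,
counts), so PCA operates on z-scored columns (population SD) — equivalently,
on the correlation matrix.  Components come from an eigendecomposition of
the covariance of the z-scores, variance-sorted, each signed so its
largest-magnitude loading is positive (a deterministic convention; PCA signs
are otherwise arbitrary).  The retained dimensionality is the smallest *m*
whose cumulative explained-variance ratio exceeds **0.75**.

k-means is Lloyd's algorithm, best of `n_init` (default 10) random
initialisations by inertia; initial centroids are distinct data points; a
cluster emptied during iteration is re-seeded at the point farthest from its
own centroid (never stealing another cluster's sole member), so returned
clusters are always non-empty.  Convergence: unchanged assignment or maximum
centroid shift < 1e-6.

**Stability selection of k.**  For each k in 3…6: one reference fit on the
full score matrix, then B (default **100**) replicate fits on bootstrap
resamples of the rows, each replicate compared with the reference on the
unique resampled rows via five agreement metrics — homogeneity,
completeness, V-measure, adjusted Rand index, adjusted mutual information —
and averaged.  The recommended k maximises mean ARI (ties → smaller k), and
the full table is always emitted so a human can override (`--k 3`).  All
five metrics are computed from the label contingency table from first
principles; AMI uses the permutation-model expected mutual information and
an **arithmetic-mean** normaliser (conventions differ across the
literature; this one is stated so the numbers are comparable).

## Statistics engine

* Student's t is pooled-variance (not Welch), two-tailed, df = n₁ + n₂ − 2.
* One-way ANOVA: F = MS_between / MS_within, df (g−1, N−g); constant data
  give F = 0.
* The two-way mixed-design RM ANOVA uses the classical univariate partition:
  between-subject SS splits into group and subjects-within-groups (the group
  effect's error); within-subject SS splits into the within factor, the
  interaction, and the residual (error for both).  With unequal group sizes
  the marginal within-level means are subject-weighted and the interaction
  SS is the cell-means remainder (clamped at zero against floating-point
  cancellation).  **No sphericity correction** is applied: reported df are
  the uncorrected integers (g−1, N−g), (a−1, (a−1)(N−g)),
  ((a−1)(g−1), (a−1)(N−g)).
* Bonferroni post hoc contrasts use the ANOVA error term matching the
  contrast: subjects-within-groups MS (on the subject-mean scale) for
  between-group contrasts, residual MS for within-level contrasts;
  p_adj = min(1, m·p).
* Benjamini–Hochberg is the step-up procedure with enforced monotonicity,
  input order preserved.
* Pearson χ² drops zero-total rows/columns, applies no continuity
  correction, df = (r−1)(c−1) on the kept table.
* Tail probabilities come from scipy's t/F/χ² distributions (incomplete
  beta/gamma routines); every statistic and sum of squares is computed in
  the package.

## Synthetic cohort generator

The generator's defaults are the study conditions the analyses expect:
32 males + 24 females in single-sex cages of 4, seven days, lights on at
06:00, six stations (2× water, ethanol 5%/10%, fentanyl 5/20 µg/ml), body
weight ~ Normal(25 g, 2 g) truncated positive.

* **Visit process**: homogeneous Poisson within each phase —
  `base_visit_rate` (default 0.5 visits/h) in the light phase, ×
  `dark_rate_multiplier` (default 3) in the dark.  The two-rate step
  function is the simplest process producing the day/night contrast the
  circadian analyses bin for.
* **Station choice**: softmax over per-(phenotype, sex, category) weights.
  Defaults favour water and low-dose fentanyl; females carry a ×2 weight on
  both fentanyl doses (the planted sex × substance interaction); the three
  phenotypes tilt toward low-dose fentanyl, high-dose fentanyl, and water
  respectively.  Escalation is an additive per-day drift (default 0.1/day)
  on the log fentanyl weight.
* **Bouts and volumes**: lognormal bout duration (median 10 s, σ = 0.5);
  each visit drinks with probability 0.6, emitting 1 Hz drink rows whose
  summed volume is Gamma(shape 2, scale 100 µl) — i.e. ~200 µl per drinking
  visit, a few ml/day/animal across six bottles.  These microstructure
  parameters are invented (no public distributional facts exist for them)
  and configurable.
* **Behaviour table**: each animal draws a latent phenotype
  (mix 0.2/0.1/0.7) and a 12-vector from N(phenotype mean, Σ), clipped at
  zero.  Default means separate the three phenotypes by ≳3 within-cluster
  SDs on most parameters — a well-separated regime; the package makes no
  claim that real behavioural batteries separate this cleanly.
* Determinism: one integer seed drives everything; identical configs give
  byte-identical fixture files.

**What the generator does not emulate**: pharmacokinetics, satiety or
social dynamics between cagemates, estrous cycles, weight change, clock
drift between devices, or RFID read dropout (reads are emitted continuously
at `rfid_hz` during a bout, so synthetic streams are denser than real ones).
Passing recovery tests therefore demonstrates the pipeline's correctness
under its own assumptions, not robustness to every artefact of real cage
hardware.

## Problem sizes in tests and the acceptance script

Test cohorts use 16 animals × 2 days with `rfid_hz` 10–20; the acceptance
script's power replicates use the full 56 animals but 2 days and
`rfid_hz=10`.  Day count and read rate only scale the number of raw rows —
the intake totals' statistical structure (per-subject substance profiles)
is unchanged — so these sizes were chosen to keep simulation cost
proportionate while testing the full stream → bout → event → ANOVA path.
Phenotype-recovery runs use n = 200 animals and a stability analysis scaled
to B = 15 bootstrap replicates, n_init = 5.

## Known limitations

* The null calibration of the mixed-ANOVA interaction test on simulated
  cohorts is mildly liberal (measured Type-I ≈ 6% at α = 0.05 over 200
  replicates): intake totals are skewed count × gamma sums whose variance
  differs across substances (water alone has two stations), violating the
  compound-symmetry assumption behind the uncorrected univariate F.  This
  mirrors real intake data; a sphericity correction would trade it for
  non-integer df.  `default_substance_weights(phenotype_tilt=False)`
  produces a subject-homogeneous cohort for calibration studies.
* Overlapping same-station bouts of different animals are resolved by a
  deterministic rule, not a probabilistic model of crowding.
* Dose-resolved polysubstance tallies at desk-scale cohorts leave many of
  the 31 combinations empty; χ² on such sparse tables is reported as
  computed, without small-sample corrections.
* The bootstrap stability protocol is one concrete instantiation of
  "replicate fits under resampling + random re-initialisation"; other
  published variants (subsampling, noise injection) would give different
  absolute metric values, though the same argmax in well-separated regimes.
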