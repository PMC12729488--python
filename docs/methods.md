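# Methods

This note documents the models and procedures implemented in `koalawalk`,
the assumptions behind the synthetic-data generator, the numerical
conventions, and the limits of what the test suite demonstrates.

## The analysis chain

Raw input is a uniformly sampled 50 Hz tri-axial (optionally six-axis)
collar stream in body axes (heave, surge, sway), in m·s⁻² or g, clipped at
±4 g by the logger. The chain is:

1. **Decomposition.** Each axis is split into a static (gravity/posture)
   component — a centred 2 s rolling mean, shrunken at the edges — and a
   dynamic residual. 2 s is the conventional smoothing width in the dynamic
   body acceleration literature; it is exposed as `smooth_s`. VeDBA is the
   per-sample Euclidean norm of the three dynamic accelerometer axes; ODBA
   is its 1-norm analogue, so ODBA ≥ VeDBA ≥ 0 holds sample-wise. Per
   second we keep the max and min of VeDBA over the 50 samples: the
   peak-sensitive summary keeps brief high-intensity bursts (a few seconds
   of ground locomotion) visible through later averaging.

2. **Windowing and features.** Streams are cut into 1 s windows with 50 %
   overlap. Each window's label is the majority per-sample label; windows
   below 70 % label purity are excluded from training (the source study
   does not state how mixed windows were handled; the threshold is exposed
   as configuration). Per axis: mean, SD, min, max, range, skewness,
   kurtosis, RMS, zero-crossing count, dominant frequency, normalised
   spectral entropy, lag-1 autocorrelation. Cross-axis: pairwise Pearson
   correlations. Whole-window: mean ODBA, mean and max VeDBA, and the
   linear trend slope of the VeDBA series. Degenerate windows (zero
   variance) map NaN-producing statistics to fixed sentinels
   (correlation → 0, skewness/kurtosis → 0, spectral entropy → 0,
   dominant frequency → 0), so the feature matrix is always finite.
   With three axes this is a 43-dimensional vector; gyroscope channels,
   when present, extend the per-axis and correlation blocks.

3. **Classification.** Windows are split 60/20/20 chronologically within
   every (behaviour, individual) stratum, so no continuous behavioural
   sequence spans two sets; strata under five windows go wholly to
   training. The classifier is a Random Forest with free hyperparameters
   `number_trees ∈ [100, 1000]`, `mtry ∈ [⌈√p⌉/2, p/2]`,
   `max_depth ∈ [4, 32]`, tuned on validation macro-F1. Macro-F1 is the
   *unweighted* mean of per-class F1: that convention reproduces the
   published macro row of the reference metric table exactly, which a
   prevalence-weighted mean does not. The reported per-class "accuracy" is
   balanced accuracy, (recall + specificity)/2 — the published Bellowing
   row is consistent with this definition and inconsistent with raw
   accuracy. The search strategy is pluggable (seeded random search by
   default, a coarse grid, or any callable); the whole search is
   deterministic given the seed. Per-second labels come from the windows
   starting on whole clock seconds; the off-grid half-overlap windows act
   purely as training oversampling.

4. **Post-processing.** Per-second labels pass through: a centred 5 s
   modal filter (ties for the mode retain the original centre label — even
   when the centre label is not among the tied modes, matching the
   published rule); collapse of maximal runs shorter than 3 s into the
   surrounding state (agreeing flanks take that state; disagreeing flanks
   take the longer one; length ties take the preceding state — the source
   procedure says only "the surrounding state", so the disagreeing-flank
   rule is this package's documented choice), with missing seconds filled
   last-observation-carried-forward and leading gaps carried backward;
   regrouping of the seven model classes into General Movement in Tree,
   Motionless in Tree, Feeding & Grooming in Tree, Walking and Other; and
   non-overlapping 20 s majority bins (bin ties take the label of the
   bin's central second, consistent with the modal filter's centre
   convention) carrying the means of the within-second VeDBA maxima and
   minima. Other is excluded from budgets and models; its removal fraction
   is reported, and a fraction above 5 % raises a model-drift warning.
   Bins with over half their seconds missing are flagged as gaps.

5. **Ground visits and budgets.** Walking bins separated by ≤ 60 s cluster
   into Ground Visits (a single left-to-right pass; validated against an
   O(n²) transitive-closure reference). Daily budgets count usable bins
   per (individual, calendar day), drop days with under an hour of
   coverage, rescale to 1440 min, and summarise by averaging within
   individuals across days before averaging across individuals. Visit
   frequency divides by recorded days only. A visit crossing midnight
   belongs to the day containing its start.

6. **Diel models.** The cyclic smooth over hour-of-day is a truncated
   Fourier basis (sine/cosine pairs of the 24 h fundamental; 4 pairs by
   default for activity, 3 for the walking curve), fitted as a linear
   mixed model with a random intercept per individual. A harmonic basis is
   periodic by construction, so prediction at hour 0 equals prediction at
   hour 24 to machine precision. Responses are aggregated to (individual,
   day, hour) means before fitting, which keeps the mixed model
   well-conditioned at full deployment sizes; with sparse hour coverage
   the harmonic order degrades automatically to what the data can resolve,
   and a single individual falls back to OLS with a flag. The walking
   curve models the per (individual, day, hour) proportion of Walking bins
   on the empirical-logit scale and back-transforms predictions.
   Energetic differences across categories use the Kruskal–Wallis test on
   log-transformed per-bin VeDBA_max followed by all pairwise two-sided
   Wilcoxon rank-sum tests (mid-ranks, normal approximation) with
   Benjamini–Hochberg adjustment. Sex and habitat effects on daily walking
   minutes use a linear mixed model with a random intercept per
   individual; because both covariates vary between animals, Wald
   statistics are referred to F(1, n_animals − p) — the between-animal
   degrees of freedom — rather than the anti-conservative normal
   approximation (with nine animals this is the F(1, 6) reference the
   original analysis reports).

## The synthetic-data generator

The generator emulates the study conditions: nine wild individuals at
50 Hz for ~8 days, plus a two-animal "captive" training protocol.

**Behaviour sequencing** is semi-Markov: states are drawn with occurrence
weight budget/dwell and explicit gamma dwell-time distributions, so
bout-length structure is controllable (needed to exercise the < 3 s blip
collapse meaningfully — a per-second Markov chain would not give it).
Default wild budgets are the published daily behaviour budgets
(Motionless 385.2, General Movement 827.3 split between undifferentiated
in-tree movement and climbing, Feeding & Grooming 224.2 split
feeding/grooming, Bellowing 0.2 min/day). Occurrence intensity carries a
cosine diel modulation per behaviour (rest peaking mid-morning, in-tree
movement early afternoon, feeding/grooming early evening); the modulation
is centred on the budget-weighted common mode so the total occupancy
intensity is hour-invariant, which keeps long-run time shares at the
configured budgets (verified to < 2 % at 100 simulated days for the major
categories; the rare classes are Monte-Carlo limited — Bellowing at
0.2 min/day yields only ~40 bouts per 100 days, so its share is checked
within sampling error, not at a fixed relative tolerance).

**Ground visits** are a time-inhomogeneous process: Poisson counts at 2.95
visits/day, with 65 % of starts inside the 02:00–05:00 window and the rest
uniform over the day; per-visit walking duration is gamma (shape 3) with
mean chosen so expected daily walking time is ~3 min — the published
headline values for visit frequency and daily walking time are mutually
inconsistent with the published mean per-visit duration (2.95 × 1.59 ≈
4.7 ≠ 3 min/day), and this package resolves the conflict in favour of the
two quantities its recovery checks target. Durations are floored at 22 s
(one full analysis bin): walking bouts shorter than the 20 s bin
resolution are unobservable by the method's own construction, so
generating them would build an irreducible bias into visit-rate recovery
rather than test anything about the pipeline. Visits are kept ≥ 3 min
apart so distinct visits never merge under the 60 s gap rule.

**Signals.** Each bout renders as the gravity projection of the
behaviour's static orientation plus a dynamic component: continuous 2 Hz
oscillation for walking; intermittent bursts for feeding/grooming/in-tree
movement; large slow excursions for climbing; near-zero noise for rest.
Per-bout jitter (orientation ±0.03, amplitude log-normal ±25 %, frequency
±5 %) and broadband noise keep neighbouring behaviours partially
overlapping — the classifier task is learnable but deliberately not
trivial, and the residual confusion (feeding vs grooming vs low-intensity
in-tree movement) mirrors the confusion structure reported for the real
deployment. Canopy sway is additive slow (0.05–0.3 Hz) sinusoidal noise
applied only during in-tree behaviours, reproducing the mechanism by which
wind-blown resting animals can be misclassified as active. Signals are
clipped at ±4 g; streams can be emitted in g for format tests. The
amplitudes themselves are placeholders calibrated only to preserve the
observed energetic ordering (walking ≫ feeding/grooming > motionless);
no published per-behaviour amplitudes exist to match.

**What the generator does not emulate:** biomechanically realistic gait,
GPS movement, temperature effects, collar slippage, inter-individual
signal variability beyond random intercept-like orientation jitter, and
the captive-to-wild domain shift that degraded the real model's wild
performance (macro-F1 ≈ 0.76 captive vs ≈ 0.46 wild). Passing tests
therefore demonstrate that the *pipeline machinery* is correct and that
parameters of a known generating process are recovered through it — not
that the classifier would reach any particular accuracy on real wild
koalas.

## Problem sizes

The packaged checks run at deliberately chosen scales: the full 9 × 8-day
deployment for label-path parameter recovery (≈ 6.2 M label-seconds;
vectorised post-processing completes in seconds), a ~1.9 h-per-animal
captive protocol (≈ 28 k windows) for classifier training, 100 simulated
days for budget convergence, and 10,000 days for the visit-rate
Monte-Carlo check. These sizes put Monte-Carlo error comfortably inside
each check's tolerance.

## Known limitations

- The seven-class taxonomy is fixed; the original sixteen raw annotations
  exist only through their grouped forms.
- The cyclic smooth is unpenalised (harmonic order is the only smoothing
  control), so the reported `smooth_edf` counts active basis terms rather
  than a penalised effective dimension.
- Ground-visit duration resolution is one 20 s bin, as in the published
  procedure; sub-bin visits are undetectable by design.
- `predict_per_second` assumes windows aligned to whole seconds; streams
  must start on a second boundary (the generator and reader guarantee
  this).
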