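# Methods

This note documents the models, estimators, parameter choices and known
limitations of `docfc`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Atlas model and pair categories

A parcellation is a list of regions with hemisphere label (L/R), an
optional homologue (mirror region in the opposite hemisphere), an MNI
centroid and a voxel count.  Homologue pairing must be an involution
across hemispheres; region ids are remapped to a contiguous 0-based index
on load.  Ordered pairs partition into HLR, HRL (homologue links by
direction), LL, RR (intra-hemispheric) and LR, RL (non-homologue
inter-hemispheric); undirected analyses collapse these to HIH, LL, RR,
LR.  Homologue pairs are *excluded* from LR/RL so the categories are
disjoint and their means independent; on a fully bilateral N-region atlas
this gives N/2 pairs per homologue direction and (N/2)(N/2−1) pairs in
each remaining category — 45 and 1980 at N = 90.  Euclidean centroid
distance defines the distance stratification (default bin edges 20 and
40 mm).

## Signal conditioning

Scans are linearly detrended and band-passed to 0.01–0.08 Hz with a
zero-phase forward–backward Butterworth filter (order 4, applied per
column; `padlen` is capped at T−1 for short series).  Zero-phase
filtering is deliberate: the directed estimator depends on temporal lags,
and a causal filter's phase delay would shift them.  Both conditioning
steps are linear, so ROI averaging (unweighted voxel mean per region) and
filtering commute; the pipeline averages first.  Filter family and order
are configurable.

## Partial correlation

`PC = −P_ij/√(P_ii P_jj)` with `P = (C + ridge·I)⁻¹`.  The ridge
(default 1e−8 in the pipeline, 0 in the bare function) guards against
ill-conditioned correlation matrices; a singular matrix without ridge is
an explicit error.  Two-sided p-values use
`t = PC·√(df/(1−PC²))`, `df = T − 2 − (N − 2)`, i.e. every other region
is treated as a controlled variable.  The estimator is verified against
an independent residual-regression oracle (regress both members on all
remaining regions, correlate the residuals) to 1e−10.

## Transfer entropy

Discretisation: each series is z-scored, multiplied by `scale`
(default 3) and rounded to the nearest integer, ties away from zero
(platform banker's rounding would silently change alphabets).  At
T = 215 this yields roughly 10–25 states per series.  The z-score step
makes the estimator invariant to acquisition units while preserving the
round-to-integer mechanism; the raw-unit alternative is scanner
dependent.  A constant series maps to a single state.

The future is the circular shift `iᶠ(t) = i(t + lag)` with lag 10
samples (20 s at TR = 2 s), fixed globally; the `lag_scan` utility
reports TE against lag for justification but the pipeline never
auto-selects.  Circular shifting keeps all T samples at the cost of
`lag` wrapped, mismatched points; a truncation mode (drop the first
`lag` points) is available.  Entropies are plug-in histogram estimates
in bits (log base 2) over dense integer joint codes; the joint coding is
order-preserving, which makes the two conditional entropies cancel
*bit-exactly* when source and target are the same series — TE(x, x) is
exactly 0.0, not merely small.  Mathematically the plug-in TE is
nonnegative; floating-point residue is clipped at zero.  The all-pairs
matrix is verified against a brute-force tabulation of the full
(future, past, source-past) joint to 1e−12 bits.

Significance: the target series is randomly permuted (destroying its
temporal structure; the source stays fixed), TE recomputed per
permutation, and the add-one p-value `(1 + #{TE_perm ≥ TE_obs})/(1 + R)`
reported.  Permutations are shared across sources of a given target —
this is what makes the all-pairs test tractable (the row-wise entropy
kernel sorts R permuted code vectors at once) and is accounted for in
the calibration experiment by spreading pairs over several independent
scans.  Pipeline default R = 100; the scaled-down studies use R = 29
(α = 0.1 is exactly attainable: p ≤ 0.1 ⇔ at most 2 of 29 exceedances)
and the calibration experiment R = 99.

Small-sample bias: plug-in entropies are biased at T = 215, so absolute
TE values (~1.8–2.0 bits here) are dominated by a bias term shared by
every pair of equal-length series.  Group comparisons at matched T are
unaffected in design, but the bias has a consequence spelled out under
Limitations.

## Synthetic cohort generator

What it emulates: per-subject region-by-time matrices with the
statistical structure the analysis assumes — 215 usable volumes at
TR = 2 s, band-limited fluctuations, strong instantaneous homotopic
coupling, lagged directed influences, and a patient-like condition with
both reduced.

The model is a lagged linear recursion
`x(t) = a·x(t−1) + Σ_L W_L x(t−L) + e(t)` followed by the standard
detrend + band-pass.  Choices, with rationale:

* **AR coefficient** a = 0.3: mild own-history smoothing; the band-pass
  dominates the final spectrum anyway.
* **Homotopic coupling** is a shared innovation per homologue pair with
  amplitude `σ·√(w/(1−w))`, so the innovation correlation of a pair
  equals the configured weight w — w lives on the correlation scale.
  Defaults: control 0.8, patient-like 0.3 (× severity).
* **Directed edges** are sampled among ordered non-homologue pairs with
  source index < target index (acyclic, hence stable for any weight) and
  at most one incoming edge per target (a driven region is dominated by
  one source rather than a washed-out mixture).  Edge lag equals the
  analysis lag (10); a mismatch can be configured for robustness checks.
  Weight 3.0 and densities 0.10 (control) / 0.05 (patient-like) were
  fixed after pilot detectability runs of the TE estimator: weaker or
  more numerous edges per target fall below the shuffle test's detection
  threshold at T = 215 (per-edge rejection ~0.85 at weight 3 vs ~0.3 at
  weight 1).  An explicit stability check (companion-matrix spectral
  radius < 1) still runs before every simulation.
* **Severity** u ~ U(0.3, 1) per patient scales the homotopic weight and
  acts on edges as a retention probability (each planted edge survives
  with probability u): sicker patients keep fewer directed influences.
  CRS-R subscales are `round(max·p)` with p an affine map of u plus
  small Gaussian jitter, clipped to each subscale's range (Auditory 4,
  Visual 5, Motor 6, Oromotor/Verbal 3, Communication 2, Arousal 3;
  total ≤ 23).  Only the monotone severity→score link is modelled; the
  jitter keeps it tight (r ≈ 0.98) so recovery failures indict the
  connectivity readout, not the score model.
* **Seeding**: one cohort seed feeds a `SeedSequence` that spawns the
  atlas seed, per-subject simulation seeds and the metadata stream;
  cohorts regenerate bit-for-bit.

What it does **not** emulate: hemodynamic convolution (no balloon
model), 1/f spectra, head motion, scanner drift beyond a linear trend,
spatial structure within regions, repeated sessions, or nonstationarity.
Passing tests therefore show that the *estimators and statistics* behave
as designed on signals with the assumed structure — not that real BOLD
data satisfy that structure.

## Group statistics

Per-scan matrices are thresholded at p ≤ α (default 0.1); category means
are taken over surviving pairs and the rejected fraction recorded.  A
category whose pairs are all rejected propagates as missing, never as
zero (zeros would bias group means downward).  The two-way ANOVA
(group × category) uses Type II sums of squares via an OLS fit — on a
balanced design this equals the classical decomposition, which the test
suite asserts against a closed form; Type II is the deliberate choice
for the unbalanced cohorts the design anticipates.  Post-hoc
per-category two-sample t-tests are Bonferroni-corrected (×m, capped at
1).  Kruskal–Wallis (tie-corrected, χ² p) is the distribution-free
companion.  Link density counts ordered pairs with p ≤ α and optionally
value above a magnitude threshold — both controls are exposed because
significance-only and magnitude-plus-significance counting are both
defensible; the default is significance-only.  CRS-R correlations are
Pearson by default (Spearman by flag) and pool all patient scans.

## Scaled-down study sizes

The validation studies run at 20 regions, 15 subjects per arm, T = 215,
R = 29 permutations, 20 cohort seeds — sizes chosen so the full suite
completes in minutes on one CPU while keeping every statistical
ingredient (category structure, permutation granularity, group sizes) at
realistic proportions.  The 90-region combinatorics are asserted exactly
on the full-size atlas, which the generator produces on demand.

## Limitations

* **Mean TE is bias-dominated.**  The unthresholded all-pairs mean of
  plug-in TE responds more to subtle changes in target
  self-predictability than to planted edges: a strongly driven target
  becomes more predictable from its own past, which *lowers* its whole
  row of TE values even as the true-edge entry rises.  Pilot runs showed
  the unthresholded category means can therefore order *against* the
  planted edge density.  The pipeline's primary TE readouts are the
  thresholded category means and the link density, where detection
  dominates; this matches the analysis procedure the pipeline implements
  (threshold at p ≤ 0.1) and recovers the planted contrast in ≥ 90% of
  cohorts.
* **Per-patient score correlations are noise-limited.**  At T = 215 a
  band-limited series carries ~60 effective degrees of freedom, so
  per-scan category means fluctuate more than the severity-induced
  spread across patients.  Correlations between connectivity readouts
  and CRS-R totals at n = 12–15 patients are positive on average
  (~0.2–0.5 depending on readout) but individual cohorts can miss large
  correlation values; the tests assert the directional property, not a
  magnitude.
* **Calibration is exact only for exchangeable targets.**  Shuffling the
  target is an exact null for i.i.d. targets (the calibration
  experiment); for autocorrelated targets the null also destroys
  temporal structure, so pair-level p-values on real, band-limited
  signals are approximate.  Group contrasts compare identically
  processed arms and are insensitive to this shared miscalibration.
* Homologue pairs closer than 20 mm are rare under the synthetic
  centroid model (mirrored across the midline), so the first distance
  bin is often empty and reported as missing.
* No multivariate/conditional TE, no kernel or nearest-neighbour entropy
  estimators, no Granger causality, no mixed-effects modelling of
  repeated scans, no graph-theoretic summaries.
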