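# Methods

## The dimensionality statistic

For a T×F matrix of one modality (TOF or ATT time series at F
frequencies), columns are mean-centred — required for "explained
variance" to be meaningful — but **not** variance-scaled: channels with
larger physical fluctuation legitimately carry more variance, and the
statistic is deliberately sensitive to that. The singular values `s` of
the centred matrix give fractions `rᵢ = sᵢ²/Σs²`, and the dimensionality
is the smallest `k` whose cumulative fraction reaches the threshold.
Numerical choices:

- threshold default **0.90** (figure convention); 0.95 (the definition's
  worked illustration) is a parameter away;
- the cumulative comparison uses `≥ τ − 1e-12`, so backends that return
  0.8999999999 for an exact 0.9 spectrum still count deterministically;
- an all-constant matrix has no variance to attribute; it is flagged
  degenerate with profile `(1, 0, …)`, hence dimensionality 1;
- bounds `1 ≤ dim ≤ F` and monotonicity in τ hold for every input, and
  the value is invariant to per-column offsets and to global scaling.

Granularity: the statistic is computed **within one single measurement**
(each probe placement), then averaged over the session's 10 measurements
to a patient-day value; stacking a session into one matrix is supported
as an option. Detrending is not applied before the PCA.

## Synthetic cohort generator

The generator's role is to provide data with the *structure* the analysis
assumes and a planted ground truth for its statistics, not to reproduce
any clinical dataset. Design:

- **Arms and schedule.** 10 septic (SG) + 10 control (CG) patients,
  enrolled interleaved (P01 septic, P02 control, …); SG sessions on days
  1, 3, 7, 14 and CG on days 1, 3; 10 single measurements per session,
  256 time samples each (the sampling count of the recorded TOF/ATT
  curves is not standardised anywhere, so a power of two in a plausible
  range was fixed once).
- **Latent severity.** One draw per patient — Beta(5, 2) for SG,
  Beta(1.2, 8) for CG — plus per-day jitter (SD 0.05, clipped to [0, 1]).
- **Signal model.** Per measurement and modality, channel f is
  `baseline(f) + scale·(l_f·z(t) + a·η_f(t))`, with `z` a shared smooth
  latent series (Hann-smoothed white noise, window 16, standardised),
  `η_f` independent smooth series, loadings `l_f` spread ±25 % across the
  band, and amplitude `a = noise_floor + severity` (floor 0.15). At
  severity 0 with zero floor the construction is exactly rank one, which
  pins the statistic's lower limit; at severity 1 roughly half the
  per-channel variance is idiosyncratic and the 90 % dimensionality
  reaches ≈ 8–9. Baselines come from a toy dispersive propagation law
  (TOF = d/(c₀ + c₁f), ATT = α·f·d; path 150 mm, c₀ = 1.5 mm/µs,
  c₁ = 0.01 (mm/µs)/MHz, α = 0.05 dB/(MHz·mm)), whose small per-pulse
  noise doubles as probe-placement jitter between the session's
  measurements.
- **Clinical surface.** SOFA = clip(round(2 + 12·sev + N(0,1)), 0, 24);
  SG ICDSC = clip(round(1 + 5·sev + N(0,0.7)), 0, 8) with the inclusion
  day floored at 4 (septic patients are delirium-screen positive at
  inclusion by design); CG ICDSC ≡ 0; CAM-ICU = (ICDSC ≥ 4), the standard
  delirium cut-off. Labs are log-normal with severity-dependent location
  (lactate, PCT, creatinine, bilirubin), chosen to reproduce the
  *direction* of septic-vs-control differences, not any particular
  medians. Signal strength is drawn from N(80.9, 14.6) truncated to
  [0, 100] — metadata only; an optional minimum-strength filter defaults
  to off.

What the generator does **not** emulate: waveform-level acquisition,
skull/probe geometry, pulsatile and blood-pressure physiology,
inter-channel noise correlation, missing or corrupted sessions, and any
real covariance between labs beyond the shared severity. Passing tests
therefore demonstrate correctness and calibration of the *analysis* on
data with a known planted structure — not clinical performance.

## Feature table

Per measurement, the 20 channel series are summarised by 12 per-channel
statistics, 5 statistics per within-modality frequency pair, 4 per
TOF×ATT frequency pair (all 100 ordered pairs, since the interaction
families are the ones reported to matter), 4 spectral slopes and the two
dimensionality values — 1,096 uniquely named columns for the 10-frequency
grid under the grammar `{modality}_{f_i}[_{f_j}]_{stat}`. Patient-day
rows are the arithmetic mean of the 10 measurement-level vectors,
matching the per-day averaging convention. Degenerate correlations
(constant series) are set to 0; standardisation z-scores each column
(sample SD) with numerically constant columns mapped to zero, so
subset-PCA fitness is invariant to feature units.

## Genetic algorithm

The recipe fixes population 1,000, subset cap 15, top-2 % elite
recombination (shared features kept; one-sided features inherited with
probability 0.5), random fill of the remainder, obligatory child
mutation, 200 generations. Everything else was open and is fixed here as:

- **Elite pairing**: uniform with replacement among the elite; half the
  next generation is bred, the rest is fresh random subsets.
- **Mutation rates**: p_add = 0.002 per absent feature (≈ 2 expected
  additions per child at P ≈ 1,200), p_delete = 0.05 per present feature.
- **Caps and repairs**: crossover deletes surplus only from one-sided
  inheritance (so intersection ⊆ child ⊆ union *and* the ≤15 cap both
  hold unconditionally); mutation deletes surplus uniformly; an emptied
  subset receives one uniform feature.
- **Elite survival** (`elitism_copy`, default on): elites advance
  unmutated, making the best-fitness trace non-decreasing; switching it
  off restores fully obligatory mutation.
- **Stopping**: a fixed generation budget, with an optional early stop
  (no gain > 1e-4 for 30 generations) since "no significant improvement"
  is not an operational criterion. Fitness uses Pearson correlation on
  raw target values; evaluations are memoised per subset.

## Classification and statistics

- Labels: patient-day positive iff ICDSC ≥ 3 or SOFA ≥ 3.
- SVM: linear kernel, C = 1.0 (RBF behind a flag), features z-scored in
  the fold, and **balanced class weights** — under the ≥3 rule positive
  days heavily outnumber negative ones and an unweighted margin collapses
  to the majority class.
- Cross-validation: stratified fivefold, **grouped by patient** by
  default so no patient spans train and test; the ungrouped variant is
  available. Row order is canonicalised on (patient_id, day) keys so
  metrics do not depend on caller ordering. Undefined per-fold rates
  (single-class folds) are excluded from fold means.
- ROC: thresholds over distinct pooled out-of-fold decision values, AUC
  by trapezoid rule (equal to the normalised Mann–Whitney U, used as the
  test oracle).
- Patient-split protocol: train on the first 10 enrolled patients, test
  on the last 10, at measurement granularity; k-means (k = 2) provides an
  unsupervised agreement diagnostic while the SVM predicts; a patient is
  correct/wrong only if *all* measurement predictions agree, else
  undecided.
- Group comparison: median with linear-interpolation (type-7) quartiles;
  Kruskal–Wallis gate followed by Mann–Whitney U (exact for tie-free
  samples of ≤ 10 per arm, normal approximation with tie correction
  otherwise); chi-squared for CAM-ICU; significance at p < 0.05 with no
  multiplicity correction (a Holm option exists in scipy if wanted, but
  the report deliberately mirrors single-test reporting).
- Correlation table: the dimensionality column uses the mean of the TOF
  and ATT patient-day dimensionalities (per-modality columns are also
  emitted); the GA column uses the component trained on that same
  parameter; all days are pooled by default.

## Problem sizes

The analysis drivers and the acceptance script run the GA at population
300–400 for 50–60 generations per target (memoised fitness makes this
seconds per target at N = 60 patient-days), which is well past the
plateau of the fitness trace at this cohort size; the library default
remains population 1,000 × 200 generations. Test-suite checks use
population 30–300 and 5–60 generations on correspondingly small
problems, with the brute-force subset enumeration and the planted-feature
construction as search oracles.

## Known limitations

- The feature vocabulary is one reasonable realisation of ">1,000
  summary features"; the original feature list is not public.
- GA hyperparameters beyond the fixed recipe are this package's choices;
  results at other rates differ in speed, not in the planted-recovery
  behaviour the tests pin.
- The synthetic severity-to-score links make most label noise sit near
  the SOFA = 3 boundary in the control arm; specificity estimates on
  small cohorts are accordingly coarse (few negative days per fold).
- The pipeline's caching keys on configuration and artifact hashes, not
  on code versions; delete the output directory after editing the code.
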