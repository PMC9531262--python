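# acg — multifrequency transcranial-ultrasound (acoustocerebrography) analysis

Acoustocerebrography (ACG) sends ultrasound pulses at several carrier
frequencies (here 10, spanning 0.5–2.5 MHz) through the head and records,
per frequency, the relative **time of flight** (TOF, µs) and **attenuation**
(ATT, dB) of the transmitted component. Because brain tissue is dispersive,
the frequency channels of a healthy brain move almost in lockstep over
time; diffuse injury — e.g. sepsis-associated encephalopathy (SAE) in
septic-shock patients — desynchronises them. This package implements a
complete analysis chain for such data, aimed at ICU researchers evaluating
ACG as a bedside screen for delirium and organ failure:

1. **Dimensionality statistic.** For a T×F matrix `X` of one modality
   (TOF or ATT across F frequencies), compute the PCA explained-variance
   fractions `r₁ ≥ r₂ ≥ …` of the column-centred matrix and define

   `dim(X, τ) = min { k : Σᵢ≤ₖ rᵢ ≥ τ }`,   τ = 0.90 by default.

   `dim = 1` means all channels follow one latent dynamic; `dim = F`
   means every channel moves independently.

2. **GA feature selection.** From a table of >1,000 per-patient-day
   summary features, a genetic algorithm evolves subsets of at most 15
   features; the fitness of a subset is `|Pearson r(PC1(subset), y)|` for
   a clinical target `y` (SOFA, ICDSC, lactate, PCT, creatinine,
   bilirubin). Defaults: population 1,000, top-2 % elite recombination,
   200 generations.

3. **Evaluation.** Patient-days with ICDSC ≥ 3 or SOFA ≥ 3 are labelled
   positive; an SVM on the GA components is scored by patient-grouped
   fivefold cross-validation (accuracy / sensitivity / specificity, ROC),
   plus a first-10/last-10 per-patient classifier issuing
   correct/wrong/undecided verdicts, nonparametric arm comparisons
   (Kruskal–Wallis → Mann–Whitney U, chi-squared for CAM-ICU) and an
   absolute-Pearson correlation table.

No clinical recordings are distributed, so a **synthetic cohort
generator** (`acg.cohort`) emulates the study design: 10 septic + 10
control patients, sessions of 10 single measurements on days 1/3/7/14
(septic) and 1/3 (control), with a latent per-patient severity driving
both channel desynchronisation and the clinical scores.

## Worked example

The analysis is organised as numbered drivers that write their tables
under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 42
python analysis/02_dimensionality.py
python analysis/03_build_features.py
python analysis/04_ga_selection.py
python analysis/05_classification.py
python analysis/06_group_report.py
```

With seed 42 this prints (abridged):

```
SG day 1: SOFA median 10.5, ICDSC median 5.5, CAM-ICU positive 10/10
CG day 1: SOFA median 3.0, ICDSC median 0.0, CAM-ICU positive 0/10
SG day-1 mean dimensionality: TOF 5.75, ATT 5.77  (n=10)
CG day-1 mean dimensionality: TOF 1.37, ATT 1.37  (n=10)
feature table: 60 patient-days × 1096 features
sofa       |r| = 0.988  (14 features, 6 attenuation/interaction-based)
fivefold CV: accuracy 81.67%, sensitivity 79.64%, specificity 100.00%
ROC AUC 0.991
first-10/last-10 verdicts: {'correct': 6, 'wrong': 0, 'undecided': 4}
sofa       dimensionality 0.95   GA 0.99
```

Reading: the septic arm's frequency channels are strongly desynchronised
(mean dimensionality ≈ 5.8 of a possible 10) while controls stay near 1;
the GA finds a ≤15-feature component correlating 0.99 with SOFA and beats
the deterministic dimensionality statistic in every correlation row; the
SVM on the two GA components separates positive patient-days well, and
6 of the 10 held-out patients are classified consistently across all of
their single measurements.

The same chain is available programmatically (`acg.run_pipeline`), with
stage caching and a manifest, for use in scripts and tests.

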