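# Methods

## The problem being modelled

Non-invasive central systolic blood pressure (SBP) is estimated from a
brachial-cuff waveform transformed to an aortic waveform, calibrated
either with brachial systolic + diastolic pressure (Type I, `C1SBP`) or
mean + diastolic pressure (Type II, `C2SBP`). Validated against invasive
aortic SBP (`AoSBP`) measured during catheterization, the two
calibrations err in opposite directions: Type I underestimates (more in
women, the elderly and at high estimated SBP amplification), Type II
overestimates (more at low heart rates). The package (a) attributes
these signed errors to clinical and pulse-wave predictors, (b) builds
least-squares "adjusted" estimators of AoSBP from the two calibrated
values plus those predictors, and (c) evaluates everything with the
device-validation vocabulary: accuracy = mean(estimate − reference),
precision = SD of the differences, % within ±10 mmHg, consensus
thresholds |accuracy| ≤ 5 mmHg and precision ≤ 8 mmHg (both inclusive),
and modified Bland–Altman plots with the *reference* on the X-axis.

## Synthetic cohort generator

Because per-patient catheterization data are not redistributable, all
analyses run on synthetic cohorts whose structure encodes the phenomena
the pipeline must detect. Per patient:

1. **Covariates.** Age ~ N(65.7, 10.0²) y; female with probability 0.29;
   height ~ N(170.0, 9.8²) cm; weight ~ N(82.7, 18.7²) kg; eGFR ~
   N(80.2, 17.4²); heart rate ~ N(67.6, 12.1²) bpm; estimated pulse wave
   velocity ~ N(9.39, 1.80²) m/s; reflection magnitude ~ N(66.9, 9.1²);
   binary flags with prevalences 0.248 (smoking), 0.282 (diabetes),
   0.798 (any antihypertensive), 0.696 (statin), 0.708 (aspirin).
   Estimated SBP amplification and augmentation index (AIx@75) are
   log-normal, matched to median (IQR) 8.0 (5.0–12.0) mmHg and 20.3
   (10.6–28.1) respectively; when the printed IQR is not log-symmetric
   the two implied shape parameters are averaged.
2. **Coupling.** A Gaussian copula ties age to ePWV (+0.3), AIx@75
   (+0.3) and amplification (−0.15). The stiffness narrative implies all
   three signs; the magnitudes are assumptions (the source cohort's
   covariances are unpublished) and are config-exposed. The
   age–amplification coupling is deliberately weaker than the other two:
   at −0.3, amplification would fall ≈0.21 mmHg per year of age, which
   would cancel the −0.17 mmHg/y direct age bias below and invert the
   intended age gradient of Type-I underestimation.
3. **Reference.** AoSBP ~ N(126.5, 21.7²) mmHg.
4. **Non-invasive channels.** With `A = AoSBP − 126.5`,

       brachial SBP = 126.5 + 0.644·A + bias(age, sex) + u + e₁
       C1SBP        = brachial SBP − amplification
       C2SBP        = 126.5 + 0.628·A + over(HR, age, AIx) + u + e₂

   * `bias(age, sex) = −0.3 − 0.17·(age − 65.7) − 6.2·female` mmHg,
     reproducing strata means of ≈ −0.3 (men) / −6.5 (women) and
     +0.1 (40–60 y) / −5.7 (≥80 y);
   * `over(HR, age, AIx) = 6.2 − 0.47·(HR − 67.6) − 0.10·(age − 65.7)
     − 0.05·(AIx − E[AIx])`: +4.7 mmHg extra overestimation per 10 bpm
     decrease in heart rate, mean overestimation +6.2 mmHg;
   * the attenuations (0.644, 0.628) < 1 are regression dilution, solved
     from the marginal SDs of the cuff measures (≈17 mmHg) versus the
     reference (21.7 mmHg) together with the difference SDs
     (≈12.1–14.4 mmHg). They reproduce the characteristic *negative*
     slope of raw modified Bland–Altman plots (underestimation grows
     with AoSBP);
   * `u ~ N(0, 9.3²)` is a cuff error **shared** by both channels (both
     descend from the same oscillometric reading); `e₁ ~ N(0, 2²)`,
     `e₂ ~ N(0, 4.8²)` are channel-specific. The shared component bounds
     the aortic variance any adjusted model can recover; its SD was
     calibrated by simulation so the fully adjusted model's in-sample
     R² is 0.70 ± 0.02 at n = 500 (population R² ≈ 0.68), which places
     the full model's modified Bland–Altman slope at R² − 1 ≈ −0.30.
     With this value the generated brachial/C1/C2 difference SDs are
     ≈12.6/14.3/14.4 mmHg;
   * cuff DBP is drawn conditionally on cuff SBP (correlation 0.7,
     config-exposed) rather than independently; only DBP is redrawn on
     the rare SBP ≤ DBP conflict, so SBP marginals stay unbiased.
5. **Plausibility screens.** Whole rows with any pressure ≤ 40 mmHg,
   heart rate ≤ 30 bpm, age ≤ 18 y or non-positive anthropometrics are
   redrawn (not truncated); redraw counts are logged at DEBUG. Under the
   defaults rejections are rare (≪1%), so configured means are recovered
   within Monte-Carlo error.

The amplification column is re-derived as `brachial SBP − C1SBP` after
rounding so the defining identity holds bit-exactly, including through a
CSV write → read round trip (`float_precision="round_trip"` on read).

**What the generator does *not* emulate.** Real waveforms, device
transfer functions, non-Gaussian blood-pressure tails, measurement
repeats, missing data, or any sex/heart-rate structure in the Type-II
bias beyond the heart-rate/age/AIx terms. Passing tests therefore
demonstrate that the *pipeline* recovers structure that is present by
construction — not that the correction model would transfer to another
device or population.

## Statistical conventions

* **Accuracy / precision**: mean and sample SD (n−1) of
  (estimate − reference); ±10 mmHg band inclusive; consensus thresholds
  inclusive.
* **Strata**: age bins [40, 60), [60, 80), [80, ∞) (left-closed);
  between-stratum tests are one-way ANOVA (age) and a pooled-variance
  Student t-test (sex), both on signed differences. If every stratum has
  zero variance the p-value degenerates to 1 (equal means) or 0
  (unequal) with a warning.
* **Modified Bland–Altman**: differences regressed on the reference;
  limits of agreement are bias ± 2·SD (exactly 2). For in-sample OLS
  predictions the slope is R² − 1 exactly
  (cov(ŷ − y, y)/var(y) = R² − 1), a property asserted to 1e-10.
* **Partial R²** uses the classical sequential-SS ratio
  `(SSE₋ⱼ − SSE)/SSE₋ⱼ`, computed from the full fit's t statistic via
  `t²/(t² + df_resid)` and verified against explicit refits; several
  alternative partial-R² definitions exist, and this choice is fixed and
  documented rather than configurable per fit. Sums of partial R² are
  *not* constrained to equal the global R².
* **VIF** = 1/(1 − R²ⱼ) from regressing predictor j on the others with
  intercept; exact collinearity reports ∞ instead of raising.
* **Sex coding**: female = 1, male = 0 in every design matrix; binary
  flags are 0/1. p-values are raw (no multiplicity adjustment).
* **LASSO**: candidates standardised to unit variance, outcome on its
  native scale, penalty path by 10-fold cross-validation with
  seed-determined folds. The default penalty is the **one-standard-error
  rule** (largest penalty within 1 SE of the minimum CV error): the
  error-minimising penalty systematically retains pure-noise candidates
  (in simulation, >1 false selection in roughly half of replicates),
  while the 1SE rule keeps strong true predictors and discards noise;
  `rule="min"` and a fixed `alpha` remain available.
* **Bootstrap validation** (default scheme): B resamples of n patients
  with replacement; the model is refit on each resample and evaluated on
  the *original* cohort; metrics are averaged over B. This leaves raw
  (unmodelled) measures unchanged and mildly degrades adjusted-model
  precision/R², the expected optimism pattern. A Harrell-style
  optimism-corrected scheme (`scheme="optimism"`) is provided as the
  alternative, since published reports rarely state which convention was
  used. Rank-deficient resamples are skipped, warned about and counted.
* **Seeding**: a single pipeline seed fans out per stage by fixed
  offsets (generator +0, LASSO +1, bootstrap +2, modulo 2³¹), so stages
  are independently reproducible.

## Problem sizes used in the shipped analyses

Identities that hold by construction (zero training accuracy, the
slope = R² − 1 identity, VIF screens) are checked at the study-scale
n = 500. Parameter recovery uses n = 10,000 (coefficient within ~2 SE)
and 60 seeded replications for confidence-interval coverage; LASSO
selection consistency uses n = 2,000 over 20 seeds; the bootstrap
optimism pattern uses B = 200 over 20 seeds. These sizes give stable
verdicts for the properties asserted while keeping the default test run
quick to execute.

## Known limitations

* The generator's covariances among predictors are assumptions; only
  their signs are anchored in the arterial-stiffness literature.
* The Type-II bias model contains no sex term, so sex differences in
  Type-II accuracy arise only indirectly; cohorts will not reproduce a
  large male–female gap in C2 bias.
* The attenuation + shared-error structure is the simplest linear
  mechanism consistent with the marginal SDs, difference SDs, R² ≈ 0.70
  and negative raw Bland–Altman slopes simultaneously; it is not a
  physiological waveform model.
* `aix75` evaluates the printed augmentation-index formula on
  device-reported components; the heart-rate normalisation to 75 bpm is
  device-internal and not re-implemented.
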