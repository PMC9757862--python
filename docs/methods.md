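# Methods

## Scope and model

`dnlipid` implements a semi-quantitative DIMS lipidomics workflow: species are
identified by accurate m/z alone (no chromatography, no MS/MS), quantified as
per-mille shares of each sample's total annotated lipid signal, and related to
cohort covariates and neonatal outcomes by standard regression. The package
assumes centroided peak lists as input; profile-mode processing, centroiding,
lock-mass recalibration and isotope deconvolution are explicitly out of scope
(that territory belongs to XCMS-class tools upstream).

## Mass lists

Species are sum compositions `CLASS(c:d)` (total acyl carbons : total C=C);
sn-position and chain isomers are unresolvable at MS1 and not modeled. Each
registered class maps (c, d) to a molecular formula — e.g. TG(c:d) →
C(c+3) H(2c−2d+2) O6 — and monoisotopic masses are summed from an
IUPAC/CODATA lightest-isotope element table (verified against pyteomics to
1e-9 Da in the test suite). Adduct sets default to [M+H]+, [M+NH4]+, [M+Na]+
in positive mode and [M−H]−, [M+CH3COO]− in negative mode — standard
direct-infusion plasma practice; TG/DG ionize predominantly ammoniated. The
shipped enumeration config (`data/masslist_default.yaml`: seven classes over
plasma-typical c/d ranges) yields ~6400 entries across both polarities,
matching the several-thousand-entry annotation lists used in routine DIMS
work. Isotopologue (M+1, M+2) peaks are not enumerated: annotation is
monoisotopic only.

## Processing chain and numerical choices

Order: S/N filter → annotation window (inherent) → presence filter → QC
linearity filter → per-mille normalization → DG tagging. This order keeps
every filter's denominator well defined.

* **Annotation** — each mass-list entry takes the single nearest observed
  centroid within 9 ppm (|observed − theoretical|/theoretical × 1e6). Exact
  |ppm| ties between two peaks go to the higher-intensity peak; determinism
  everywhere else follows from sorted inputs. Two entries may legitimately
  claim the same peak (unresolved isobars).
* **Signal/noise** — one noise level per spectrum, taken from file metadata
  when present, otherwise the median intensity of unannotated peaks. Signals
  with S/N < 3 are removed (boundary 3.0 retained).
* **Presence** — a variable must be detected (> 0 after S/N) in ≥ 50 % of
  non-QC samples; the boundary is inclusive. QC samples never enter the
  denominator and never appear in the output matrix.
* **QC linearity** — Pearson correlation of raw QC intensity against the
  dilution factor (0.25, 0.5, 1.0); retained iff r > 0.75 strictly.
  Zero-variance QC responses have undefined r and are rejected. At least two
  distinct dilution levels are required; a missing QC manifest is a hard
  error, not a skipped filter.
* **Normalization** — rows are divided by their total over retained variables
  and scaled to 1000. Positive- and negative-mode variables are concatenated
  per subject *before* normalizing, so one total-lipid-signal denominator per
  individual. Normalization is idempotent to 1e-9; subsetting a normalized
  matrix triggers an explicit re-normalization warning because row sums no
  longer hold.
* **DG tagging** — in-source fragmentation makes TGs appear as DGs, so DG
  variables carry a "TG-fragment" interpretation tag; names and values are
  untouched (DG species stay reported as DG).

## Discovery statistics

Group comparison uses the equal-variance Student t-test (Welch optional);
zero-variance-in-both-groups variables are flagged and reported with p = 1.
The multiple-testing limit is 0.05/√n for n lipid variables — the
square-root form reflects their strong interdependence; at n = 430 this gives
0.00241, applied as 0.002.

The sparse PLS-DA is a NIPALS PLS1 with the centered class indicator as
response and column-standardized X: per component, the X-weight vector
w ∝ Xᵀy is soft-thresholded so only its `keep_per_component` largest
absolute entries survive (default 10 % of variables, minimum 10), scores
t = Xw, regression-mode deflation of X and y. Variables are ranked by maximum
|w| across components (default 2); the algorithm has no random element, so
ranks are reproducible. With one component and no sparsity, ranks reduce to
the absolute covariance of each standardized column with the centered label —
the closed form used as an oracle in the tests. A species is *relevant* when
it is in the top 10 loadings **and** its t-test p-value is below the
corrected limit.

## Regression

Lipid exposures are standardized to 1 SD on the complete-case subsample;
columns with |skewness| > 2 are natural-log transformed first (zeros replaced
by half the minimum positive value). OLS provides coefficients with t-based
95 % CIs; logistic models are fitted by Newton scoring (IRLS) to
|Δ| < 1e-8 within 100 iterations and reported as odds ratios with Wald CIs.
Perfect or quasi-separation is detected (diverging coefficients,
non-convergence, infinite standard errors) and raised as an error rather than
reported as a number. Ethnicity enters as indicator contrasts against White
(the largest group); parity as the nulliparous indicator. All models are
complete-case — nothing is imputed — and `n_used` counts exactly the rows
with every model variable observed. Rank-deficient designs abort with the
collinear columns named. The fully adjusted model contains maternal age, BMI,
parity, ethnicity, fasting glucose, neonatal sex and trial arm, plus
gestational age at birth for the abdominal-circumference outcome. The
total-triglyceride aggregate exposure is the per-sample sum of all TG
variables, standardized like any species.

## The synthetic cohort generator

The generator emulates the study conditions: 867 obese pregnancies
(BMI ≥ 30, log-normal truncated), a GDM fraction of 241/867 under the IADPSG
thresholds, covariate marginals matching the published group summaries (age
30.3 ± 5.7 euglycemic / 31.9 ± 4.7 GDM; ethnicity 67/21/7/5 %; abdominal
circumference centered at 32.4 cm, missing in 450/867; 1-h glucose missing in
40/867). Design choices where only marginals are known:

* **Glucose triplet** — trivariate log-normal with pairwise correlation 0.5
  and euglycemic-median locations; no published joint distribution exists.
* **GDM targeting** — a common log-scale location shift is solved exactly by
  order statistics of each subject's critical shift (the closed-form root of
  the empirical classifier count), so labels always satisfy the IADPSG rule —
  never relabeled.
* **Effect channels** — each DNL-panel species has a latent standardized
  score z = β·(g₀ − mean) + e with Var(z) ≈ 1, β from the published
  glucose-association coefficients (e.g. 0.40 for DG(32:0) per mmol/L fasting
  glucose). Abundance = baseline · exp(0.30·z). Outcomes receive additive
  contributions from fasting glucose and from the same latent scores
  (defaults from the published unadjusted outcome coefficients), so
  dependence between lipids and outcomes flows only through the stated
  channels.
* **Composition** — DNL-panel baselines (10^3.8–10^4.3 counts) sit well below
  the bulk PC/TG background (10^4.5–10^5.5), as minor species do in real
  plasma; consequently the per-mille denominator is essentially
  glucose-independent and the generating β is recoverable after
  normalization. Doubling all baselines leaves the per-mille matrix exactly
  unchanged (closure, tested).
* **Instrument layer** — centroids at the rendered adduct's theoretical m/z
  with N(0, 3 ppm) multiplicative mass error (safely inside the 9 ppm
  window; a warning fires at ≥ 3 ppm), log-normal intensity noise (σ = 0.10),
  120 uniform-m/z decoy peaks with exponential intensities (most fall below
  3× the emitted noise level, exercising the S/N filter), and pooled-truth QC
  spectra at 0.25/0.5/1.0×. Optional saturating species render flat QC
  responses (exercising the linearity filter) and dropout species exercise
  the presence filter.

All randomness flows from one master seed through named child streams
(cohort, lipid, background, outcome, missingness, spectra, baselines), so
outputs are bit-reproducible and a change in one stage's parameters does not
perturb another stage's draws.

**What the generator does not emulate:** chromatographic or batch drift,
correlated lipid-lipid biology beyond the glucose channel, isotope envelopes,
in-source fragment peaks (the DG/TG relation is a tag, not a simulated
fragment), non-random missingness, and real compositional correlation
structure. Passing tests therefore demonstrate that the *pipeline* recovers
what the generator encodes under realistic noise — not that the biological
effect sizes themselves are reproduced from real data, which are available
only on request from the originating consortium.

## Problem sizes in the test suite

Stochastic suites are sized to keep the default run fast while leaving
sampling error well below the margins being asserted: parameter recovery runs
the full spectra→regression chain at n = 2000 × 100 replicates with the
compact one-adduct-per-species simulation mass list (~40 variables); type-I
control uses 100 null cohorts of n = 250 × 20 species (2000 tests); the
attenuation property uses 100 replicates of n = 600 on the latent-abundance
scale. The attenuation scenario sets a glucose→percentile effect of 20
points/mmol/L with outcome noise SD 4 so the mediated signal dominates
per-replicate sampling noise — with the default outcome noise (SD 27,
realistic for percentile outcomes) the mediated component (~0.5 points per SD
lipid) is statistically invisible in any single replicate and the qualitative
comparison would be uninformative.

## Known limitations

* Annotation is purely m/z-based: isobaric species within 9 ppm are
  indistinguishable, and each mass-list entry reports whatever peak is
  nearest — there is no isotope-pattern or fragmentation evidence.
* The per-mille scale is compositional; coefficients are interpretable as
  shares of total lipid signal, not concentrations.
* The insulin-resistance index is generated directly (insulin·glucose-based
  index); the external homeostatic-model calculator is out of scope.
* Birthweight percentiles are consumed as given (customized-percentile
  computation is out of scope) and simulated as clipped Gaussians, which only
  approximates a true percentile distribution.
* The sPLS-DA component count and sparsity defaults (2 components, 10 % keep)
  are reasonable conventions, not calibrated values; loading ranks beyond the
  top handful should not be over-interpreted.
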