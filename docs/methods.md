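# Methods

## The glycoform-resolved PK model

A therapeutic antibody preparation is a mixture of glycoforms g with
relative abundances f_g. Two assays observe the mixture in serum:

* ELISA measures the absolute total concentration C_total(t) (µg/mL) but is
  blind to glycosylation;
* LC-MS glycopeptide analysis measures the compositional profile f_g(t)
  (fractions summing to 1) but carries no absolute scale.

Their product C_g(t) = f_g(t)·C_total(t), formed per animal and time point,
is an absolute per-glycoform concentration and is the quantity this package
analyzes. The identity Σ_g C_g = C_total holds exactly by construction and
is asserted throughout.

### Signal correction and traits

Extracted LC-MS intensities come with a background estimate per analyte. In
late, dilute samples co-isolated interferences inflate low-abundance
glycoforms, so a fixed fraction (default 0.3) of the reported background is
subtracted from each signal (clamped at zero) before total-area
normalization. Derived traits are abundance-weighted structural sums over
all quantified glycoforms: galactosylation and sialylation are per-antenna
occupancies (Σ f_g·n_gal(g)/2, Σ f_g·n_sia(g)/2; two antenna positions),
fucosylation, oligomannose and monoantennary are indicator sums. Traits are
linear in the profile, so the trait of a mixture is the mixture of traits.
Whether oligomannose species should be excluded from the galactosylation
denominator is a convention choice; the inclusive convention is used.

### Non-compartmental analysis

Each per-glycoform series is summarized model-free:

* Cmax/Tmax from the observed points.
* λz by log-linear least squares over candidate terminal windows — the last
  k points for k from 3 up to all points from Cmax on (after subcutaneous
  dosing, Tmax itself is excluded; after an IV bolus the curve is terminal
  from the first sample at 0.08 h). The window with the highest adjusted R²
  wins; ties within 1e-4 go to the longer window. Non-positive
  concentrations are excluded before fitting; fewer than 3 usable points,
  or no window with a negative slope, mark λz "not estimable" (the series
  keeps its AUC_last but reports no AUC∞ or clearance).
* AUC_last by the linear trapezoid (default). The linear rule is chosen
  over lin-up/log-down because it makes glycoform AUCs exactly additive to
  the total-concentration AUC — a structural identity of the splitting —
  at the cost of a small upward bias on convex decays; lin-up/log-down is
  available by configuration. There is no back-extrapolation before the
  first sample.
* AUC∞ = AUC_last + C_last/λz; an extrapolated share above 20% emits a
  quality warning (not an error).
* Clearance CL_g = dose_g/(AUC∞/24) in mL/day/kg (dose in µg/kg, AUC in
  µg·h/mL; hours are the internal time unit everywhere, with the /24
  conversion confined to this formula). After subcutaneous dosing the
  quantity is the apparent clearance CL/F. The per-glycoform dose is
  dose_g = nominal dose × f_g(standard), where the standard profile is the
  glycosylation profile measured in serum spiked with 10 mg/L of the same
  drug substance — measuring the dose fractions with the same assay (and
  the same biases) as the serum samples.
* The "Total" row is the NCA of the unsplit concentrations with the full
  nominal dose, restricted to the same retained time grid as the splits so
  that AUC additivity holds exactly; an unrestricted total NCA can be had
  from `nca_series` directly.

Points are retained only when inside the analysis window (default 240 h,
limiting anti-drug-antibody interference), above the ELISA quantitation
limit (7 ng/mL), and carrying a usable glycosylation profile.

### Statistics

Because absolute clearances vary strongly between animals while glycoforms
within an animal share that variability, clearances are normalized to a
reference glycoform (default G0F) within each animal, and glycoform-vs-
reference contrasts use paired t tests across animals. Serum-profile
comparisons between groups use two-sided Welch tests per glycoform. Each
comparison family — all contrasts of one experimental group, or all
glycoforms of one profile comparison — is adjusted by the Benjamini-
Hochberg step-up procedure at a 5% FDR. Degenerate tests (zero-variance
differences) report a flagged NaN p value, never 0, and are excluded from
the family size. Summary intervals are t-based (df = n−1). Star annotations
follow the p < 0.01 / 0.001 / 0.0001 tiers and are shown only for tests
that survive FDR adjustment.

The profile comparison additionally screens for analytical batch effects:
each glycoform is also compared between the groups' spiked standards, and a
serum difference is flagged "PK-specific" only when the standard comparison
is not significant; significance in both demotes the flag to
"batch-effect".

## The synthetic study generator

The generator exists to make every pipeline stage testable against known
truth. It simulates one-compartment kinetics per glycoform — IV bolus
C_g(t) = (D_g/V)·e^(−k_g t), or first-order subcutaneous absorption
C_g(t) = F_g·D_g·ka/(V(ka−k_g))·(e^(−k_g t) − e^(−ka t)) — with
k_g = CL_ref·m_g/V. A one-compartment model is used deliberately: the NCA
targets (AUC, CL) are model-free, and the closed forms (C0 = D/V,
AUC∞ = F·D/CL) provide exact oracles for recovery tests.

Observation layers: the ELISA total carries mean-one log-normal error
(concentrations are positive and assay error proportional); LC-MS
intensities are s·C_g(1+ε_g) plus a planted interference — a fixed fraction
(0.3) of a gamma-distributed background reported alongside each signal —
which the pipeline's background correction removes in expectation.
Profiles are only emitted where the observed total reaches the 1 µg/mL
profiling floor, and totals below the ELISA limit are flagged BLOQ, so the
generator reproduces the loss of late, dilute samples seen in real studies.

### Default parameters and their calibration

| parameter | default | rationale |
| --- | --- | --- |
| V | 50 mL/kg | minipig plasma-scale volume; C0 = 10 µg/mL at 0.5 mg/kg |
| CL_ref | 17.0 mL/day/kg | k = 0.34/day, t½ ≈ 49 h: the glycoform mixture crosses the 1 µg/mL profiling floor at the last IV sample (168 h), so late samples censor and the terminal slope is identifiable within the sampling window |
| multipliers m_g | Man5 1.20, monoantennary 1.08, G1F 0.92, G2F and sialylated 0.85 | the structure-to-clearance pattern the analysis is designed to resolve |
| ka | 6/day | subcutaneous Tmax between 7 and 24 h |
| f_base | 0.5 | subcutaneous bioavailability of a mAb; CL/F ≈ 2×CL |
| β (absorption_gal_bias) | 0.466 | calibrated numerically so the serum galactosylation trait at 24 h is 3.5 percentage points higher after SC than after IV (noiseless model; 0.180 → 0.215) |
| elisa_cv, intensity_cv | 0.10 | proportional assay noise of ELISA and of per-glycoform LC-MS intensities |
| background level | 200 (a.u.), interference fraction 0.3 | low-signal interference scale; matched to the correction the pipeline applies |
| schedules | IV 0.08–168 h, SC 2–240 h; 5 animals/group | the single-dose minipig design |

The clearance calibration deserves emphasis. Published per-glycoform
clearance values of a few mL/day/kg coexist, in the real studies, with
serum concentrations that fall from ~10 µg/mL to below the profiling floor
within a week — behavior produced by target-mediated (nonlinear) disposition,
which is out of scope here. A linear one-compartment model cannot produce
both at once: a clearance of 0.9 mL/day/kg at V = 50 mL/kg implies a
38.5-day half-life, under which the concentration declines only ~12% over
the whole sampling window, no sample is ever censored, and the terminal
slope is statistically unidentifiable at realistic assay noise (the
log-linear fit's standard error is ~90% of the slope itself, and clearance
ratios become arbitrarily unstable because ~88% of AUC∞ is extrapolated).
The generator therefore reproduces the observable time course (initial
concentration, decline, censoring pattern, ~10% between-animal spread of
recovered clearances) rather than the printed clearance magnitude; the
quantities the analysis actually targets — within-animal clearance ratios
and their significance structure — are unaffected by the absolute scale.

The subcutaneous galactosylation shift is implemented as galactose-
dependent bioavailability, F_g = min(1, f_base·(1+β·n_gal(g)/2)). The
observable (a galactosylation-enriched serum profile around Cmax after SC)
cannot distinguish preferential transport of galactosylated glycoforms
from immediate pre-systemic clearance of agalactosylated ones;
bioavailability bias is the simpler mechanism and reproduces the profile
shift.

### What the generator does not emulate

No target-mediated disposition (real studies of target-binding mAbs show
nonlinear kinetics), no anti-drug-antibody time course (the analysis
window exists to avoid it), no between-animal kinetic variability (all
animals share the true parameters; observed spread comes from assay noise,
so paired-test power on synthetic data speaks to assay noise only), no
glycan-pairing effects (glycopeptide-level profiles lose pairing
information; the simulation treats glycoforms independently), and no
multi-dose designs. Passing recovery tests therefore demonstrate that the
pipeline's estimators are correct and calibrated under the stated noise
model — not that real nonlinear, immunogenic kinetics are captured.

## Numerical choices and degenerate inputs

* Profiles whose raw sums lie within 5% of 1 (or of 100 for percent-scale
  tables) are renormalized; anything further off is rejected as a data
  error. Renormalization is skipped when the sum is already within 1e-9 of
  1, making it idempotent and write/read round-trips bit-exact.
* λz window ties are resolved toward more points (tolerance 1e-4 in
  adjusted R²); a flat series (zero variance of log-concentration) carries
  no slope information and is not estimable.
* BH adjustment is computed on the family of non-degenerate p values;
  rank-specific thresholds (i/m)·FDR are reported alongside reject flags.
* Unknown glycoforms anywhere (profiles, standards, multipliers) raise
  immediately with the offending name; registry closure is never silent.
* The provisional H6N4F1S2 entry is treated as a diantennary,
  digalactosylated, disialylated, fucosylated species inferred from its
  monosaccharide composition, and is marked provisional in the registry.

## Problem sizes used in validation

The validation suite simulates complete studies end to end: 50 replicate
studies for multiplier recovery, 200 for null error control and 200 for
detection power, 100 IV/SC study pairs for the serum-profile shift, and
1000 random instances per statistical oracle. These sizes put the
Monte-Carlo error of each estimate well inside the margins being asserted
while keeping a full validation run in the tens of seconds on one core.

## Known limitations

* Clearance after subcutaneous dosing is identified only as CL/F;
  bioavailability is never resolved separately, so IV/SC clearance
  comparisons confound elimination and absorption.
* With sparse terminal sampling the extrapolated AUC share can be large;
  the 20% warning threshold is a convention, and clearances driven by
  heavy extrapolation inherit λz's noise.
* The serum-profile batch screen is a significance filter, not an effect
  estimator: a true PK difference that also shows a batch effect in the
  standards is conservatively demoted.
* Compositional profiles couple all glycoforms (fractions sum to 1); a
  strong change in one glycoform necessarily moves the others, which the
  per-glycoform Welch tests do not model jointly.
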