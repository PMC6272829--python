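# Methods

This note documents the models, conventions and numerical choices behind
`pmqc`, and what its synthetic-data tests do and do not demonstrate about
real instrument data.

## Mass arithmetic and formula enumeration

Monoisotopic atomic masses (C 12 exactly, H 1.0078250319, O 15.9949146221,
N 14.0030740052, S 31.97207069, Cl 34.96885271) live in one table in
`pmqc.chem`. Negative-mode ion m/z follows the standard convention:
deprotonation subtracts the proton mass (1.007276 Da) and the electron mass
is carried explicitly only in the attachment adducts — [M+Cl]⁻ adds
34.968853 + 0.000549 and [M+HCOO]⁻ adds 44.998203 (CHO₂ plus one electron).
The dimer [2M−H]⁻ is 2M − 1.007276.

Formula enumeration searches integer compositions inside element bounds
(default CHO: C 0–60, H 0–100, O 0–30; N, S, Cl can be opened via the
`bounds` argument) and retains candidates whose theoretical mass lies within
the ppm tolerance of the observation and whose ring-and-double-bond count
(C − (H+Cl)/2 + N/2 + 1) is non-negative. The published element-ratio
heuristic (0.2 ≤ H/C ≤ 3.1, O/C ≤ 3) is applied as a *demotion*, not a
filter: failing candidates sort after passing ones but stay in the list,
because glycosylated natural products sit close to the O/C boundary.
Ordering is deterministic: heuristic pass, then |ppm|, then fewer
heteroatoms, then the formula string.

The default search tolerance is ±5 ppm rather than the sub-2-ppm accuracy an
Orbitrap can deliver, because externally calibrated survey scans routinely
drift 3–4 ppm — exactly the offset the shipped 25-compound library shows
against theory. 2 ppm remains a caller option. The isotope check is the
first-order M+1/M ratio (Σ countₑ × minor/major abundance of e), a linearized
plausibility screen, not an isotopologue envelope.

## Spectral trees and tolerances

MS^n data are modelled as a tree: each stage carries its precursor, its
peaks (relative intensity renormalized to base peak = 100 on read; absent
intensities default to 1, so bare peak lists come out flat at 100), and the
child stage keyed by the selected fragment. Child precursors must appear in
the parent peak list.

Printed MS^n tables mix 4-decimal Orbitrap MS² values with unit-resolution
ion-trap MS³ values, so fragment comparisons are two-tier: ±0.01 Da when
both values carry decimals, ±0.5 Da when either is integer-printed. This is
what lets high-resolution data separate a hexosyl (162.0528) from a caffeoyl
(162.0317) loss while nominal data reports both as consistent. For rule
scoring, a delta matching several loss names keeps only the nearest-mass
name; the full ambiguous list is available from `neutral_losses`.

Adduct pairing tests every co-eluting ion pair against HCOOH attachment
(+46.0055), HCl attachment (+35.9767) and dimerization (m₂ = 2m₁ + 1.007276)
at ±0.01 Da; unpaired ions default to [M−H]⁻.

MGF is the MS²-only interchange format; a JSON tree dialect (documented in
`spectra.py`) is the canonical MS^n fixture format and round-trips
losslessly. mzML reading is provided for MS² scans but is not exercised by
the shipped fixtures.

## Diagnostic-ion classification

A family rule lists diagnostic m/z values, supporting neutral-loss names,
and a required score. Evidence is counted anywhere in the MS^n tree,
precursor ions included — a precursor such as 289.0708 (catechin [M−H]⁻) or
405.1177 (THSG) is itself diagnostic. The point system:

| evidence                                              | points |
|-------------------------------------------------------|--------|
| exact-tier diagnostic match (both values high-res)     | 2      |
| nominal-tier match that is a base peak                 | 2      |
| nominal-tier match with relative intensity ≥ 25        | 1      |
| matched supporting neutral-loss name                   | 1      |

A rule fires when at least one diagnostic ion matched and the total reaches
the threshold (default 2); the naphthalene rule additionally requires a loss
(CH₃• or hexosyl), since its 245/259 diagnostics are common aglycone masses.
The intensity gate is what keeps spectra with only minor coincidental
405/243 peaks (e.g. ~20% relative intensity) out of the stilbene family
while a genuine 243 base peak suffices. Family ties break on evidence score,
then exact-mass hits, then a configured priority
(stilbene > anthraquinone > tannin > naphthalene > sugar — ordered by the
specificity of the exact-mass diagnostics). All of this is configuration
(`data/rules.yaml`), not code; rules derived from the shipped library rather
than from published fragmentation work are marked fixture-derived there.

Library identification requires three concordant observations: precursor
within the ppm tolerance of the entry's theoretical adduct m/z, retention
time within ±0.2 min (standards are matched by retention time; the window is
a package default, callers can widen it for drifting columns), and at least
one shared fragment peak. Matching a reference-standard entry yields
"identified", any other library entry "tentative"; rule evidence alone gives
"class_only". Several passing entries are all reported and the result is
flagged ambiguous. Positional isomers (two galloyl-glucoside peaks with
identical fragmentation) are separated only by retention time.

The profile comparison counts a compound as "phenolic" when its family is
anything but sugar: the two primary metabolites (sucrose, glucose) are
excluded from the 23-compound phenolic profile, and the three
processed-only features are counted from their origin flags.

## SRM quantification and validation

Calibration is unweighted ordinary least squares of peak area on
concentration (µg/mL) over a 7-level two-fold dilution series (1/2 … 1/128
of the working stocks: GA 8, EM 2.75, THSG 210, EMG 228 µg/mL); r² is the
squared Pearson correlation and the working range is [min, max] level. No
1/x weighting is applied — the shipped reference lines are consistent with
simple regression.

Peak integration takes the baseline as the median of out-of-window points,
the area as the trapezoidal integral of the baseline-subtracted trace, and
S/N as apex height over the SD of out-of-window residuals. The apex is
*located* on a moving-average-smoothed copy of the window (width ≈ one tenth
of the window, ≥3 points) and its height *read* from the raw trace: a plain
window maximum is biased upward by noise extremes (≈ +40% at S/N 3), while
this locate-then-read estimator is unbiased to within a few percent in
simulation and exact on noiseless data. A flat baseline yields infinite S/N
with an explicit zero-noise flag.

LOD and LOQ are the concentrations where S/N reaches 3 and 10, linearly
interpolated between bracketing dilution levels (flagged when interpolated
or when no level reaches the threshold). S/N must be nondecreasing in
concentration; a violating series is rejected rather than silently sorted.

Content in mg/g dry weight is
(area − intercept)/slope × dilution factor × 25 mL / 0.2 g / 1000, with
flags for above-range injections (re-measure after dilution), censoring
below the LOQ, and negative back-calculations (clipped to zero). The
missing→zero rule applies only to the group-comparison intensity matrix,
never to quantitative reports. Recovery is
(detected − original)/spiked × 100 and RSD is sample SD (n−1) over mean
× 100.

## Group comparison

The intensity matrix is compounds × (group, batch, replicate) EIC peak
areas with zeros for undetected or unintegrable peaks; each compound is
normalized to its maximum across all samples, putting every compound on a
common relative scale. The model is a two-way fixed-effects ANOVA
(group × compound with interaction). Per-compound group contrasts use the
pooled residual mean square of that model (the desktop "two-way ANOVA +
Bonferroni post-tests" idiom), multiplied by m = 12 compounds, with
significance tiers at adjusted p < 0.05/0.01/0.001. Technical replicates
are averaged per batch by default so batches carry the degrees of freedom
(n = 10 per group in the default design); the all-replicates layout is
available but treats pseudo-replicates as independent. No log transform is
applied by default; one is available via `log_transform=True`.

## Simulators: what they emulate, and what they don't

Mass error is Gaussian in ppm (multiplicative), σ = 3 ppm by default so the
synthetic data reproduce the 3–4 ppm deviations seen in the shipped library;
σ = 0 returns exact theoretical masses. Chromatograms are a single Gaussian
peak plus white noise on a uniform grid over the 10-minute run (120
points/min). Group intensities are log-normal with CV 20% around per-compound
base means log-spaced over 10⁴–10⁶ counts, with the processed group's mean
multiplied by per-compound folds (default: 3-fold on the eight
processing-affected markers); optional zero-inflation exercises the
missing→zero path. Each generator draws from its own named stream derived
from (seed, stream name), so generators never perturb one another and every
run is bit-reproducible.

Not emulated: retention-time drift and peak-shape asymmetry, isotopologue
envelopes, correlated (pink) detector noise, matrix effects and ion
suppression, co-eluting interferences, and batch effects. Tests passing on
these simulations therefore demonstrate the *arithmetic and inferential*
correctness of the pipeline under its stated error model — not robustness to
instrument pathology. In particular, the simulated identity-recovery rate
(~92% at σ = 3 ppm against a hard ±5 ppm gate; the normal-tail bound
2Φ(5/3) − 1 ≈ 0.904 per ion) reflects the error model, and the type-I
behaviour of the ANOVA is checked against its nominal level within
Monte-Carlo error (mean false flags per run ≤ α + 2 SE over the null seeds).

## Problem sizes

The test suite and the acceptance script keep simulations at desk scale as
a design choice: 20 seeds for planted-effect comparisons, 500 seeds for the
null calibration of the ANOVA, 100 seeds × 4 analytes for noisy calibration
fits, 10–20 seeds for peak-list recovery, 1000 random spectra for the
negative control. These sizes put Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

- The classifier is a rule base, not a learned model: a family absent from
  the rules is reported unknown, and rules transcribed from the shipped
  library will not generalize to unrelated chemotypes without editing
  `rules.yaml`.
- Positional isomers and anomeric configurations are outside MS-only
  discrimination; the confidence ladder tops out at reference-standard
  identity.
- mzML support maps MS² scans only and does not reconstruct MS^n lineage.
- The ANOVA assumes homoscedastic cells after max-normalization; strongly
  heteroscedastic data should use the log transform option.
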