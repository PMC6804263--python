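# Methods

This note records the models, conventions and numerical choices behind
`chansuqc`, and what the synthetic studies do and do not demonstrate.

## Mass arithmetic

Element monoisotopic masses are hard-coded CODATA/AME values to ≥6
decimals; the electron mass (5.4858e-4 Da) is subtracted once per unit
charge in every cation m/z, so `mz_of("C24H34O4")` = 387.2530 for
protonated bufalin. Theoretical values are compared with measured ones
only through ppm windows, never equality: precursor matching uses the
instrument's ±5 ppm calibration guarantee, fragment matching uses 10 ppm
with a 5 mDa absolute floor. The floor matters for small ions — the
arginine-series ion near m/z 70 is routinely reported ~2 mDa (≈30 ppm)
from the C4H8N⁺ theory, which a pure ppm rule would reject. The fragment
tolerance is a package convention (only the precursor rule is an
instrument specification) and both are configurable.

Conjugate arithmetic is condensation chemistry: conjugate = parent +
moiety − H2O, with the argininyl diacid homolog n (n = 2…9, succinyl …
undecanedioyl) built as arginine + HOOC-(CH2)n-COOH − H2O. The test suite
asserts this identity exactly (to 1e-9 Da) for every bufogenin × moiety
pair, and pyteomics' mass calculator serves as an independent oracle for
all formula masses.

## Compound knowledge base

The packaged database (41 records) covers the four chemotypes with the
named constituents of the fingerprint peak set and the quantitation
panel: 9 amino acids (arginine and its eight diacid conjugates), 4
serotonin-family alkaloids, 26 bufogenins and 2 bufotoxins. Records carry
positional substituent tags (`3_OH`, `16_OAc`, `14_15_epoxy`, `19_CHO`,
`19_CH2OH`, …) from which fragmentation is predicted; bufotoxins link to
their parent aglycone. For three minor constituents whose exact
substitution is not settled in the literature
(hellebrigenol-9,11-ene, resibufaginol, cinobufaginol) the formulas are
derived from their parents by standard mass arithmetic and should be
treated as tentative. Retention times form a synthetic monotone ladder
(2.5 min spacing over 5–85 min) in fingerprint-peak order; true retention
times are instrument-specific and are a fixture choice here.

## Annotation and classification

`predict_fragments` applies the class grammar described in the README.
The dehydration ladder counts every steroid hydroxyl tag (including
14-OH); the 14,15-epoxide contributes no water loss. Substituent losses
combine with each dehydration stage; the α-pyrone elimination requires ≥2
prior dehydrations. Scoring weights default to 0.3 (precursor), 0.5
(fragment coverage), 0.2 (diagnostics); when a class defines no
diagnostic ion the diagnostic weight folds into the fragment term. Ties
are broken by retention-time consistency with the knowledge base, then
record id, making output order deterministic. Intensities are carried for
reporting but never scored — the workflow reasons on accurate m/z only.

The chemotype classifier is database-free and follows a fixed decision
order: conjugate neutral loss (bufotoxin) → indole core ion (alkaloid) →
arginine series below the steroid mass range (amino acid) → dehydration
ladder on a >350 Da precursor, with the pyrone elimination as supporting
evidence (bufogenin) → unknown. A single-hydroxyl bufogenin
(resibufogenin) shows only one water loss and no pyrone stage, so the
bufogenin rule requires one dehydration, not two.

The polarity model for isomer ordering is a heuristic: only 5-OH > 16-OH
is established for these compounds; the default 5 > 11 > 12 > 16 with
unit gaps is configurable, and equal polarity scores are flagged
unresolved rather than silently ordered. Note the heuristic does not
reproduce the observed elution order of every isomer group (e.g.
gamabufotalin elutes before telocinobufagin although the model scores
telocinobufagin as more polar); it is applied only where the workflow
needs it — co-eluting isomer pairs with distinct tagged substituents.

## Fingerprints

Peak bounds are taken at the midpoint of each inter-apex valley and the
baseline is anchored on the median of the central few percent of each
gap. Both choices are deliberate: estimating bound or baseline from the
noisy minimum couples the integration window to the noise and biases
areas upward by O(noise × span); with noise-independent bounds and
anchors the integrator is unbiased to within ~3 ppm of area (verified on
12,000+ simulated peaks) and recovers isolated Gaussian areas within
0.001% at zero noise. Detection thresholds default to 10× a robust noise
estimate (MAD of the first-differenced signal); alignment uses greedy RT
agglomeration with a 0.5 min tolerance; all are configurable.

The similarity value (SV) is the cosine of two samples' relative-peak-area
vectors over the characteristic peak set (Pearson correlation available).
The exact formula of the commercial fingerprint-similarity software used
in this field is unpublished; cosine on peak vectors is adopted as the
convention and SVs should be compared within this package only.
Characteristic peaks are the shared peaks greedily accumulated (largest
mean area first) to ≥90% of total mean area.

## Quantitation

Calibration is ordinary least squares of area on concentration; R² is the
squared Pearson correlation. LOD/LOQ interpolate the dilution series at
S/N 3 and 10 with S/N = peak height / baseline-noise SD. Contents convert
as c (µg/mL) × 20 mL / 60 mg = mg/g. Back-calculated concentrations
outside the validated linear range are flagged with a warning but kept
(zero-floored when non-positive). All RSDs use the sample SD (n−1); the
packaged 20-batch table stores means and SDs as published, with the
replicate count behind the SDs defaulting to 3.

A note on rounding: the packaged table's maximum per-batch total computes
to 169.23 mg/g from the rounded cells while the published value is
169.22; the difference is rounding of unrounded source data and the tests
assert the total at ±0.02.

## Chemometrics

Kruskal–Wallis uses the tie-corrected H with the χ² approximation
(delegated to scipy); an exact mode enumerates every distinct assignment
of observations to the group layout for N ≤ 12. At that size the χ² tail
approximation agrees with exact enumeration to <0.01 when groups are
clearly separated (the regime of the origin test), but can deviate by
~0.03 for moderately overlapping groups — use the exact mode there. On
the packaged batch means, six of the seven markers test below p = 0.01;
bufotalin is marginal (p ≈ 0.024) on these rounded per-batch means, which
carry less information than replicate-level measurements.

OPLS-DA follows the orthogonal-signal-correction formulation for a
one-hot class response: components orthogonal to the whole predictive
weight subspace span(XᵀY) are stripped from the autoscaled X, then a
PLS2 regression (one predictive component per class contrast) fits the
filtered matrix. R²Y is the explained fraction of the centered response
on the full fit; Q² = 1 − PRESS/SS by venetian-blind cross-validation
(every k-th sample, default 7 folds) with the filter and fit re-estimated
per fold. Orthogonal filtering never reduces the fit: R²Y is
non-decreasing in the number of orthogonal components on the packaged
data. Scaling (autoscale default), fold count and component counts are
configurable.

Clustering is UPGMA on Euclidean distances (scipy linkage); the heatmap
export is the leaf-ordered matrix with per-feature min–max scaling, plus
a Newick rendering of the dendrogram.

## Synthetic studies

The generator emulates a 20-batch, five-origin study: per-batch contents
are origin mean × mean-one lognormal noise, with origin means and
between-batch CVs derived from the packaged content table; chromatograms
are sums of symmetric Gaussian peaks (σ = 0.2 min) on the retention
ladder, marker areas following the validated response lines at the
60 mg / 20 mL preparation, background peaks at fixed areas with 3% CV,
baseline noise SD 0.05 AU, RT jitter SD 0.02 min; spectra are forward
applications of the fragmentation grammar with uniform ±3 ppm jitter and
5 uniform low-intensity decoys; calibration series use 6 geometric levels
over each validated range in triplicate at 0.5% area CV. One seed fixes
every draw; identical configs are bit-identical.

What passing tests show — and what they do not: the synthetic data share
the *structure* the analysis assumes (linear response, resolved symmetric
peaks, rule-conformant fragmentation, lognormal between-batch variation),
so round-trip recovery demonstrates internal consistency of the pipeline,
not performance on real venom. Real chromatograms have tailing, co-elution
and drifting baselines that the generator deliberately omits; real spectra
contain rearrangement ions outside the rule grammar; and the published
similarity ranges and OPLS-DA R²Y/Q² depend on raw instrument data that
were never deposited, so they are reproduced only as qualitative
properties (within-origin > between-origin similarity; high Q² for
separable classes, collapsing under label permutation; perfect UPGMA
origin partition at the study's noise level).

Problem sizes used throughout (tests and the acceptance script): 20
batches × 31 fingerprint peaks per chromatogram at a 0.01 min grid, 41
annotated spectra, and 50 seeded replicates for the bias check — sizes
chosen to mirror the study's scale while keeping a full run in well under
a minute.

## Known limitations

* Annotation cannot separate stereoisomers or identically-tagged isomers
  (e.g. cinobufagin vs 3-epi-cinobufagin): they tie by construction and
  are reported as a flagged tie.
* The classifier's bufogenin rule accepts any >350 Da precursor with a
  dehydration ladder; unusual non-steroid species in that window would
  need database evidence to be rejected.
* Negative-ion mode, multiply charged species, isotope-pattern scoring
  and warping-based full-curve alignment are out of scope.
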