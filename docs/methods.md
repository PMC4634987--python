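# Methods

## Scope and data model

`oralcna` analyses multi-biopsy cohorts of oral potentially malignant
disorders (OPMDs) and oral squamous cell carcinomas (OSCCs). The data
model has four layers:

1. **Genome** — chromosomes with centromeres and cytobands (0-based
   half-open coordinates throughout; only SEG export is 1-based closed, the
   convention of that format family), plus an ordered probe grid. Real
   UCSC cytoBand files are parsed directly; arms are inferred from band
   name prefixes and the centromere from the p/q boundary.
2. **Arrays** — per-probe log2 ratios for one biopsy, with a dLRs noise
   estimate and QC state.
3. **Events** — piecewise-constant segments, thresholded into gains and
   losses, classified focal or broad.
4. **Units** — one patient×subsite with collapsed histology, ploidy class,
   CNA presence and burden scores, the row unit of all association tests.

## Clonality dilution model

The expected log2 ratio of a clonal CNA with total copy number `q_t`
carried by a cell fraction `alpha` in a background of ploidy `D` is
`log2((alpha*q_t + 2(1-alpha)) / (alpha*D + 2(1-alpha)))`. The function
returns −∞ as an explicit homozygous-deletion sentinel when the numerator
vanishes (`alpha = 1, q_t = 0`); the simulator caps rendered means at −6
log2 units in that case, a conventional deep-deletion floor. At
`alpha = 0.5, D = 2` the model gives −0.415 for a hemizygous deletion and
+0.322 for a single-copy gain; where these are quoted at two decimals the
deletion value is written −0.41, i.e. truncated toward zero, matching the
convention of the printed source values this package reproduces.

## Preprocessing

* **Replicate averaging** — arithmetic mean per probe in log2 scale; a
  probe with no finite measurement is a hard error.
* **dLRs** — IQR of consecutive same-chromosome probe differences divided
  by 1.349·√2, an unbiased robust estimate of the per-probe SD for iid
  Gaussian noise. Arrays with dLRs > 0.35 are discarded (strictly greater;
  0.35 itself passes); a per-sample allowlist reproduces the manual rescue
  of borderline arrays after visual inspection, and rescued arrays carry an
  override flag.
* **Winsorization** — per chromosome, residuals from the median are clamped
  at ±k·1.4826·MAD with k = 2.5 (configurable; the MAD multiple is not
  pinned by the analysis being reproduced, and 2.5 is the common choice).
  Inlier probes are returned bit-identical; only clamped probes change.

## Segmentation

Per chromosome, the piecewise-constant fit minimizing
`SSE + gamma * (number of breakpoints)` is found **exactly** by dynamic
programming over changepoint positions with PELT-style pruning. Pruning is
lossless for this cost (splitting a block never increases its SSE), and
the tests verify equality with exhaustive enumeration over all 2^(n−1)
breakpoint subsets up to n = 20.

The penalty default is γ = 40 applied to the profile divided by its dLRs
estimate (`normalize=True`). The scale on which a penalty of this
magnitude is meant to act is ambiguous — raw log2 residuals or
noise-normalized ones — and both are supported; normalized is the default
because a fixed γ then transfers across arrays of different noise levels.
The divisor is floored at 1e-3 so noiseless synthetic profiles remain
finite. Missing probe values are dropped, not imputed; segment probe
counts refer to retained probes. Segment boundaries in bp are midpoints
between flanking probes.

Degenerate inputs: a chromosome with no finite probes is skipped with a
warning; γ ≤ 0 is a parameter error.

## CNA calling

Thresholds are ±0.3 with **inclusive** comparison (≥ +0.3 is a gain,
≤ −0.3 a loss); the source text gives the cutoff without stating
inclusivity, and the inclusive convention is recorded in run metadata.
Adjacent same-state regions are merged with probe-weighted means.
Non-neutral regions are split at centromeres; an arm piece covering more
than half its arm is **broad**, anything smaller is **focal** and is
annotated with every overlapped cytoband. A region is either broad or
focal, never both — the full GISTIC2.0 arbitrated deconstruction, which
can assign both, is deliberately out of scope, and output headers state
this simplification.

**Recurrence.** For each direction, focal analysis scores cytobands and
broad analysis scores arms: the marker value of a sample at a
band/arm is the amplitude of its strongest matching event beyond the
threshold, floored at zero, and `G = Σ_samples amplitude` weights
frequency and amplitude in the GISTIC spirit without the full model. The
null permutes each sample's marker vector by cyclic shifts — within each
chromosome for bands, across the genome-wide arm list for arms —
preserving within-block spatial autocorrelation (independent shuffling is
a config option). Empirical p-values use the (1+exceedances)/(1+n_perm)
estimator over the full band/arm family, followed by BH; focal rows are
retained at q < 0.25, broad at q < 0.3. Presence vectors are derived from
the per-sample event lists (not from the marker matrix), so they are
consistent with the event tables by construction.

## Statistical units and burden scores

Units collapse biopsies by (patient, subsite): histology by severity
(ND-OPMD < D-OPMD < OSCC, any recorded dysplasia grade collapsing to
D-OPMD), ploidy by the any-aneuploid rule. "DNA index ≠ 1" is
operationalized as |DI − 1| ≥ 0.05 (configurable): flow-cytometric DI is a
continuous measurement and an exact-inequality reading is not
implementable. The subsite-exclusivity flag marks patients whose lesions
are limited to a single subsite, for the limited-to-TNG/BM stratified
analyses.

TFG/TFL count distinct cytobands hit by at least one focal gain/loss in
any biopsy of the unit; TBG/TBL count distinct broad regions, keyed by
(arm, direction) so partial-arm broad events on the same arm count once.
All four are monotone under adding biopsies (any-rules), which the
property suite checks on 1,000 random configurations.

## Association testing

* **Fisher 2×2** — two-sided p as the sum of hypergeometric probabilities
  of tables (fixed margins) no more probable than the observed one; this
  convention reproduces the printed p-values of the source tables to four
  decimals. The odds ratio is ad/bc with Haldane–Anscombe +0.5 on all
  cells when any cell is zero, CI by the Woolf logit method; the
  conditional-MLE exact OR is available as an option since the source does
  not name its method.
* **Breslow–Day** — classic statistic against the Mantel–Haenszel common
  OR, with the linear expected-cell solution when the common OR is exactly
  1 (the quadratic degenerates there) and optional Tarone correction;
  strata with empty margins are dropped with a warning.
* **Mann–Whitney** — exact enumeration when min(n₁,n₂) ≤ 8 without ties,
  otherwise normal approximation with tie and continuity corrections.
  Identical constant groups return p = 1 rather than an undefined value so
  degenerate cohorts flow through the suite.
* **BH q-values** — step-up with an explicit family size m ≥ the number of
  supplied p-values; the figure-legend families of size 4 are plan
  parameters, never inferred from the data.
* **Discrete 2×2 FDR** — for each candidate threshold t among observed
  p-values, the expected null discovery count sums each table's own
  attainable-p distribution `P_j(P_j ≤ t)`; q is the minimum estimated FDR
  over thresholds ≥ p. With filtering on, tables whose minimum attainable
  two-sided p exceeds 0.05 (the cap is configurable; the source does not
  print its value) are removed from the family and reported as filtered.
  Discreteness makes this estimator no larger than BH, to which it
  converges as margins grow; tests verify exact agreement with a
  from-scratch enumeration oracle for table totals ≤ 12.

The default analysis plan mirrors the published layout: CNA×ploidy within
each histology stratum, CNA×histology (ND-OPMD vs D-OPMD/OSCC),
CNA×subsite (TNG vs BM), and Mann–Whitney comparisons of TFG/TBG/TFL/TBL
under the same three groupings as BH families of four. Findings are
flagged at q < 0.1.

## Synthetic cohorts

The generator emulates the cohort structure the analysis was designed for:
patients carry lesions at one or more of seven oral subsites (subsite and
histology-given-subsite mixes follow the published biopsy table
proportions; ~13% of patients get a second subsite; biopsies per subsite
are 1 + Poisson(0.6), matching the ~1.6 biopsies/subsite of the study
scale), aneuploidy probability rises from ND-OPMD (0.2) through D-OPMD
(0.45) to OSCC (0.65) and is elevated (0.45) for tongue ND-OPMDs,
mirroring the reported tongue excess. Aneuploid DI values are uniform in
[1.1, 2.2]; flow cytometry itself is out of scope, so DI is a label, not a
simulated histogram.

Events are planted per biopsy (Poisson counts, mean 2.5 in aneuploid vs
0.5 in diploid biopsies, so burden associates with aneuploidy as
observed); half are focal (1–3 contiguous cytobands) and half broad (whole
arm or a >55% telomere-anchored arm fraction), disjoint within a biopsy
(single dominant clone; α is drawn once per biopsy, default 0.5).
Recurrence is concentrated by a hotspot cytoband and hotspot arm that
attract half of their class's events with a fixed gain direction —
calibrated to the published recurrent-CNA carrier frequencies (the top
recurrent gains were present in roughly half the examined units; the
defaults here produce ~20–25% carriers, conservative relative to that).
Copy numbers default to gains of 3–5 and losses of 0–1.

Rendering adds iid Gaussian noise (default SD 0.15 log2 units) and sparse
outliers (1% of probes, extra SD 1.0). The generator does **not** emulate
dye bias, GC waves, replicate feature-level files, or subclonal mixtures —
so passing recovery tests demonstrate correctness of the inference
machinery under the stated noise model, not robustness to real-array
artefacts.

Problem sizes used by the test and acceptance sweeps: 8 chromosomes × 6
cytobands (10 Mb each), 200 kb probe spacing (2,400 probes), cohorts of 60
biopsies, 20 seeds, 500 permutations — sizes chosen so a sweep is a
desk-scale computation while leaving ~50 probes per cytoband, enough for
stable focal segment means at the default noise.

## Known limitations

* The recurrence stage is a declared simplification of GISTIC2.0: no
  ziggurat deconstruction, no peel-off, no gene-level tables or peak
  confidence regions; mixed array designs are handled only by shared-probe
  intersection.
* Calls carry no germline/somatic annotation, so germline CNVs (a known
  caveat for bands such as 14q32.33) are not distinguished.
* The cohort-level published results (aneuploidy fractions, the specific
  80 recurrent CNAs) depend on the unreleased per-sample arrays and are
  not reproduced; the package reproduces every self-contained printed
  number and validates the machinery on synthetic ground truth instead.
* No survival/progression modelling; the unit table is cross-sectional.
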