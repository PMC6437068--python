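# Methods

`spherolipid` re-implements, as a tested pipeline, the comparative
lipidomics workflow used to characterize spheroid-induced
epithelial–mesenchymal transition (EMT) in breast cancer cells: two
culture conditions ("Adherent" vs "Sphere", n = 5 each) profiled by
LC-MS/MS lipidomics and GC-MS fatty-acid (FAME) analysis, with a
transcript fold-change overlay on the unsaturated fatty-acid biosynthesis
pathway. This note records the models, the defaults, and the choices made
where the design was genuinely open.

## Lipid nomenclature and masses

Shorthand names are parsed over eight classes (LPC, PC, PC O-, PE, PE O-,
TG, SM, Cer) at species-sum (`PC(34:1)`) or molecular-acyl
(`TG(17:0/17:0/17:0)`) resolution, with omega labels (`22:6n3`) retained.
Sphingolipid names written without the `d` prefix are canonicalized to the
di-hydroxy-base form (`Cer(18:1/17:0)` → `Cer(d18:1/17:0)`).

Elemental compositions come from a packaged class-template table
(`data/class_templates.tsv`), not code: each class contributes a core
formula plus per-chain increments (ester chain CnH(2n−2−2d)O, ether alkyl
CnH(2n−2d); sphingolipid classes fold base + N-acyl into one hydrocarbon
term against a residual core). This construction guarantees the CH2 and
H2 arithmetic (one carbon = +CH2, one double bond = −H2) and reproduces
literature formulas (e.g. DPPC C40H80NO8P, triheptadecanoin C54H104O6).
New classes are a table row, not a code change.

Adduct defaults per class reflect the mobile-phase additives of a
reversed-phase ESI method with ammonium acetate/formic acid: formate
adducts for the phosphocholine classes, [M−H]− for PE and Cer, [M+NH4]+
for TG, [M+H]+ available in positive mode. The quantified adduct per
class is not stated in the source protocol; the first table entry is the
default and the table is user-editable.

Saturation buckets follow the figure convention: 0 = SFA, 1 = MUFA,
≥3 = PUFA; di-unsaturated chains get their own DUFA bucket rather than
being silently merged, because the polyunsaturated marker is explicitly
"≥3 C=C bonds".

## Rule-based MS/MS identification

Identification mirrors a library-search-plus-manual-confirmation
protocol, made deterministic. Candidates are proposed by precursor m/z
match (default 10 ppm) against a species library over each class's
default adducts; each candidate is then confirmed against a packaged
fragmentation-rule table (`data/fragmentation_rules.tsv`): required
class-diagnostic evidence (fixed ions such as the demethylated
phosphocholine anion C4H11NO4P−, m/z 168.043, or neutral losses such as
methyl formate from formate adducts, water/formaldehyde from ceramide,
ammonia from TG ammonium adducts) and forbidden fragments (the other
families' diagnostics). A candidate is confirmed iff it meets the
`min_required` count with no forbidden ion present; partially supported
candidates are tentative; ties among confirmed isobars are broken by
score, then absolute precursor error, then name. All candidates are
retained in an audit table. Fragment targets are stored symbolically
(formulas, not numbers) so their m/z values derive from the same atomic
masses as everything else.

Tolerances default to 10 ppm precursor / 0.02 Da fragment (QTOF-class);
the benchmark in the tests uses 5 ppm / 0.01 Da.

## Quantification

Identified intensities become ng-equivalents by class-specific internal
standards (LPC(17:0), PC(17:0/17:0), PE(17:0/17:0), Cer(d18:1/17:0) at
400 ng; TG(17:0/17:0/17:0) at 2,000 ng), then amounts per µg protein.
No ether-class or SM standards are spiked in the protocol, so PC O- and
PE O- share their diacyl counterpart's standard and SM shares the
ceramide standard (nearest sphingolipid); both fallbacks are defaults,
overridable, and logged at WARN. Compositions close to 100% at class or
species grain; the class-composition denominator is total normalized
lipid (the `composition.scope` config records this choice). Zeros
propagate as zeros — no imputation; the statistics layer handles them
via the log pseudocount.

The GC-MS path converts FAME areas via per-fatty-acid relative response
factors against the C23:0 (or C17:0) standard:
amount_i = area_i / (rrf_i · area_IS) · spiked amount, then closure. A
missing response factor defaults to 1.0 with a warning (strict mode
raises). The lipidome itself can be decomposed into an esterified
fatty-acid profile: each molecular species contributes its amount once
per ester/amide chain; ether alkyls and sphingoid bases are not
esterified fatty acids and are excluded, as are species resolved only to
class totals.

## Statistics

Preprocessing for multivariate analysis is quantile normalization (each
sample forced onto the mean quantile vector, ties averaged), log2 with a
pseudocount of half the smallest nonzero value (base and zero-handling
are unstated in the source; both are config), and pareto scaling
((x − mean)/√sd, constant features centered only).

Univariate testing is pooled-variance Student's two-tailed t (Welch
available by flag), with exact Benjamini–Hochberg step-up q-values
implemented here and checked in the tests against brute-force enumeration
and statsmodels. Zero-pooled-variance features get t = 0, p = 1 and a
flag. Significance gates default to p < 0.05 and q < 0.10.

PCA is SVD of the column-centered matrix with a deterministic sign
convention (largest-magnitude loading positive). PLS-DA is PLS1 via
NIPALS on the centered 0/1 class code (w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt,
q = yᵀt/tᵀt, deflate); it matches scikit-learn's PLSRegression in the
tests but is not backed by it. VIP_j = sqrt(p·Σ_a SS_a w_ja² / Σ_a SS_a)
with SS_a = q_a² t_aᵀt_a, so mean(VIP²) ≡ 1; reported VIPs come from the
one-component model ("VIP of the first component"). Q² = 1 − PRESS/TSS
with out-of-fold predictions, stratified leave-one-out by default for
n = 10 (the source does not state the CV scheme; k-fold is available);
the component count is chosen by maximizing Q².

The gene-set enrichment score is the signed extremum of the weighted
Kolmogorov–Smirnov running sum (hits weighted by |metric|^exponent,
default exponent 1; exponent 0 recovers the classic statistic).
Permutation p-values for gene sets are out of scope; only the statistic
is provided, and the ranking metric is the caller's choice.

## Pathway indices and overlay

Product/substrate composition ratios proxy enzyme activities:
16:1/16:0 and 18:1/18:0 (SCD desaturation), 18:0/16:0, 20:0/18:0,
22:0/20:0 (elongation cycle; PTPLB/PECR, ELOVL3 on the longer steps),
20:4n6/20:3n6 (FADS1 Δ5-desaturation) and 22:6n3/22:5n3 — the DHA index,
treated as a single composite step attributed to ELOVL2; the C24
intermediates of that route are not modeled because only the composite
ratio is observable in a FAME profile. ACOX3 (the peroxisomal
β-oxidation arm) has no single substrate/product pair and is left
unmapped by default; it surfaces in the unmatched-genes report. The map
is a TSV and user-extensible.

Indices are compared between groups with the same pooled t-test
(direction gate p < 0.05); zero substrate yields a missing ratio, never
infinity. Transcript log2 fold-changes are matched to steps
case-insensitively, and concordance — the fraction of directional steps
whose sign matches the mean annotated log2FC — gets a permutation p-value
by shuffling the gene-to-step assignment (p = 1 by construction for a
single step).

## The synthetic-data generator

The generator emulates the study design, not any real raw data: it
defines the conditions under which the pipeline is validated.

* **Lipidome**: 123 molecular species over the eight classes (unique
  class × C:DB so masses are unambiguous), log-normal intensities with
  class-level abundance offsets (species spread 0.5, replicate noise 0.25
  log10 units), a global per-sample instrument response (sd 0.2 log10)
  that internal-standard normalization must remove, the five standards
  spiked at their nominal amounts with 0.05 log10 pipetting noise, and
  protein ~100 ± 10 µg.
* **Planted effects** (Sphere vs Adherent, multiplicative on means):
  Cer ×6.0, PC O-/PE O- ×0.15, 16:1-containing ×5.0, ≥3-double-bond
  ×0.18. 74 of the 123 species carry an effect; the magnitudes are sized
  so that at n = 5 and 0.25 log10 noise roughly 60% of species clear the
  p < 0.05 / q < 0.10 gates after closure and preprocessing — the
  qualitative design point of the study being emulated. `null()` switches
  every effect off.
* **MS/MS benchmark**: true spectra carry the class-required fragments
  (±0.004 Da jitter) plus random noise peaks kept away from any
  diagnostic m/z; precursor errors are drawn uniformly within the
  instrument accuracy bound (default ±2 ppm — the calibrated-QTOF
  reading of mass accuracy). Decoys sit exactly on a real precursor but
  carry a *different* family's diagnostics (phosphocholine ↔ PE ↔ Cer
  swaps; TG decoys show the forbidden headgroup ion instead of the
  ammonia loss), so they must be rejected by the rules, not by mass.
  The decoy fraction is relative to the number of true spectra.
* **FAME areas**: a 13-fatty-acid baseline typical of cultured breast
  cancer cells, Sphere shifts that raise both desaturation indices and
  lower the three elongation indices and the DHA index while raising the
  FADS1 index, near-unity response factors, 0.035 log10 area noise and a
  0.15 log10 per-sample scale removed by the C23:0 standard.
* **Transcripts**: log2FC means SCD +1.5, ACOX3 +0.8, FADS1 +0.7,
  PTPLB −1.2, PECR −1.0, ELOVL2 −2.0, ELOVL3 −1.5, with 0.1 measurement
  noise.

What the generator deliberately does **not** emulate: chromatographic
drift and co-elution, isotope envelopes, in-source fragmentation, batch
effects, missing-at-random dropouts, or correlated biological variation
between species. Passing tests therefore demonstrate correctness of the
computations and recoverability of effects under the declared noise
model — not robustness to every artifact of real instrument data.

## Numerical choices and degenerate inputs

Quantile normalization with ties uses average ranks, so exact multiset
equality across samples holds only for tie-free data. The BH step-up is
exact (no null-proportion estimation). NIPALS stops early when the
weight vector collapses (deflated y orthogonal to X). PCA/PLS sign and
tie conventions are deterministic, as is identification tie-breaking.
All-zero samples, zero-intensity standards, non-positive protein, zero
substrate ratios, empty or universe-sized gene sets, and rank-deficient
PCA requests raise named errors or warnings rather than producing
silent infinities.

## Problem sizes in the validation suite

The test suite and the acceptance script run entirely on generated data:
type-I calibration uses 500 null datasets (mean fraction p < 0.05 and the
BH false-discovery proportion), direction recovery uses 200 paper-preset
datasets per check, the identification benchmark one 148-spectrum set,
and the permutation-Q² check 50–100 label shuffles. These sizes give
two-decimal stability of the reported rates while keeping a full run
under a minute.

## Known limitations

Absolute molar quantification (per-species response factors, isotope
correction) is out of scope; amounts are ng-equivalents relative to one
standard per class. The fragmentation rule set is a minimal diagnostic
default, not a vendor-grade library. sn-position, stereochemistry and
oxidized lipids are not represented. GSEA significance (permutation FDR)
is not implemented. The reproduction of the original study's literal
headline numbers requires its supplementary normalized lipid table as an
input; the pipeline accepts such a table, but the repository ships no
third-party data.
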