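# Methods

## Scope and data model

`mthet` starts at per-position allele counts (A/C/G/T + depth over all
16,569 positions of the human mitochondrial reference, rCRS coordinates,
1-based inclusive, circular) for each single cell and for one bulk
"consensus" sample per donor.  Everything upstream — alignment, duplicate
marking, base-quality filtering — is outside the package; the aggregate
effect of residual read errors is represented by a single symmetric per-base
miscall probability.

## Variant calling and heteroplasmic fraction

The heteroplasmic fraction of an alternate base is `HF = alt/(alt+ref)`:
the variant allele depth relative to the reference allele depth.  An
`alt/total-depth` denominator is available (`denominator="total"`), but the
ref+alt form is the default.  Zygosity uses strict inequalities: HF > 0.98
homoplasmic; 0.02 < HF ≤ 0.98 heteroplasmic; otherwise sub-threshold.
Sub-threshold calls are flagged, never dropped — the mass of calls below the
0.02 floor is itself reported (it is dominated by sequencing noise and
genuine ultra-low heteroplasmy and typically makes up the large majority of
all candidate calls).

Emission criteria, with defaults and reasons:

* `report_floor = 0.002` — an order of magnitude below the analysis floor;
  keeps the sub-threshold noise spectrum visible without emitting every
  stray read.
* `min_alt_depth = 4` — roughly `report_floor ×` nominal depth (2000×).
  Protects sites whose true allele differs from the reference: there the
  reference base has near-zero depth and one or two miscalls would otherwise
  surface as high-HF calls.
* `min_informative_fraction = 0.5` — a call is only emitted when ref+alt
  reads carry at least half the site's depth.  The alt/(alt+ref) definition
  presumes the ref/alt pair represents the site; at a germline-variant site
  a *third* base paired with the depleted reference base fails this and
  would otherwise yield HF ≈ 1 artifacts.
* `min_site_depth = 500` — calls at thinner sites are flagged
  low-confidence and excluded from somatic sets (well below the 1500× QC
  floor, so it only matters for QC-exempt analyses).
* Every call carries a binomial p-value of its alt count against
  Binomial(depth, error_rate); it is reported, not used as a hard filter.

Coverage QC passes a cell iff ≥ 99% of the genome is covered at ≥ 1500×
(boundary arithmetic is exact: 16,404/16,569 passes, 16,403 does not).

## Genome annotation

The packaged locus map is the standard rCRS feature table (D-loop
m.16024–576 wrapping the origin, 2 rRNAs, 22 tRNAs, 13 protein-coding
genes with strand and frame).  Position→class assignment for burden counting
is first-wins in genome order; consequence annotation instead evaluates
*every* overlapping gene (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4, MT-ATP6/MT-CO3)
and reports the most severe effect (stop-gain > stop-loss > missense >
synonymous).

Burden normalisation uses the fixed class lengths 1124 (D-loop), 2511
(rRNA), 1486 (tRNA) and 11,382 bp (protein-coding).  The packaged map's
arithmetic totals are 1122, 2513, 1504 and 11,341 bp; the constants are
applied as given (they are the published normalisers for this analysis) and
the residuals are pinned by a dedicated test rather than silently
recomputed.  The ~87 unannotated intergenic positions carry no class and do
not enter burdens.

Low-complexity masks default to 66–71, 300–316, 513–525, 3106–3107,
12,418–12,425 and 16,181–16,194 (1-based inclusive).  The fifth region is a
corrected reading of a source that lists an end coordinate beyond the
genome; the set is user-overridable, except the rCRS placeholder 3106–3107
which is always masked.  Membership tests are O(1) against a precomputed
boolean genome array.

## Somatic definition

Within one donor's cells (post-QC, post-mask, post-homology):

1. heteroplasmic in exactly one cell with HF > 0.02 and < 0.98;
2. absent from the consensus — operationalised as HF < 0.02 there, since
   zero alt reads is unattainable under sequencing error;
3. absent (same floor) from every other cell of the sample.

Cells that failed QC cannot veto a variant.  With a single analysable cell
the privacy criterion is vacuous and a warning is raised.  Alongside the
somatic survivors, each cell retains its pre-floor candidate list
(consensus-absent, private, 0 < HF < 0.98) for the HF histogram.

The homology check asks what fraction of the consensus homoplasmies the
cell shares and requires > 0.99.  "Shares" means the cell carries the
allele as its *major* allele (HF > 0.5), not necessarily above 0.98: under
drift a shared heteroplasmy near the top of the range can average above
0.98 in the consensus while sitting at ~0.93 in one cell, and an ancestry
marker is shared whenever the cell predominantly carries it.  A consensus
with no homoplasmies cannot be assessed (warned, not failed).

## Consequence and pathogenicity

Synonymy is decided per codon under the vertebrate mitochondrial genetic
code (translation table 2: AGA/AGG stop, ATA Met, TGA Trp), with the codon
read 5'→3' on the coding strand — for MT-ND6 the reverse complement of the
genomic triplet.  Genes whose stop codons are completed by polyadenylation
are A-padded and variants in those 1–2 terminal bases carry a caveat flag.
The test suite checks the implementation against an independent brute-force
oracle that rebuilds the whole mutated CDS and compares whole-protein
translations.

MutPred and APOGEE 2 scores are consumed as lookup tables, never computed;
classification thresholds are strict (> 0.50 and > 0.38).  Unscored
variants keep null flags and are excluded from pathogenic-fraction
denominators, with unscored counts always reported alongside.  Non-coding
variants never acquire pathogenicity flags.

## Statistics

Group comparisons are one-way ANOVA plus Dunnett's many-to-one contrasts
(multivariate-t single-step, via `scipy.stats.dunnett`) against a mandatory
explicit reference group (a designated donor for between-sample contrasts,
the D-loop for between-locus contrasts); two-group contrasts
(non-synonymous vs synonymous) use the two-sided Mann-Whitney U test.
Groups with fewer than two observations are excluded with a warning.
P-values are unadjusted by design.  Counts are treated as continuous in the
ANOVA; cells with zero somatic variants contribute zero counts to burden
comparisons but no rows to HF comparisons.  Score-distribution shape
reports **both** kurtosis conventions explicitly (excess, normal = 0; and
Pearson, normal = 3) to preclude silent convention mismatch, plus
Shapiro-Wilk normality (requiring ≥ 8 scores and non-degenerate variance).
The Dunnett implementation is pinned against frozen R `multcomp::glht`
reference values, and all three test procedures are calibrated under null
simulations (empirical type-I error within 3 binomial SE of 0.05 over
1000 replicates).

## Synthetic study generator

The generator emulates the structure of a 13-donor, ~8-cells-per-donor
single-cell mtDNA study with deep amplicon coverage.  Per sample:

* **Germline**: 30 homoplasmic variants shared by all cells and the
  consensus (the scale of a typical European haplotype's divergence from
  the rCRS).
* **Shared heteroplasmies**: 1–7 per sample (uniform), sample-level HF
  uniform on 0.02–0.94; each cell's fraction is the sample fraction evolved
  by Wright-Fisher drift.
* **Private somatic variants**: Poisson(80) per cell.  Initial fractions
  are Exp(mean 0.015) capped at 0.5, with a 1% clonal-expansion component
  uniform on 0.25–0.90; each then drifts for 20 generations at copy number
  N = 800.  These choices reproduce the observed per-cell scale (~80
  candidate variants per cell of which ~25 exceed the 0.02 floor; most
  retained HFs below 0.1, rare variants above 0.5) and are fixed, not
  fitted.  Alt bases are transitions with probability 0.9, matching the
  transition-dominated spectra of mtDNA somatic variation.
* **Drift**: discrete Wright-Fisher binomial resampling per generation
  (absorbing at 0 and 1), chosen over Moran steps for its closed-form
  variance `h₀(1−h₀)(1−(1−1/N)^t)`, which the tests check directly.
* **Counts**: depth ~ NegBin(mean 2000, dispersion 200 — sd ≈ 148, so
  QC-passing coverage profiles are the default and QC failure is exercised
  by dedicated cells with low-coverage windows); a symmetric per-base
  miscall probability of 0.001 mixes fractions as
  `P(obs=b) = f_b(1−4e/3) + e/3`; counts at each position are multinomial
  and always sum to depth.
* **Consensus**: the cell-weighted pool of the sampled cells' true
  fractions — germline at 1.0, shared heteroplasmies at the mean of the
  drifted per-cell fractions, each private somatic variant diluted to
  `h/n_cells`.  This makes the consensus-absence criterion exactly testable:
  a private variant with `h/n_cells` at or above the 0.02 floor is
  genuinely present in the consensus and is *correctly* rejected by the
  pipeline, so recovery metrics exclude such variants from the recall
  denominator (they are identifiable from the ground truth alone).
* Variant positions are drawn uniformly over unmasked positions (optionally
  D-loop-enriched to emulate a control-region hotspot), never colliding
  across cells, so privacy ground truth is exact.
* All randomness flows from one root generator; a fixed seed reproduces
  byte-identical output files.

What the generator does **not** model — and what passing tests therefore do
not establish about real data: NUMT contamination, strand- or
context-dependent error, alignment artifacts, indels/deletions, PCR
amplicon boundary effects, true mutational hotspots beyond the optional
uniform D-loop multiplier, and any relationship between pathogenicity
scores and the underlying sequence (fabricated score tables draw MutPred
from Beta(5, 2) and APOGEE 2 from Beta(1.3, 1.5), chosen once to give the
qualitative right-skew of such predictors, with ~5% of variants left
unscored).

## Problem sizes and determinism

The default verification runs use 13 samples × 8 cells at 2000× (the
emulated study design), 10,000 Wright-Fisher replicates for the variance
check, 1000 random coding substitutions for the consequence oracle and 1000
null replicates per statistical procedure.  Dunnett p-values use the
library's quasi-Monte-Carlo multivariate-t integration and are reproducible
to ~1e-4; all other results are exactly seed-deterministic.

## Known limitations

The pipeline treats each (position, alt) pair independently: multi-allelic
sites yield one call per alt, and no phasing is attempted.  The HF
definition cannot quantify a secondary alternate allele at a site whose
major allele already differs from the reference (such calls are suppressed
by the informative-fraction guard rather than mis-reported).  The homology
proxy is a sharing fraction, not a formal contamination deconvolution.
Burden normalisation inherits the small mismatch between the published
locus-length constants and the annotation's arithmetic totals.
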