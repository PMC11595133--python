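# Methods

This note documents the models, decision rules, numerical choices and
known limitations of cernakit, in the order the pipeline runs them.

## Differential expression

Counts are normalized with median-of-ratios size factors: for each
sample, the factor is the median over features (restricted to features
positive in every sample) of that sample's count divided by the
feature's geometric mean across samples. Size factors are defined only
up to a common scale; all downstream quantities depend on factor ratios
only. If no feature is positive everywhere, normalization fails with an
explicit error rather than silently switching references.

Per feature, the test statistic is a two-sided **pooled-variance Student
t** on log2(normalized count + 1). With three replicates per group the
Welch–Satterthwaite degrees-of-freedom approximation is measurably
conservative (null rejection near 0.03 instead of 0.05), while the
pooled test is exact under normality for equal group sizes and a common
null distribution; on null negative-binomial simulations with 2500
features it rejects at 0.044–0.052 at the nominal 0.05 level (the
acceptance suite re-measures this). Degenerate rows with zero variance
in both groups get p = 1 when the group means agree and p = 0 when two
distinct constant levels are observed.

Fold changes are computed on pseudocounted normalized group means,
log2((mean_A + 1)/(mean_B + 1)), so zero counts stay bounded. A feature
is **up** iff p < 0.05 and log2FC > 1, **down** iff p < 0.05 and
log2FC < −1, both strictly: a feature at log2FC = 1.0 exactly is not
differential, whatever its p-value. Raw p-values drive the DE call;
FDR correction is applied only in enrichment. Orientation (which group
is the log2FC numerator) is a parameter; the default is the
alphabetically first group label.

FPKM quantification (count × 10⁹ / (length × library size)) and the
2^−ΔΔCt relative-expression helper for qPCR validation are provided for
completeness; neither feeds the network stages.

## lncRNA identification

Candidates are transcripts with spliced length > 200 nt (strict) and at
least two exons. Coding potential is decided by **verdict
intersection**: a table with one non-coding flag per transcript from
each of four predictors (the CPC2 / CNCI / PLEK / Pfam quartet in the
standard workflow), retaining only transcripts all four call
non-coding. The predictors themselves are consumed as a TSV, not
executed. For self-contained runs an ORF-length heuristic fills all
four slots identically: a transcript is non-coding iff its longest
forward-frame ATG-to-stop ORF is shorter than 100 codons (an ORF of
exactly 100 codons counts as coding; open-ended runs with no stop codon
do not count). Only forward frames are scanned — transcript sequences
are already stranded. An optional id exclusion list removes annotated
transcripts before the verdict step.

## Binding prediction

### Energy model

Duplex stability uses the nearest-neighbor decomposition: an initiation
penalty (+4.09 kcal/mol) plus a sum of stacked-dinucleotide free
energies over consecutive base pairs. The shipped table covers all
ordered pairs of Watson–Crick and G·U wobble pairs with Turner-style
ΔG°37 values (Xia et al. 1998 for WC/WC; Mathews et al. 1999 for wobble
stacks) and is strand-symmetric by construction. Loops and bulges are
not modeled: an alignment gap simply breaks the stack and forfeits the
stacking energy across it. This keeps every reported energy
hand-checkable against the table.

### miRNA target sites

Scoring follows the miranda family: match +5, G·U wobble +1, mismatch
−3, gap open −9, gap extend −4, with substitution scores at miRNA
positions 2–8 (the seed; position 1 is the 5′ nucleotide) multiplied by
4.0 — the 5′ scaling factor of miranda v3.3a. With these constants a
perfectly complementary 21–23-nt site scores 210–225, comfortably above
the default threshold S ≥ 150. (A 5′ weight of 2 would cap a perfect
22-mer at 145 and make the default threshold unreachable; all constants
remain configurable through `ScanParams`.)

A site is reported iff S ≥ s_min (150), duplex ΔG ≤ dg_max (−30
kcal/mol), and — under the default strict-seed mode — positions 2–8 are
contiguously Watson–Crick paired with no gaps or wobbles. Under strict
seed the scan is **seed-anchored**: exact 7-mer seed complements are
located by string search and a banded Smith–Waterman (affine gaps,
Gotoh) is run in a window around each anchor. This is exact for
strict-seed semantics, since any valid site must contain the literal
seed match; without strict seed a full local alignment with iterative
masking is used instead (slower, intended for small inputs).
Overlapping candidate sites are resolved by score, then lower energy,
then leftmost position. Whole transcripts are scanned, not just 3′
UTRs. Sequences are handled in DNA spelling with T ≡ U.

### lncRNA–mRNA trans duplexes

Trans interactions are maximal exactly complementary stretches between
the two transcripts (Watson–Crick; G·U optionally), found by hashing
min_stretch-mers of the reverse-complemented mRNA, kept when at least
10 bp long with nearest-neighbor energy at or below the cutoff. The
default cutoff of −100 is stored unit-agnostic: read as kcal/mol it
demands roughly 55+ bp of pairing — the literature value it mirrors
comes from tools whose energy scale is not documented, so the cutoff is
a parameter rather than a resolved constant. The synthetic generator
plants 80-nt stretches, long enough to satisfy the literal default.

## Co-expression networks and triplet assembly

Pearson correlations are computed across all samples of both groups
pooled (n = 6 by default) on log2(normalized count + 1). The p-value
comes from t = r·√((n−2)/(1−r²)) on n−2 df; exact collinearity is
snapped to r = ±1 with p = 0 (within 1e−14 of 1). Zero-variance
features raise in the scalar API and yield no edges in the bulk scan.

An edge requires |r| > 0.80 and p < 0.05, both strict, plus the sign
the ceRNA model dictates: negative for miRNA–mRNA and miRNA–lncRNA,
positive for mRNA–lncRNA. The network universe defaults to the
differential features of each class (lncRNAs additionally restricted to
identified lncRNAs); a flag lifts this to all features. miRNA edges are
then filtered to pairs with at least one predicted binding site.

**cis** lncRNA targets: same chromosome, interval distance (0 when
overlapping, else the gap between interval ends — feature boundaries,
not TSS, since the window is defined around the whole locus) at most
100 kb *inclusive*, plus a co-expression edge at |r| > 0.8 in either
sign. A signed display distance marks upstream (−) vs downstream (+)
placement. **trans** targets: a duplex hit plus a co-expression edge.

A triplet (mRNA, miRNA, lncRNA) is emitted iff the miRNA has qualifying
negative, site-backed edges to both the mRNA and the lncRNA, and the
mRNA–lncRNA pair has a positive edge. The **ceRNA score** is the
mRNA–lncRNA correlation r — the natural per-triplet summary of
competition strength — and an optional score floor (`score_min`,
default none) can refine the list further; no more elaborate scoring is
assumed. Output is sorted by score descending with deterministic
id-based tie-breaks.

## Enrichment

Over-representation of a query gene set against a background universe:
for each term, p = P(X ≥ k) with X hypergeometric(N, K, n), where the
term's gene set is first intersected with the background and empty
terms are dropped before correction (so m counts only tested terms).
Benjamini–Hochberg step-up FDR is reported alongside raw p; results are
ranked by p. The enrichment score is −log10(p). The background defaults
to all features of the relevant class in the expression matrix; the
caller may narrow it.

## Synthetic data generator

The generator emulates a two-breed, three-replicate design:

* **Counts**: negative binomial with var = μ + αμ², α = 0.05 by
  default, per-sample depth factors uniform in [0.75, 1.3], feature
  base means log10-uniform in [1.5, 3.5] (≈ 30–3000 counts — desk-scale
  stand-ins for 20M-read libraries). α = 0 is the exact zero-noise
  limit: counts equal rounded means and all other noise sources (depth,
  latent factors) are switched off, enabling exact tests (replicates
  identical, planted correlations exactly ±1).
* **Planted DE**: 20% of each class by default at |log2FC| = 3, applied
  one-sided to group A. Planted DE features draw their base abundance
  from the upper half of the mean range so the pseudocounted fold-change
  estimate is within 0.1 of the planted value in the noiseless limit.
* **Triplets** (30 by default): the miRNA is shifted in one direction,
  its mRNA and lncRNA targets in the other; a shared Gaussian latent
  factor (σ = 0.35 log2 units) on the mRNA and lncRNA means adds
  within-group co-variation. Pooled across samples this yields
  r(miRNA, target) < 0 and r(mRNA, lncRNA) > 0 in expectation — the
  cross-group mean shift dominates r at n = 3+3, mirroring the real
  design. Each planted target carries the exact reverse complement of
  its full miRNA, which passes any reasonable S/ΔG threshold without
  tuning the generator to the scanner; triplet miRNAs are redrawn until
  their perfect-duplex energy is ≤ −35 kcal/mol so an AU-rich
  composition cannot push a planted site above the −30 threshold.
* **Trans pairs** (5) share an exact 80-nt complementary stretch;
  **cis pairs** place lncRNA loci at exact distances straddling the
  100-kb boundary (0, 50 000, 100 000, 100 001, 150 000 bp by default).
  Both kinds of pair are planted as co-directional DE with a shared
  latent factor so the expression filter can pass them.
* All remaining sequence content is uniform-random over {A,C,G,T};
  mature miRNAs are 21–23 nt. Identical config + seed reproduces every
  output byte for byte (per-stage child generators from one seed).

What the generator does **not** emulate: read-level artifacts (GC bias,
positional coverage, mapping ambiguity), isoform structure, genomic
sequence (transcript sequences are generated directly), biological
correlation beyond the planted structures, and batch effects. Passing
recovery tests therefore demonstrates the correctness and calibration of
the inference chain under its own model assumptions, not performance on
real libraries.

## Validation summary (what the acceptance suite measures)

* every core statistic against an independent oracle (direct formulas,
  exhaustive enumeration, brute-force scans, Monte-Carlo);
* DE type-I error on null simulations within 0.05 ± 0.02;
* under the default conditions with five fixed seeds: planted-DE
  sensitivity ≥ 0.9, scanner sensitivity 1.0 on planted sites with ≤ 5%
  of 200 random scans producing any site, triplet precision and recall
  ≥ 0.8;
* exact strict-boundary behavior (log2FC = 1.0, r = 0.80, 200-nt /
  1-exon candidates, 9-bp stretches, 100 000 vs 100 001 bp);
* byte-identical pipeline reruns.

Problem sizes were chosen so the whole suite runs in well under a
minute of compute per criterion on a single core.

## Known limitations

* The DE test is a t-test on transformed counts, not a count GLM; it is
  calibrated for the simulated design but does not shrink dispersions
  and is not expected to reproduce DESeq2/edgeR results numerically.
* The energy model ignores loop, bulge, dangling-end and
  accessibility terms; absolute ΔG values are comparable within the
  package, not with full secondary-structure folders.
* Correlation p-values are raw (an optional BH flag exists); with ~10⁵
  candidate pairs the edge lists are permissive by design, and the
  binding-site requirement is what controls the final network's
  precision.
* With n = 6 samples, the |r| > 0.8 threshold sits near the p < 0.05
  boundary (|r| ≈ 0.811), so both thresholds bind almost identically;
  planted triplet edges with sample r near 0.80 can be lost, which is
  the dominant recall cost in recovery experiments.
* The 2-of-4 or 3-of-4 verdict relaxations seen in some workflows are
  not offered; the intersection is strict.
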