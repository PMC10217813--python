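# Methods

This note documents the models, parameter choices and numerical decisions
behind `seedcerna`, and what the synthetic fixtures do and do not show
about real data.

## Scope and data model

The pipeline starts from assembled transcript models (GTF), transcript and
mature-miRNA sequences (FASTA), a feature × sample count table and a sample
design (variety ∈ {M, H}; timepoints 5/10/20/30 days after flowering;
replicates). Read alignment, transcript assembly and database annotation
are upstream of this package; functional annotation is a join against a
user-supplied gene → term table (`cerna.annotate_targets`).

Coordinates are 0-based half-open internally; GTF I/O converts to 1-based
closed at the boundary. Contrasts are oriented later-over-earlier
timepoint, so a transcript that falls across development has negative
log₂FC.

## lncRNA identification

Basic screen: spliced length ≥ 200 nt, ≥ 2 exons, and max-over-samples
FPKM ≥ 0.1. The expression gate is deliberately the most permissive
reading of an FPKM threshold applied across many libraries (a transcript
expressed in any one condition is kept); a per-sample or per-condition
reading would only shrink the candidate set.

Coding potential uses four in-repo verdicts combined by intersection — a
transcript is non-coding only if every scorer says so:

1. **ORF rule** — longest sense-strand ATG…stop span (stop included,
   length 0 without an in-frame stop) < 300 nt. Requiring a stop codon is
   appropriate for assembled, strand-specific transcripts. This rule also
   stands in for a protein-domain screen: a transcript without a
   substantial ORF cannot encode a domain.
2. **Fickett TESTCODE** < 0.95 — the published position/composition lookup
   tables; the position parameter for each base is max/(min+1) over its
   three codon-position counts, the content parameter its overall
   fraction, each binned and weighted.
3. **Hexamer score** < 0 bits — mean log₂ likelihood ratio of in-frame
   hexamers (step 3 in the frame of the longest ORF; frame 0 when there is
   none), under coding vs non-coding hexamer tables with pseudocount 1
   over all 4⁶ hexamers.
4. **Logistic combiner** P(coding) < 0.5 over (ORF length, Fickett,
   hexamer), fitted by maximum likelihood.

All cutoffs are configurable. Within the pipeline, the coding model is
trained on the annotated protein-coding transcripts of the input GTF and
the non-coding background on dinucleotide-preserving shuffles
(Altschul–Erikson) of the *entire candidate pool*, so the background
matches the candidates' base and dinucleotide composition while destroying
codon structure. This matters: with a background that does not match the
candidate population's composition, neutral sequence scores near 0
bits — exactly on the hexamer decision boundary — and the consensus becomes
unstable.

Positional classes use precedence sense > antisense > intronic > lincRNA:
exonic overlap with a coding exon on the same / opposite strand gives
sense / antisense; a span fully inside one intron of a coding gene (either
strand) with no exonic overlap gives intronic; no overlap with any coding
gene span gives lincRNA. A span that overlaps a gene without exonic
overlap but is not contained in a single intron (possible only for
transcripts straddling a gene boundary) falls back to lincRNA. Summary
percentages are 100·count/total rounded to one decimal; medians use the
standard even-n midpoint.

## Differential expression

Size factors are median-of-ratios over features with all-positive counts,
normalized to unit geometric mean — this makes re-estimation on the
normalized matrix return exactly 1 and leaves all ratios unchanged.

The two-group test is the classic count-based exact test: under the null,
each group's count sum is negative-binomial with mean q̂·Σsⱼ and variance
q̂·Σsⱼ + α·q̂²·Σsⱼ² (q̂ the pooled normalized mean, sⱼ the size factors);
the two-sided p-value is the probability, conditional on the total, of a
split at most as likely as the observed one. Log₂ fold changes use
normalized means with pseudocount 0.5.

Dispersion is method-of-moments: the pooled within-group variance of
normalized counts minus shot noise, over q̂². Three sharing modes are
provided; the default (`pooled`) assigns every feature the median of the
informative gene-wise estimates. At n = 3 per group the gene-wise
estimates are so noisy that using them directly is anti-conservative
(empirical type-I error ≈ 0.10 at nominal 0.05 in our null simulations),
while taking the maximum of gene-wise and pooled is conservative
(≈ 0.033); the shared-median mode is calibrated at both 0.05 and 0.01 and
is therefore the default. `per-feature` and `pooled-max` remain available
for heterogeneous-dispersion data.

Screening gates: "fold change ≥ 2" is interpreted two-sided on the linear
scale, |log₂FC| ≥ 1, with the boundary included; the FDR boundary is
strict (<) for the lncRNA and ceRNA gates and inclusive (≤) for the small
RNA gate, exactly as the respective thresholds are stated. Small RNA
counts run through the same machinery with their own size factors (they
come from separate libraries).

## miRNA target scanning and ceRNA inference

The scanner slides the reverse-complemented mature miRNA along the
transcript. Penalties: mismatch 1.0, G:U wobble 0.5, single-nucleotide
target bulge 1.0; each doubled at miRNA positions 2–13 from the 5′ end
(the seed-proximal region plant small RNAs pair almost perfectly); at most
one bulge per site; sites reported at total penalty ≤ 4.0. A bulge "after
miRNA position j" leaves one target base unpaired between the bases facing
positions j and j+1 and takes position j's weighting. The implementation
is vectorized over start positions (prefix sums over the bulge split
point) and is checked in the tests against an exhaustive alignment
enumeration; the best-scoring variant per start position is reported.

Cis targets are coding genes whose span lies within 100 kb (inclusive,
strand-agnostic, 0 for overlap) of the lncRNA span.

ceRNA pairing: for each (lncRNA, mRNA) sharing k > 5 distinct miRNA ids
("more than 5", read strictly — family members with identical mature
sequences count separately), the upper-tail hypergeometric probability of
the overlap is computed with the miRNA universe M set to all miRNAs
entering the analysis (the expressed set, configurable). BH correction
runs across all tested pairs in one batch; survivors need p < 0.01 and
FDR < 0.01. Negative-regulation screening keeps pairs whose lncRNA and
mRNA calls are significant and same-signed while shared miRNAs are
significant and opposite-signed; shared sets are pruned to opposite-signed
miRNAs and the k > 5 gate re-checked. lncRNA–mRNA candidate pairing is "at
least one common targeting miRNA" before gating.

## The synthetic generator

The generator emulates the two-variety × four-timepoint design on a single
miniature chromosome and is the package's test bed; its defaults are the
study conditions:

- 80 coding genes (3–5 exons of 250–420 bp; first intron enlarged to
  2.5 kb to host intronic lncRNAs; 15 kb intergenic gaps), 18 lncRNAs
  (6 lincRNA / 4 antisense / 4 intronic / 4 sense, every class realized by
  construction), two lincRNAs placed > 100 kb from any gene as cis-window
  negatives, and three planted screen-failure controls (length < 200 nt,
  single exon, silent).
- Coding transcripts carry one GC3-biased ORF (≥ 300 nt incl. stop)
  between AT-rich UTRs; non-coding sequence is AT-rich
  (A/T 0.30, C/G 0.20) with every complete ORF broken below 150 nt — both
  compositional asymmetries mirror real plant transcriptomes and give the
  coding scorers a realistic signal.
- 30 mature miRNAs of 21 nt (the standard plant length): one 6-member
  family sharing a single mature sequence, plus singleton decoys, each
  decoy given one exact site in a non-module mRNA (and one in the sponge)
  so that sub-threshold shared sets exist.
- The planted ceRNA motif — one lincRNA sponge, the 6-member family, 15
  mRNAs with family sites in their 3′ UTRs — drifts in the oil variety:
  sponge and mRNAs down 4-fold from 5 to 30 days, family miRNAs up
  4-fold, satisfying negative regulation.
- Counts are negative-binomial with gene-wise dispersion from a
  Gamma(shape 8) around mean 0.05, baseline means log-uniform on
  [20, 300] (module features 150–300), 3 replicates per condition (the 16
  pooled libraries of the emulated design do not pin a replicate
  structure; 3 gives testable dispersion estimation), and 10% of
  non-module features drifting 4-fold in a random direction per variety.
  Drifting features move geometrically across the four timepoints so the
  first-vs-last contrast realizes the full fold change.

Everything derives from one seed (separate streams per stage), and
identical configurations produce byte-identical fixture files.

What passing tests on this generator shows: that each stage implements its
stated rule exactly, that the statistics are calibrated under the
generator's noise model, and that the full pipeline recovers a planted
module through every gate with no false pairs at desk scale. What it does
not show: robustness to mis-assembled transcript models, fragment-level
FPKM deconvolution, sequencing artifacts, dispersion trends with
expression, or performance at genome scale — real transcriptomes are
larger, noisier and unlabeled.

## Numerical choices and degenerate inputs

- Hypergeometric tails come from scipy's log-gamma based implementation;
  tests pin exact agreement (|Δ| < 10⁻¹²) with integer enumeration for all
  universes M ≤ 25, and k = 0 returns exactly 1.
- The exact NB test enumerates the conditional distribution of the group-A
  sum given the total (log-pmf shifted by its maximum before
  exponentiation); observed-probability comparisons use a 1 + 10⁻¹⁰
  relative guard against ties lost to rounding. Zero totals give p = 1.
- ORF ties (equal length) resolve to the smaller start offset, then lower
  frame index.
- Empty candidate sets propagate: no survivors → no coding screen, empty
  but valid network exports, and a report with empty sections.
- `fold_increase` is (b − a)/a rounded to 2 decimals and requires a > 0.
- Size-factor estimation refuses matrices with no all-positive feature
  rather than silently adding a pseudocount.

## Problem sizes

Default fixtures are 101 transcripts + 30 miRNAs × 24 samples; a full
pipeline run takes ~1 s and the whole test suite (including the 2000-
feature null calibration and the exhaustive scan/hypergeometric oracles)
runs in well under a minute on one CPU.
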