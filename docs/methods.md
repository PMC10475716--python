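# Methods

## The problem

Thymomas carry one of the lowest mutation burdens among solid tumors, and
the tissue available for sequencing is usually a mixture of neoplastic
epithelial cells, non-tumoral thymocytes and stroma. Two consequences
drive every design choice in this package:

1. **No matched normal.** Somatic status must be inferred from a single
   tumor sample. The separating signal is the allele fraction (AF):
   germline heterozygous variants cluster at ~0.5 and homozygous at ~1.0,
   while a clonal heterozygous somatic mutation in a sample of purity
   *p* has expected AF *p*/2 — in thymocyte-rich histotypes often below
   0.1.
2. **Deep targeted coverage.** AF-based separation only works when
   binomial sampling noise is small relative to the gap between *p*/2 and
   0.45; the pipeline is built for panel data with hundreds to thousands
   of reads per locus.

## Filter cascade

A call passes iff **all** of the following hold (reason codes in
parentheses; every violated rule is recorded, the cascade never
short-circuits, so tallies are independent of rule order):

| rule | fails when | default |
|---|---|---|
| population frequency (POP_AF) | annotated max population AF ≥ `max_pop_af` | 1e-4 |
| coverage (LOW_DEPTH) | depth < `min_depth` | 20 reads |
| allele fraction (LOW_AF) | AF < `min_af` | 0.04 |
| germline window (GERMLINE_AF) | AF ≥ `max_af` | 0.45 |
| strand bias score (STRAND_BIAS_PHRED) | Phred-scaled exact-test score > `max_sb_phred` | 60 |
| strand bias ratio (STRAND_BIAS_OR) | odds ratio > `max_sb_or` | 3 |
| mismatch load (MISMATCHES) | mean mismatches per alt read ≥ `max_mean_mismatches` | 3 |
| noise (LOW_SNR) | signal-to-noise < `min_snr` | 4 |
| microsatellite (MSI) | caller MSI flag set and `exclude_msi` | on |

Boundary semantics are deliberate and unit-tested: "at least 20 reads"
and "at least 4%" are inclusive pass conditions; the germline exclusion
at AF ≥ 45% and the mismatch rule at ≥ 3 are inclusive fail conditions;
the strand-bias rules are strict (> 60, > 3) and the noise rule strict
(< 4). At zero depth AF is defined as 0 (the call fails LOW_DEPTH, not
GERMLINE_AF). A call lacking an optional evidence field does not fire
that rule; `strict_missing` turns absence into rejection. Upstream
BAM-level steps (MAPQ filtering, indel realignment) are out of scope and
assumed done by the caller.

## Exact tests

Pairwise gene co-occurrence uses the two-sided Fisher exact test on 2×2
per-sample presence/absence tables (scipy), reporting raw p-values —
no multiple-testing correction, matching the display convention of
co-occurrence matrices in this field, with significance stars at 0.05 and
borderline at 0.1. Odds ratios are reported under two conventions: the
conditional-MLE estimate and a Haldane (add 0.5) cross ratio that stays
finite on zero cells; p-values never use a continuity correction. A gene
mutated in no sample or in every sample makes the test degenerate; such
pairs are reported with p = 1 and direction "none". A "mutated sample"
carries ≥ 1 nonsynonymous coding mutation in the gene (synonymous and
noncoding records are excluded unless `coding_only=False`).

The histotype-association test is the Freeman–Halton extension of the
Fisher exact test to 2×k tables, implemented as full enumeration of the
margin-fixed table space in log space: p is the sum of multivariate
hypergeometric probabilities of all tables no more probable than the
observed one (relative tolerance 1e-7 against floating-point ties).
Above a configurable table-space bound (2e7 candidate tables) a seeded
multivariate-hypergeometric Monte Carlo estimate (200k draws) is used
instead. The implementation is verified against scipy's 2×2 Fisher test
(all tables with N ≤ 25) and against an exact rational-arithmetic
enumeration oracle for k > 2; it also reproduces R `fisher.test` values
to printed precision. Zero-margin tables return p = 1 with a warning.
Detection percentages are half-up-rounded integers recomputed from stored
counts, and histotype merges (e.g. the mixed B2-B3 class into B3) sum
counts, conserving totals. NOS/unknown-histotype samples are excluded
from the association test by default — an unknown label is not a
biological class — with `exclude_nos=False` as the switch.

## Consequence classification

Transcript models are interval skeletons (CDS exons, UTRs, splice
window). Precedence: splice site (intronic bases within ±2 of an exon
boundary by default — the canonical donor/acceptor dinucleotides) >
coding > UTR > intron > flank (±1 kb) > intergenic. Coding SNVs are
resolved by translating the affected codon of the spliced,
strand-oriented CDS (biopython's standard table); equal-length multi-base
substitutions are "nonframeshift substitutions", and indels are
frameshift or in-frame by length mod 3. When several transcripts overlap
a locus the most severe consequence wins. Classification is validated
against a whole-protein brute-force translation oracle over every
possible SNV of both fixture genes, including a minus-strand model. The
coding subtotal of a class tally includes synonymous and splice-site
changes — the definition under which a published per-class table's
238/83 (total/coding) split reconciles. M-CAP predicted-impact calling
is a strict threshold (score > 0.025); driver-list membership is an
independent flag, so a known driver with a sub-threshold score (the
recurrent GTF2I L424H case) keeps its driver status.

## Signatures

Single-base substitutions are binned into the standard 96 channels
(6 pyrimidine-centred substitution classes × 16 flanking contexts),
ordered lexicographically (`A[C>A]A` … `T[T>G]T`); purine-reference
records are reverse-complemented into the pyrimidine channel, an
involution covered by a property test. De novo extraction is
non-negative matrix factorization under generalized Kullback–Leibler
divergence with multiplicative updates — the loss is provably
non-increasing per iteration and asserted so in tests — taking the best
of `n_restarts` (default 30) seeded random initializations; signatures
are normalized to probability rows with exposures absorbing scale.
sklearn's KL-NMF serves as an independent cross-check in the tests, never
as the implementation. Matching assigns each de novo signature its
argmax-cosine reference profile (ties broken by lowest index); cosine ≥
0.80 is the default "assigned" threshold.

The packaged reference matrix is a **synthetic stand-in** for the
COSMIC v2 catalogue (30 profiles × 96 channels, generated
deterministically by `scripts/build_reference_signatures.py`). Each
numbered profile encodes the qualitative channel preferences the
correspondingly numbered COSMIC v2 signature is known for — e.g. 1: C>T
at NpCpG (5-methylcytosine deamination), 2/13: APOBEC C>T / C>G at TpC,
4/29: tobacco-class C>A, 6/15/26: mismatch-repair classes — plus a
seeded Dirichlet background (12% mass) so every profile has full
support. Numeric values are *not* the published catalogue values, so
matches against real tumor data are not meaningful; planted-signature
simulation and recovery, which is what the tests exercise, is unaffected
by this substitution because simulation and matching use the same matrix.

## Synthetic cohorts

The generator emits, per sample: `n_germline_per_sample` germline
variants (het:hom ratio 2:1; true AF 0.5 / 0.995; 90% carry a common
population-AF annotation, the remaining 10% model rare/private variants
and can only be removed by the AF window); Poisson(`somatic_rate`)
clonal somatic mutations at true AF purity/2 with channels drawn from a
signature mixture (per-sample exposures are Dirichlet-distributed around
the cohort mixture — between-sample exposure variation is what makes the
mixture identifiable to NMF); an optional recurrent driver call at its
real genomic locus, injected with histotype-dependent probability
concentrated in A/AB; and Poisson-rate artifacts whose true AF lies
inside the somatic window and which breach **exactly one** evidence
threshold each, so every reason code is individually testable. Observed
alt reads are Binomial(depth, true AF) with negative-binomial depth
(default mean 1248, echoing deep panel coverage; dispersion 8); calls
with zero sampled alt reads are not emitted (a caller would not report
them). Purity is Beta-distributed per histotype (means: A 0.60, AB 0.40,
B1/B2 0.15, B2-B3 0.20, B3 0.30; concentration 40) — the per-histotype
means are stated modelling assumptions encoding the thymocyte-dilution
narrative, not published measurements. Default cohort shape (67 samples,
histotype mix 12/12/5/21/5/8/4, driver rates ≈ 0.5/0.42/0.1 in A/AB/B2)
mirrors the study cohort the package is shaped around. Somatic records
are assigned effect classes drawn from the published per-class tally, so
downstream catalog summaries see realistic class proportions.

What the generator does **not** model: copy-number change and LOH (the
clonal model is strictly AF = purity/2), subclonal structure (available
only as an optional AF multiplier), read-level errors, mapping artifacts
beyond the injected evidence breaches, and germline AF skew from CNVs.
Passing parameter-recovery tests therefore demonstrates that the cascade
implements its thresholds correctly under the stated statistical model —
not that those thresholds are optimal for any particular real dataset.

Problem sizes used by the test suite were chosen for statistical
resolution: the filter-recovery check uses 50 samples at depth 200 and
purity 0.2 (≈ 10k germline / ≈ 200 detectable somatic calls, so the
0.99/0.95 bounds are measured with adequate precision), and the
signature-recovery check uses 40 samples × ~150 somatic SNVs from a
two-signature mixture, enough counts for stable rank-2 KL-NMF.

## Known limitations and data caveats

* Published per-histotype tables in this literature do not always
  reconcile with their stated cohort sizes; `detection_table` therefore
  logs a reconciliation warning when counts disagree with an expected
  total, and the association test computes from whatever table it is
  given. Both nonsynonymous-only and all-coding sample counts can be
  derived from a tally, exposing rather than resolving such
  discrepancies.
* The exact-test enumeration is exponential in k; beyond the Monte Carlo
  bound the p-value is a seeded estimate (standard error ≈ 1e-3 at the
  default 200k draws).
* Genome build is treated as opaque metadata: coordinates are never
  lifted over or mixed, and all internal coordinates are 1-based closed
  with conversion only at the BED boundary.
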