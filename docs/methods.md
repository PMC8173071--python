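# Methods

## Coordinate model

All internal coordinates are 0-based half-open on a fixed chromosome set;
GTF (1-based closed) converts at the file boundary in both directions, and
BED12 blocks are expanded to absolute exon coordinates on read. The identity
key for isoform matching everywhere is the *intron chain*: the ordered
(donor, acceptor) coordinate pairs of a multi-exon structure. Strand-aware
ends follow the usual convention (5′ = start on `+`, end on `-`).

## Transcript-model construction

**Clustering.** Reads are grouped by (chromosome, strand, intron count) and
scanned in a canonical order (first intron boundary, then span); each read
joins the first existing cluster whose *representative* (seed read) has
every intron boundary within 20 bp. Mono-exon reads additionally need both
ends within 60 bp. This greedy representative linkage is deterministic and
order-independent because of the canonical sort; the linkage rule itself is
a design choice — the tolerances are the fixed parameters, and first-fit is
the simplest deterministic rule that respects them. Terminal tolerances are
deliberately *not* enforced for multi-exon reads: a 5′-degraded read should
co-cluster with full-length reads of the same remaining chain, and 5′
variability is resolved later by the collapse step. Clusters below 3 reads
are discarded (counted, never re-used).

**Consensus.** Each boundary of the model is the member median, ties
resolved to the lower value so even-sized clusters stay deterministic. A
consensus producing an empty exon or intron rejects the cluster with a
warning; this cannot happen for clusters within tolerance but is guarded.

**Loci and collapse.** Models on one strand whose 3′ ends lie within 100 bp
form a locus (connected components; on sorted ends these are exactly the
maximal chains of ≤ 100 bp gaps). Within a locus, model A is absorbed into
B when (a) A's intron chain is a contiguous 3′-terminal subsequence of B's
(equality allowed) with boundaries within 5 bp, (b) 3′ ends are within
100 bp, and (c) A's 5′ end lies within 5,000 bp of the 5′ end of the B exon
its first exon aligns to. The survivor has the most introns, then higher
support, longer span, smaller start; fragments are processed
fewest-introns-first and the procedure iterates to a fixed point, which the
tests verify is absorption-free and identical to an exhaustive pairwise
oracle. Support is additive under absorption, so total support never
exceeds the read count.

The 100 bp locus tolerance reuses the 3′ collapse tolerance; the two could
in principle differ, but a single 3′ scale keeps the locus definition and
the collapse consistent.

## Classification

Class codes are re-implemented with a fixed precedence
(`= c k m n j o e i y x p s u`) rather than delegated, so their semantics
are explicit and testable: `=` requires an exact intron-chain match with
free terminal ends (0 bp tolerance — degradation is already handled by the
collapse); `c`/`k` are contiguous sub-chain containments; `m`/`n` are
all/partial intron retention; `j` shares ≥ 1 exact intron; `o` any other
same-strand exon overlap; `e` a mono-exon read poking ≥ 10 bp into a
reference intron (checked before `o`, which would otherwise shadow it);
`i`/`y` intron containments; `x`/`s` opposite-strand exon/span overlap; `p`
same-strand within 2,000 bp downstream of a reference 3′ end; `u`
intergenic. Among overlapping references the highest-precedence code wins,
ties broken by shared introns then overlap length. Categories follow the
any-annotation rule: any `=` → known isoform; else any of `c k j m n o` →
novel isoform; else any of `i u y x` → novel locus; else artifact.

Accuracy metrics operate on multi-exon sets at five levels: exonic-base
overlap (strand-aware union/intersection), exact unique exons (terminal
exons matched on the internal boundary only), exact introns, exact intron
chains, and loci (reference gene groups vs predicted loci, matched by
same-strand exon overlap).

## Quantification

A read is compatible with a model when its intron chain is a 3′-terminal
subsequence of the model's within 20 bp per boundary and it lies inside the
model span (± 60 bp); mono-exon reads must sit inside the model's
3′-terminal exon. Anchoring at the 3′ end reflects that degraded cDNA loses
5′ sequence. Ambiguous reads are apportioned by EM over equivalence classes
of identical compatible sets (uniform initialisation, relative tolerance
1e-6, ≤ 100 iterations); estimated counts are conserved at every iteration
and the likelihood is non-decreasing (asserted in tests). TPM is
proportion × 10⁶ with *no* length normalisation: each full-length read
represents one molecule, so a length term would bias recovery. Reads
compatible with nothing are reported as unassigned, never force-assigned.

## Tissue specificity

Excluded samples are dropped first, then any tissue left with fewer than
two replicates; x_i is the arithmetic mean TPM over a tissue's replicates
("average expression", hence mean rather than median). Transcripts with
expression in at most one sample are excluded from scoring, as are all-zero
rows. TSI = max(x)/Σx ∈ [1/n, 1]; boundaries are taken literally —
tissue-specific iff TSI ≥ 0.8, broad iff TSI < 0.5. The stratified summary
uses the 1 and 10 TPM cutoffs. No additional expression floor is applied
beyond the single-sample rule; whether the original analysis used one is
not stated, so the more inclusive choice is documented here. A TSS is
uniquely active in a tissue when its ± 50 bp window overlaps no other
model's same-strand window (two TSS clash iff ≤ 100 bp apart).

## Splicing events and position statistics

Local events are enumerated pairwise within each locus: SE (internal exon
vs joined flanking junctions), RI (consecutive exon pair vs fused exon with
shared outer boundaries), MX (adjacent intron pairs sharing outer junctions
with non-overlapping exclusive middle exons), A5/A3 (introns sharing one
boundary, with the *flanking exons at the differing boundary overlapping
each other*), AF/AL (distinct, non-overlapping terminal exons with distinct
inner junctions splicing into overlapping partner exons). The two overlap
requirements make A5/A3 and AF/AL disjoint: a shared-boundary alternative
whose variable exons overlap is a splice-site event; one whose terminal
exons are disjoint is a terminal-exon event. Events deduplicate on their
coordinate tuple, so counts are input-order invariant.

The shuffle re-places each interval uniformly at random with its length
preserved, rejecting placements that touch excluded regions (≤ 10,000
tries, then an error naming the interval). Genome-wide placement
(chromosome weighted by length) is the default used for the headline
proximity test; a `same_chrom` flag restricts placement to the original
chromosome. Nearest-gene distances follow the bedtools `closest -d`
convention (overlap = 0, book-ended = 1), cross-checked against the
bedtools binary in the tests. The rank-sum test uses midranks; the exact
two-sided p-value is enumerated over all C(n₁+n₂, n₁) labelings when
n₁+n₂ ≤ 12 without ties, otherwise a normal approximation with tie and
continuity corrections (identical samples give p = 1 by convention).

## The synthetic-data generator

The generator emulates the statistical regime of a large multiplexed
full-length cDNA study, not its sequences: coordinates only, no bases, no
basecalling error model, no barcode structure.

* **Genes** are placed without overlap on two synthetic chromosomes,
  8–20 kb apart. Exon counts follow a categorical distribution (mean ≈ 4.5,
  10% mono-exon genes); exon lengths are log-normal, sized per gene so the
  full-length mature transcript targets the configured 759 b mean read
  length; intron lengths are log-normal around 700 bp.
* **Isoforms** (1–4 per gene) derive from the gene's master chain by exon
  skipping, 30–80 bp splice-site shifts, or alternative terminal exons
  placed inside flanking introns. Two guards keep the design *resolvable*:
  no isoform's intron chain may be a 3′-terminal subsequence of a sibling's
  within the 5 bp collapse tolerance (it would be indistinguishable from a
  degradation product), and same-intron-count siblings must differ by
  ≥ 40 bp (twice the 20 bp cluster tolerance) at some boundary (otherwise
  their reads co-cluster and the minor isoform is unrecoverable by
  construction, for any method honouring the tolerances).
* **Novelty plan**: 10% of genes (whole, multi-exon) are withheld from the
  emitted public reference as novel loci; 10% of transcripts (non-first
  isoforms of retained genes) as novel isoforms, so each keeps an
  exon-overlapping sibling in the reference.
* **Expression**: a fraction (default 0.3) of transcripts is expressed in
  exactly one tissue, the rest in all tissues, with log-normal
  per-transcript means (~40 reads/sample) and negative-binomial replicate
  counts (dispersion 0.3) over 5 tissues × 2 replicates (~20k reads total).
  Off-tissue expression of designed-specific transcripts is exactly zero,
  so their specificity is recoverable in principle.
* **Degradation**: with probability 0.3 a read loses a geometric number of
  5′ bases (mean 300) in transcript coordinates, projected to the genome;
  reads never shrink below 50 b. This mirrors 5′-biased RNA degradation and
  is exactly the signal the collapse step exists to absorb.
* **Splice jitter**: each internal boundary wobbles *with probability 0.15*
  by a discretised Gaussian (sd 3 bp, clipped to keep exons/introns ≥ 1 bp);
  terminal ends always wobble at twice that scale. Real spliced aligners
  snap most junctions exactly and a minority wobble by a few bases; a
  model that jitters every boundary would also make the per-boundary median
  differ from the true coordinate with substantial probability, i.e. exact
  chain recovery would fail for reasons unrelated to the pipeline.
* **Noise**: mono-exon reads at 2% of the genic read count, placed
  uniformly outside exonic space with log-normal lengths — these exercise
  the cluster-size floor and the single-exon filter.

Determinism: every component draws from its own `numpy` generator stream
derived from the single config seed, so outputs are byte-identical across
runs and platforms.

What passing tests on this generator do **not** show: robustness to
alignment artifacts (multi-mapping, softclip-induced boundary shifts at
repeats), chimeric or fusion reads, internal priming, base-quality
filtering, or reference annotations with overlapping genes. The realized
mean read length sits slightly below the configured target (typically
5–10%) because derived isoforms and degraded reads are shorter than the
full-length transcripts the target is calibrated on.

## Problem sizes and numerical choices

Default experiments are sized for seconds-scale runs on one CPU: 20 genes /
~40 transcripts / ~20k reads for recovery and classification, 200 designed
transcripts for specificity recovery, 8 samples × 1,000 reads for EM
recovery, 2,000 null simulations for rank-sum calibration, 1,000 placements
for shuffle uniformity. EM recovery is reported as the mean relative error
of estimates averaged over replicate samples — a single 1,000-read sample's
multinomial noise alone exceeds 5% relative error for minor isoforms, so
the estimator, not one draw, is what is being bounded. Median ties resolve
low; collapse survivor ties resolve by support, span, then start; all
percentage reports come from the same ratio/partition helpers the tests
exercise against printed-count identities.

## Known limitations

Single-linkage-style greedy clustering can split a read group whose
pairwise boundary spread exceeds the tolerance (the guaranteed-recovery
regime is jitter ≤ half the tolerance); the class-code precedence is a
documented choice and other tools' versions differ in `m`/`n`/`o` edge
semantics; locus-level accuracy depends on the locus definition (3′-end
groups), which differs from gene-level loci in reference annotations; the
quantifier has no analogue of alignment quality filtering, which operates
on evidence this coordinate-level pipeline does not consume.
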