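# Methods

## Insertion evidence from alignments

A gene-trap flank read begins at the genomic base adjacent to the viral
long terminal repeat, so the first sequenced base of the read marks the
insertion position. For a forward-strand alignment that is the leftmost
aligned reference base (SAM `POS`); for a reverse-strand alignment it is
the rightmost aligned base, `POS` plus the reference-consumed CIGAR
length minus one, because a minus-strand read is sequenced right to left
relative to the reference. The reference span is computed from the CIGAR
operations M/D/N/=/X directly (htslib reports an end of `POS + 1` for
degenerate, reference-free CIGARs, which would silently mislocate such
records; they are instead skipped with a warning). Unmapped, secondary
and supplementary records are ignored. The mapping-quality filter
defaults to MAPQ ≥ 10, a compromise between discarding multi-mapper
noise and keeping sensitivity in repetitive introns; it is a plain
parameter. All internal coordinates are 1-based inclusive; UCSC
annotation input (0-based half-open) is converted at the parsing
boundary.

Plain SAM without a header is accepted: when no `@SQ` lines are present,
reference names and generous length bounds are scanned from the records
and a temporary headered copy is handed to pysam, since htslib refuses
headerless SAM text.

## Read preprocessing

Optional FASTQ preprocessing removes a 3' adaptor (longest read suffix
matching a prefix of the adaptor, minimum overlap 3 nt, at most 10%
mismatches — conservative enough not to eat genomic sequence) and then
quality-trims the 3' end: bases are removed while the mean Phred score
over the trailing 4-base window is below the cutoff (default Q20), then
any remaining trailing bases individually below the cutoff are stripped.
The two steps are iterated to a fixed point, which makes the whole
operation idempotent — a useful contract when pipelines are re-entered —
at negligible cost since the second iteration is almost always a no-op.
Reads shorter than 26 nt after trimming are discarded; shorter flanks
align too ambiguously to place an insertion.

## Independent insertions (I.I.)

Read counts per insertion reflect amplification far more than cell
abundance, and sequencing/trimming errors shift starts by 1–2 nt. Both
artifacts are removed by collapsing: per chromosome and strand, the
position with the highest remaining read count becomes an insertion,
absorbing all positions within ± *window* nt of it (cumulative read
count retained), until no positions remain; sites below the read-count
threshold are then dropped. Greedy highest-count-first anchoring is used
because the insertion is defined as the peak position; a left-to-right
sweep could anchor windows at non-peak shoulders. Count ties break
toward the smaller coordinate, making the procedure fully deterministic.
The greedy rule also forbids transitive chains: any two reported sites
on one strand are more than *window* apart.

Defaults: window 5 nt (shifts of a few nucleotides are corrected, and
true neighbouring insertions are almost always further apart than 5 bp);
threshold 2 reads (suppresses single-read alignment artifacts without
materially reducing insertion numbers). The control pool may use its own
threshold to compensate for unequal sampling depth between pools.

## Gene models and statistics

All transcript variants sharing a gene name (on one chromosome and
strand) merge into a single span `[min txStart, max txEnd]`; the exon
union is the interval union of all their exons and the introns are the
remainder, so the two sub-regions partition the span exactly. A gene
name annotated at several loci becomes separate models suffixed `_1`,
`_2`, … in genomic order — merging discontiguous loci would fabricate
giant phantom introns. All annotated exons count as exonic, UTRs
included. Overlapping genes each receive any shared insertion; no
exclusivity is imposed.

Per gene: `n_II` counts insertions anywhere in the span; an exonic
insertion disrupts in either orientation, while an intronic one
disrupts only when the trap's splice acceptor is oriented with
transcription, so `n_DI = n_exonic + n_intron_sense`. The orientation
bias `Bias = (n_intron_sense + pc)/(n_intron_anti + pc)` (pseudocount
pc = 1) measures the excess of disruptive over neutral intronic
insertions independently of insertion numbers; the additive pseudocount
keeps it finite when no antisense insertions were seen and shrinks the
ratio at low counts. The mapping from read strand to splice-acceptor
orientation depends on which side of the vector the sequencing primer
sits, so an `orientation_mode` switch (`as_aligned`/`inverted`) flips
the effective strand globally when a protocol requires it.

Replicates aggregate component-wise (exonic, intronic sense, intronic
antisense) by sum or median, with derived statistics recomputed from the
aggregated components; medians of even replicate counts may be
half-integral, which all downstream arithmetic accepts (Fisher testing
rounds half-up).

## Candidate ranking

Each gene's evidence is the vector (fe_II, fe_DI, fe_bias) of
pseudocounted selected/control fold enrichments. No library-size
normalization is applied: the two pools are compared through ranks and
outlier structure, not absolute rates, and per-dataset read thresholds
are the supported depth adjustment. Genes with zero insertions in both
pools are excluded before ranking — their vectors would sit at the
pseudocount identity and only densify the null cluster — and reported
separately.

**LOF.** The Local Outlier Factor is computed on the raw (not
log-transformed) enrichment vectors with Euclidean distance and
neighbourhood size k = 20; a log-feature option exists behind a flag.
The implementation follows the classical definition exactly, including
tie-inclusive k-distance neighbourhoods (every point within the
k-distance belongs to the neighbourhood, so it may exceed k points).
One numerical guard: the mean reachability distance is floored at 1e-10
(densities capped at 1e10), so a point duplicated more than k times —
common in sparse screens where many genes share one small count
vector — scores exactly 1 instead of producing infinities that would
propagate to every neighbour of the duplicate cluster and destroy the
ranking. On continuous data the floor is unreachable and the scores are
the textbook values; uniform rescaling of all vectors leaves them
unchanged. Candidates sort by decreasing LOF, ties by gene name.

**FT.** Per gene, a one-sided Fisher's exact test of the 2×2 table
contrasting the gene's D.I. with the rest of the dataset's D.I. in
selected vs control pools; the enrichment p-value is the upper
hypergeometric tail. Only the enrichment side is tested because
depletion is not a screening signal here. Sorting is by p ascending,
ties by descending D.I. fold enrichment, then gene name.

**Rank.** Genes are ranked by D.I. descending within each pool (ties
averaged); the score ln(rank_selected) − ln(rank_control) is sorted
ascending. The logarithm base only scales scores and never reorders.

## The simulator

The generator emulates the screen's data-generating process on a toy
single-chromosome genome: equal-size genes (four 300 nt exons separated
by 3 kb introns, 10 kb intergenic gaps, alternating strands), a control
pool placed uniformly, and a selected pool drawn over genome segments
with each gene's span weighted by its selection coefficient. Intronic
insertions in weighted genes of the selected pool fall sense with
probability `sense_bias_selected`, exercising the Bias statistic
independently of count enrichment. Each insertion amplifies into
`round(lognormal(μ=2.0, σ=1.5))` reads (clipped ≥ 1, mean ≈ 21, spread
over several orders of magnitude — the pathology motivating I.I.
collapsing), and each read start independently shifts by ±1–2 nt with
probability 0.1, mimicking trimming/sequencing-error jitter that the
default 5 nt window corrects. All randomness flows from one seed;
identical configs give byte-identical SAM/annotation/truth outputs.
Insertions are sampled a read-length margin away from chromosome ends so
every simulated alignment stays in range.

The reference condition — 500 genes, five planted at weight 20 with
sense bias 0.9, 10,000 insertions per pool — is the package default and
the scale at which recovery and robustness are verified. Deliberately
not modelled: real sequence content (alignment is simulated, not
performed), chromatin-dependent insertion hotspots, overlapping or
variable gene structures, and passenger co-selection. Passing tests
therefore demonstrate the correctness and robustness of the analysis
chain under the stated statistical structure, not performance on any
particular real screen.

## Verification sizes and numerical choices

The oracle batteries run at desk scale: 200 random position-count maps
(≤ 500 positions) against a literal greedy re-derivation; every 2×2
table with total ≤ 50 against exact integer enumeration (agreement ~1e-16,
asserted at 1e-10); LOF clouds up to n = 200 for k ∈ {5, 10, 20} against
a brute-force transcription of the definition (asserted at 1e-9);
planted-gene recovery over 40 seeded reference screens (required in
≥ 95%); top-5 stability across window ∈ {5, 10, 25} × threshold ∈ {1, 2}.
Degenerate inputs are defined, not special-cased: empty streams yield
empty outputs, a window of 0 collapses nothing, identical pools give
unit enrichment vectors everywhere, and an all-duplicate LOF cloud
scores 1 for every point.

## Known limitations

Transcript-expression-aware refinement of gene models is out of scope,
as is invoking aligners (alignments arrive as SAM) and UMI-based
deduplication (the protocol sequences a single LTR-proximal flank).
Whether the original screen protocols count UTR exons as exonic or trim
LTR-derived 5' bases before alignment is protocol-dependent; here all
annotated exons are exonic and no 5' trimming is performed.
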