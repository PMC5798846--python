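"""Synthetic gene-trap screen generator with ground truth.

Emulates the data-generating process of a haploid insertional-mutagenesis
screen at desk scale: a toy single-chromosome genome tiled with gene
models, a control pool of insertions placed uniformly, a selected pool
drawn with per-gene selection weights, heavy-tailed (lognormal) PCR
amplification of each insertion into many reads, and small alignment
jitter of individual read start positions.  Output is plain SAM plus the
toy annotation and a per-insertion truth table, so the whole analysis
chain can be exercised and scored against known ground truth.

The generator captures the statistical structure that the analysis must
be robust to — amplification spread over orders of magnitude, 1-2 nt
alignment shifts, strand-biased intronic insertions in selected genes —
but not sequence content: reads carry placeholder sequence and alignment
is simulated, never performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptRecord, build_gene_models
from .sequence_io import AlignedFlank

logger = logging.getLogger(__name__)

READ_LENGTH = 30  # all simulated reads are 30M alignments
_EDGE_MARGIN = READ_LENGTH + 5  # keep alignments clear of chromosome ends

CHROM = "chr1"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic screen.

    The defaults describe the reference condition used throughout the
    package's own verification: 500 genes on one chromosome, 10,000
    independent insertions per pool, five genes under strong selection
    (20x weight) whose intronic insertions in the selected pool fall in
    the sense orientation with probability 0.9, lognormal read
    amplification spanning several orders of magnitude, and a 10% chance
    of a 1-2 nt alignment shift per read.
    """

    n_genes: int = 500
    n_insertions_control: int = 10_000
    n_insertions_selected: int = 10_000
    #: gene name -> selection weight (>= 0); genes not listed have weight 1
    selection_coefficients: dict[str, float] = field(default_factory=dict)
    #: probability that an intronic insertion in a selected (weight > 1)
    #: gene lands in the sense orientation in the selected pool
    sense_bias_selected: float = 0.9
    #: (mu, sigma) of ln read-count; counts are rounded and clipped >= 1
    read_count_lognormal: tuple[float, float] = (2.0, 1.5)
    jitter_prob: float = 0.1
    jitter_max_nt: int = 2
    seed: int = 0
    # toy gene geometry
    n_exons: int = 4
    exon_length: int = 300
    intron_length: int = 3_000
    intergenic_length: int = 10_000
    genome_length: int | None = None  # default: computed from the layout

    @property
    def gene_span_length(self) -> int:
        return self.n_exons * self.exon_length + (self.n_exons - 1) * self.intron_length

    @property
    def effective_genome_length(self) -> int:
        minimum = (
            self.n_genes * (self.gene_span_length + self.intergenic_length)
            + self.intergenic_length
        )
        if self.genome_length is None:
            return minimum
        if self.genome_length < minimum:
            raise ValueError(
                f"genome_length {self.genome_length} cannot hold {self.n_genes} genes"
                f" (need >= {minimum})"
            )
        return self.genome_length

    def __post_init__(self) -> None:
        for name, p in (("sense_bias_selected", self.sense_bias_selected),
                        ("jitter_prob", self.jitter_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(w < 0 for w in self.selection_coefficients.values()):
            raise ValueError("selection weights must be >= 0")


def default_config(seed: int = 0, n_selected_genes: int = 5,
                   selection_weight: float = 20.0, **overrides) -> SimulationConfig:
    """The reference screen: evenly spaced strongly selected genes."""
    base = SimulationConfig(seed=seed, **overrides)
    step = base.n_genes // (n_selected_genes + 1) if n_selected_genes else 1
    planted = {
        _gene_name(step * (i + 1)): selection_weight for i in range(n_selected_genes)
    }
    return replace(base, selection_coefficients=planted)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth: one row per insertion, plus the planted gene set."""

    insertions: pd.DataFrame  # pool, chrom, strand, position, gene, region
    selected_genes: tuple[str, ...]


@dataclass
class SimulatedScreen:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    transcripts: list[TranscriptRecord]
    gene_models: list[GeneModel]
    truth: TruthTable
    #: read-level insertion evidence after amplification and jitter
    control_flanks: list[AlignedFlank]
    selected_flanks: list[AlignedFlank]

    def write_outputs(self, out_dir) -> dict[str, Path]:
        """Write SAM pools, UCSC-style annotation and truth table."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "control_sam": out / "control.sam",
            "selected_sam": out / "selected.sam",
            "annotation": out / "annotation.txt",
            "truth": out / "truth.tsv",
            "selected_genes": out / "selected_genes.txt",
        }
        write_sam(self.control_flanks, self.config.effective_genome_length,
                  paths["control_sam"])
        write_sam(self.selected_flanks, self.config.effective_genome_length,
                  paths["selected_sam"])
        write_annotation_table(self.transcripts, paths["annotation"])
        self.truth.insertions.to_csv(paths["truth"], sep="\t", index=False)
        paths["selected_genes"].write_text(
            "".join(f"{g}\n" for g in self.truth.selected_genes)
        )
        return paths


def _gene_name(i: int) -> str:
    return f"gene_{i:04d}"


def make_toy_annotation(config: SimulationConfig) -> list[TranscriptRecord]:
    """Deterministic toy gene layout: equal-size genes, alternating strands.

    Coordinates follow the UCSC convention (0-based half-open) exactly as
    a Table Browser export would.
    """
    records = []
    cursor = config.intergenic_length  # 0-based start of the first gene
    for i in range(config.n_genes):
        exon_starts = tuple(
            cursor + j * (config.exon_length + config.intron_length)
            for j in range(config.n_exons)
        )
        exon_ends = tuple(s + config.exon_length for s in exon_starts)
        records.append(TranscriptRecord(
            gene_name=_gene_name(i),
            transcript_id=f"tx_{i:04d}",
            chrom=CHROM,
            strand="+" if i % 2 == 0 else "-",
            tx_start=cursor,
            tx_end=exon_ends[-1],
            exon_starts=exon_starts,
            exon_ends=exon_ends,
        ))
        cursor = exon_ends[-1] + config.intergenic_length
    return records


def write_annotation_table(records: list[TranscriptRecord], path) -> None:
    """Write transcripts as a UCSC Table Browser style export."""
    with open(path, "w") as fh:
        fh.write("#name\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname2\n")
        for r in records:
            starts = ",".join(str(s) for s in r.exon_starts) + ","
            ends = ",".join(str(e) for e in r.exon_ends) + ","
            fh.write(
                f"{r.transcript_id}\t{r.chrom}\t{r.strand}\t{r.tx_start}\t"
                f"{r.tx_end}\t{starts}\t{ends}\t{r.gene_name}\n"
            )


def _region_of(gene: GeneModel, position: int) -> str:
    for s, e in gene.exon_union:
        if s <= position <= e:
            return "exon"
    return "intron"


def _sample_pool(
    rng: np.random.Generator,
    config: SimulationConfig,
    genes: list[GeneModel],
    n_insertions: int,
    selected_pool: bool,
) -> pd.DataFrame:
    """Draw insertion positions/strands for one pool.

    Control pools are uniform over the insertable genome (a margin at
    each chromosome end keeps simulated alignments in range); selected
    pools weight each gene's span by its selection coefficient, with
    intergenic space at weight 1.  Intronic insertions in weighted genes
    of the selected pool are drawn sense with ``sense_bias_selected``.
    """
    genome_length = config.effective_genome_length
    lo, hi = _EDGE_MARGIN + 1, genome_length - _EDGE_MARGIN

    # segment list: genes plus intergenic gaps covering [lo, hi]
    seg_start, seg_end, seg_weight, seg_gene = [], [], [], []
    cursor = lo
    weights = config.selection_coefficients
    for gi, g in enumerate(genes):
        if g.span[0] > cursor:
            seg_start.append(cursor)
            seg_end.append(g.span[0] - 1)
            seg_weight.append(1.0)
            seg_gene.append(-1)
        w = weights.get(g.gene_name, 1.0) if selected_pool else 1.0
        seg_start.append(g.span[0])
        seg_end.append(g.span[1])
        seg_weight.append(w)
        seg_gene.append(gi)
        cursor = g.span[1] + 1
    if cursor <= hi:
        seg_start.append(cursor)
        seg_end.append(hi)
        seg_weight.append(1.0)
        seg_gene.append(-1)

    starts = np.array(seg_start)
    lengths = np.array(seg_end) - starts + 1
    probs = np.array(seg_weight) * lengths
    total = probs.sum()
    if total <= 0:
        raise ValueError("selection weights leave no insertable mass")
    probs = probs / total

    seg = rng.choice(len(starts), size=n_insertions, p=probs)
    positions = starts[seg] + rng.integers(0, lengths[seg])

    gene_idx = np.array(seg_gene)[seg]
    gene_names, regions, sense = [], [], np.zeros(n_insertions, dtype=bool)
    coin = rng.random(n_insertions)
    for i in range(n_insertions):
        gi = gene_idx[i]
        if gi < 0:
            gene_names.append("")
            regions.append("intergenic")
            sense[i] = coin[i] < 0.5
            continue
        gene = genes[gi]
        region = _region_of(gene, int(positions[i]))
        gene_names.append(gene.gene_name)
        regions.append(region)
        under_selection = (
            selected_pool and weights.get(gene.gene_name, 1.0) > 1.0
        )
        p_sense = (
            config.sense_bias_selected
            if under_selection and region == "intron" else 0.5
        )
        sense[i] = coin[i] < p_sense

    gene_strand = np.array([
        genes[gi].strand if gi >= 0 else "+" for gi in gene_idx
    ])
    flip = {"+": "-", "-": "+"}
    strands = np.where(
        sense, gene_strand, np.vectorize(flip.get)(gene_strand)
    )
    return pd.DataFrame({
        "pool": "selected" if selected_pool else "control",
        "chrom": CHROM,
        "strand": strands,
        "position": positions.astype(np.int64),
        "gene": gene_names,
        "region": regions,
    })


def _amplify_and_jitter(
    rng: np.random.Generator, config: SimulationConfig, insertions: pd.DataFrame
) -> list[AlignedFlank]:
    """Expand insertions into read-level evidence with amplification and jitter."""
    mu, sigma = config.read_count_lognormal
    n = len(insertions)
    multiplicity = np.maximum(
        np.round(rng.lognormal(mu, sigma, size=n)), 1.0
    ).astype(np.int64)
    positions = np.repeat(insertions["position"].to_numpy(), multiplicity)
    strands = np.repeat(insertions["strand"].to_numpy(), multiplicity)
    total = len(positions)
    if config.jitter_prob > 0 and config.jitter_max_nt > 0:
        jittered = rng.random(total) < config.jitter_prob
        magnitude = rng.integers(1, config.jitter_max_nt + 1, size=total)
        sign = rng.choice((-1, 1), size=total)
        positions = positions + jittered * magnitude * sign
    return [
        AlignedFlank(CHROM, s, int(p), 42)
        for s, p in zip(strands, positions)
    ]


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Run one simulation: annotation, both pools, truth, read evidence.

    Fully deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    transcripts = make_toy_annotation(config)
    genes = build_gene_models(transcripts)
    order = {g.gene_name: g for g in genes}
    genes = [order[_gene_name(i)] for i in range(config.n_genes)]

    control = _sample_pool(rng, config, genes, config.n_insertions_control, False)
    selected = _sample_pool(rng, config, genes, config.n_insertions_selected, True)
    truth = TruthTable(
        insertions=pd.concat([control, selected], ignore_index=True),
        selected_genes=tuple(sorted(
            g for g, w in config.selection_coefficients.items() if w > 1.0
        )),
    )
    control_flanks = _amplify_and_jitter(rng, config, control)
    selected_flanks = _amplify_and_jitter(rng, config, selected)
    logger.info(
        "simulate_screen(seed=%d): %d+%d insertions -> %d+%d reads",
        config.seed, len(control), len(selected),
        len(control_flanks), len(selected_flanks),
    )
    return SimulatedScreen(
        config=config,
        transcripts=transcripts,
        gene_models=genes,
        truth=truth,
        control_flanks=control_flanks,
        selected_flanks=selected_flanks,
    )


def write_sam(flanks: list[AlignedFlank], genome_length: int, path) -> None:
    """Write read evidence as minimal plain SAM (placeholder sequence).

    A flank records the first sequenced base; for minus-strand reads SAM
    POS is therefore the flank position minus the alignment span plus 1.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{genome_length}\n")
        cigar = f"{READ_LENGTH}M"
        for i, f in enumerate(flanks):
            if f.strand == "+":
                flag, pos = 0, f.position
            else:
                flag, pos = 16, f.position - READ_LENGTH + 1
            fh.write(
                f"read_{i}\t{flag}\t{f.chrom}\t{pos}\t{f.mapq}\t{cigar}"
                f"\t*\t0\t0\t*\t*\n"
            )


def truth_recovery_report(truth: TruthTable, candidates: pd.DataFrame,
                          top_n: int = 10) -> dict:
    """Compare planted selected genes with the top of a candidate list."""
    planted = set(truth.selected_genes)
    top = list(candidates.sort_values("rank_position")["gene"].head(top_n))
    hits = sorted(planted & set(top))
    misses = sorted(planted - set(top))
    if not planted:
        warnings.warn("no planted selected genes in the truth table")
        precision = recall = 0.0
    else:
        precision = len(hits) / top_n
        recall = len(hits) / len(planted)
    return {
        "top_n": top_n,
        "hits": hits,
        "misses": misses,
        "precision": precision,
        "recall": recall,
    }
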