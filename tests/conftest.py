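import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hapscreen import annotation

UCSC_HEADER = "#name\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname2\n"


def ucsc_table(rows: list[tuple]) -> str:
    """Build a UCSC-style annotation export from transcript tuples.

    Each row is (transcript_id, chrom, strand, txStart, txEnd,
    exon_starts, exon_ends, gene_name) with exon coordinate lists.
    """
    lines = [UCSC_HEADER]
    for name, chrom, strand, start, end, ex_s, ex_e, gene in rows:
        starts = ",".join(map(str, ex_s)) + ","
        ends = ",".join(map(str, ex_e)) + ","
        lines.append(f"{name}\t{chrom}\t{strand}\t{start}\t{end}\t{starts}\t{ends}\t{gene}\n")
    return "".join(lines)


@pytest.fixture
def two_gene_models():
    """Two toy genes on opposite strands: plus-strand gA, minus-strand gB.

    gA: span 1-based [101, 400], exons [101,200] and [301,400], intron
    [201,300].  gB: span [1001, 1600], exons [1001,1100] and [1501,1600],
    intron [1101,1500].
    """
    import io
    table = ucsc_table([
        ("txA", "chr1", "+", 100, 400, (100, 300), (200, 400), "gA"),
        ("txB", "chr1", "-", 1000, 1600, (1000, 1500), (1100, 1600), "gB"),
    ])
    return annotation.build_gene_models(
        annotation.parse_annotation(io.StringIO(table))
    )


@pytest.fixture
def small_screen():
    """A small simulated screen shared by several test modules."""
    from hapscreen import default_config, simulate_screen
    config = default_config(
        seed=11, n_genes=60, n_insertions_control=1500,
        n_insertions_selected=1500,
    )
    return simulate_screen(config)
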