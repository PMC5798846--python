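"""FASTQ preprocessing and SAM alignment ingestion.

Gene-trap insertion sites are evidenced by sequencing reads whose first
sequenced base lies immediately adjacent to the viral long terminal repeat:
the genomic coordinate of that base is taken as the position of the
insertion event.  This module turns raw reads (optionally) and read
alignments (primarily) into strand-aware insertion evidence.

Coordinates are 1-based inclusive throughout (SAM convention).  For a
forward-strand alignment the first sequenced base is the leftmost aligned
reference base (``POS``); for a reverse-strand alignment it is the rightmost
aligned reference base, because a minus-strand read is sequenced right to
left with respect to the reference.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33
#: width of the sliding window used for 3' quality trimming
QUALITY_WINDOW = 4
#: minimum read/adaptor overlap considered an adaptor match
MIN_ADAPTOR_OVERLAP = 3
#: maximum fraction of mismatches tolerated in an adaptor match
MAX_ADAPTOR_MISMATCH_FRAC = 0.10

DEFAULT_MIN_READ_LENGTH = 26
DEFAULT_QUALITY_CUTOFF = 20
DEFAULT_MIN_MAPQ = 10


class FastqFormatError(ValueError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


@dataclass(frozen=True)
class RawRead:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class AlignedFlank(NamedTuple):
    """One read's genomic insertion evidence.

    ``position`` is the 1-based coordinate of the first sequenced base of
    the read on the reference, i.e. the putative insertion position.
    """

    chrom: str
    strand: str  # '+' or '-'
    position: int
    mapq: int


# ---------------------------------------------------------------------------
# FASTQ reading / writing
# ---------------------------------------------------------------------------

def read_fastq(path_or_handle) -> Iterator[RawRead]:
    """Parse a FASTQ file (4-line records, Phred+33) into ``RawRead``s.

    Raises :class:`FastqFormatError` naming the (0-based) record index of
    the first malformed record.
    """
    handle = path_or_handle
    close = False
    if isinstance(path_or_handle, (str, os.PathLike)):
        handle = open(path_or_handle)
        close = True
    try:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record at index {index}: {exc}"
                ) from exc
            yield RawRead(
                id=title.split()[0] if title else "",
                sequence=seq.upper(),
                qualities=tuple(ord(c) - PHRED_OFFSET for c in qual),
            )
            index += 1
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[RawRead], handle) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    for read in reads:
        qual = "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
        handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
        n += 1
    return n


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

def _adaptor_suffix_length(sequence: str, adaptor: str) -> int:
    """Length of the longest read suffix matching a prefix of ``adaptor``.

    A match requires an overlap of at least :data:`MIN_ADAPTOR_OVERLAP`
    bases with at most 10% mismatches.  Returns 0 when nothing matches.
    """
    max_overlap = min(len(sequence), len(adaptor))
    for overlap in range(max_overlap, MIN_ADAPTOR_OVERLAP - 1, -1):
        suffix = sequence[-overlap:]
        prefix = adaptor[:overlap]
        mismatches = sum(a != b for a, b in zip(suffix, prefix))
        if mismatches <= int(MAX_ADAPTOR_MISMATCH_FRAC * overlap):
            return overlap
    return 0


def _quality_trim_length(qualities: tuple[int, ...], cutoff: int) -> int:
    """New length after 3' quality trimming.

    Bases are removed from the 3' end while the mean Phred score over the
    trailing window (width :data:`QUALITY_WINDOW`, shorter near the start)
    stays below ``cutoff``.
    """
    n = len(qualities)
    while n > 0:
        window = qualities[max(0, n - QUALITY_WINDOW):n]
        if sum(window) / len(window) >= cutoff:
            break
        n -= 1
    # a good window can still end in stray low-quality bases; strip them
    while n > 0 and qualities[n - 1] < cutoff:
        n -= 1
    return n


def _trim_read(read: RawRead, adaptor: str, quality_cutoff: int) -> RawRead:
    """One adaptor-removal + quality-trim pass over a single read."""
    seq, qual = read.sequence, read.qualities
    if adaptor:
        cut = _adaptor_suffix_length(seq, adaptor)
        if cut:
            seq, qual = seq[:-cut], qual[:-cut]
    keep = _quality_trim_length(qual, quality_cutoff)
    if keep < len(seq):
        seq, qual = seq[:keep], qual[:keep]
    if seq is read.sequence:
        return read
    return RawRead(id=read.id, sequence=seq, qualities=qual)


def preprocess_reads(
    reads: Iterable[RawRead],
    adaptor: str = "",
    min_length: int = DEFAULT_MIN_READ_LENGTH,
    quality_cutoff: int = DEFAULT_QUALITY_CUTOFF,
) -> Iterator[RawRead]:
    """Adaptor-trim and quality-trim reads, dropping those now too short.

    Each read has its adaptor suffix removed (longest read suffix matching
    a prefix of ``adaptor``, minimum overlap 3, at most 10% mismatches),
    is then 3'-quality-trimmed, and the two trimming steps are iterated to
    a fixed point so the whole operation is idempotent.  Reads shorter
    than ``min_length`` after trimming are discarded; input order is
    preserved.  An empty ``adaptor`` skips adaptor removal.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    n_in = n_out = 0
    for read in reads:
        n_in += 1
        trimmed = _trim_read(read, adaptor, quality_cutoff)
        while len(trimmed) < len(read):
            read, trimmed = trimmed, _trim_read(trimmed, adaptor, quality_cutoff)
        if len(trimmed) >= min_length:
            n_out += 1
            yield trimmed
    logger.info("preprocess_reads: %d reads in, %d kept", n_in, n_out)


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def _ensure_sam_header(path: str) -> tuple[str, bool]:
    """Return a path to a SAM file that carries @SQ lines.

    htslib refuses to iterate SAM text without a header, but plain
    single-flank alignment dumps sometimes lack one.  When no @SQ line is
    present, scan the records for reference names and rightmost
    coordinates, and write a temporary copy with a synthesized header.
    Returns ``(usable_path, is_temporary)``.
    """
    with open(path) as fh:
        for line in fh:
            if line.startswith("@SQ"):
                return path, False
            if not line.startswith("@"):
                break
    lengths: dict[str, int] = {}
    header: list[str] = []
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                if not line.startswith("@HD"):
                    header.append(line)
                continue
            body.append(line)
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6 or fields[2] == "*":
                continue
            rname, pos = fields[2], int(fields[3])
            # generous span bound; only the name resolution matters
            lengths[rname] = max(lengths.get(rname, 0), pos + 10_000_000)
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".sam", delete=False, prefix="hapscreen_hdr_"
    )
    with tmp:
        tmp.write("@HD\tVN:1.6\tSO:unknown\n")
        for rname in sorted(lengths):
            tmp.write(f"@SQ\tSN:{rname}\tLN:{lengths[rname]}\n")
        tmp.writelines(header)
        tmp.writelines(body)
    return tmp.name, True


def load_alignments(sam_path: str, min_mapq: int = DEFAULT_MIN_MAPQ) -> Iterator[AlignedFlank]:
    """Convert SAM records into strand-aware insertion evidence.

    Unmapped, secondary and supplementary records are skipped, as are
    records below ``min_mapq``.  Forward-strand records yield the leftmost
    aligned reference base; reverse-strand records yield the rightmost
    aligned reference base (POS plus reference-consumed CIGAR length minus
    one) with strand '-'.  Records whose CIGAR consumes no reference bases
    are skipped with a warning.
    """
    path, is_tmp = _ensure_sam_header(os.fspath(sam_path))
    n_in = n_out = 0
    try:
        with pysam.AlignmentFile(path, "r") as sam:
            for rec in sam:
                n_in += 1
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                # htslib reports end = pos + 1 for reference-free CIGARs;
                # count reference-consuming ops (M/D/N/=/X) explicitly
                ref_len = sum(
                    length for op, length in (rec.cigartuples or [])
                    if op in (0, 2, 3, 7, 8)
                )
                if not ref_len:
                    logger.warning(
                        "read %s: CIGAR %s consumes no reference bases; skipped",
                        rec.query_name, rec.cigarstring,
                    )
                    continue
                if rec.is_reverse:
                    # rightmost aligned base: POS + reference span - 1
                    flank = AlignedFlank(rec.reference_name, "-",
                                         rec.reference_start + ref_len,
                                         rec.mapping_quality)
                else:
                    flank = AlignedFlank(rec.reference_name, "+", rec.reference_start + 1, rec.mapping_quality)
                n_out += 1
                yield flank
    finally:
        if is_tmp:
            os.unlink(path)
    logger.info("load_alignments: %d records in, %d flanks out", n_in, n_out)
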