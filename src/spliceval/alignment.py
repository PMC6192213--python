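"""SAM alignment parsing: genomic blocks, aligned fraction, match rate.

An alignment is reduced to the list of genomic blocks it covers, split at
introns (CIGAR ``N``). Deletions (``D``) never split a block — SAM reserves
``N`` for spliced gaps — so "split read" here means spliced or chimeric
placement, not indel structure. Match rate is the fraction of aligned
(M/=/X) query bases identical to the reference base they are paired with;
insertions and clipped bases enter neither numerator nor denominator.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .intervals import ContractError, GenomicInterval, ParseError

logger = logging.getLogger(__name__)

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")

# query-consuming and reference-consuming CIGAR ops
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class AlignmentRecord:
    """One read's alignment, reduced to scoring-relevant features.

    ``blocks`` are the intron-split genomic intervals covered by the primary
    line plus any same-chromosome, same-strand supplementary lines.
    ``aligned_query_fraction`` is aligned query bases / full read length
    (soft- and hard-clipped bases included in the denominator).
    """

    read_id: str
    is_aligned: bool
    chrom: Optional[str] = None
    strand: Optional[str] = None
    blocks: Tuple[GenomicInterval, ...] = ()
    aligned_query_fraction: float = 0.0
    match_rate: Optional[float] = None
    read_len: int = 0
    is_primary: bool = True
    is_chimeric: bool = False

    def __post_init__(self) -> None:
        if not self.is_aligned and self.blocks:
            raise ContractError(f"read {self.read_id}: unaligned record with blocks")
        if not 0.0 <= self.aligned_query_fraction <= 1.0:
            raise ContractError(
                f"read {self.read_id}: aligned_query_fraction "
                f"{self.aligned_query_fraction} outside [0,1]"
            )

    @property
    def span(self) -> Optional[GenomicInterval]:
        if not self.blocks:
            return None
        return GenomicInterval(self.chrom, self.blocks[0].start, self.blocks[-1].end)


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    """Tokenize a CIGAR string; raises :class:`ParseError` on invalid input."""
    if not cigar or cigar == "*":
        raise ParseError(f"cannot tokenize CIGAR {cigar!r}")
    pos = 0
    out: List[Tuple[int, str]] = []
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise ParseError(f"invalid CIGAR {cigar!r} at offset {pos}")
        out.append((int(m.group(1)), m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise ParseError(f"invalid CIGAR {cigar!r} at offset {pos}")
    return out


def blocks_from_cigar(pos: int, cigar: str) -> Tuple[List[Tuple[int, int]], int, int]:
    """Walk a CIGAR from 1-based ``pos``; return (blocks, aligned_query_len, read_len).

    Blocks are 0-based half-open ``(start, end)`` genomic intervals; ``N``
    closes the current block, ``D`` extends it, ``I``/``S``/``H`` consume no
    reference. ``aligned_query_len`` counts M/=/X/I bases; ``read_len`` adds
    soft and hard clips (so fractions are comparable across aligners that
    hard-clip).
    """
    if pos < 1:
        raise ContractError(f"SAM POS must be >= 1, got {pos}")
    ops = parse_cigar(cigar)
    ref = pos - 1
    block_start = ref
    blocks: List[Tuple[int, int]] = []
    aligned = 0
    clipped = 0
    for length, op in ops:
        if op in ("M", "=", "X"):
            ref += length
            aligned += length
        elif op == "I":
            aligned += length
        elif op == "D":
            ref += length
        elif op == "N":
            if ref > block_start:
                blocks.append((block_start, ref))
            ref += length
            block_start = ref
        elif op in ("S", "H"):
            clipped += length
        # P consumes nothing
    if ref > block_start:
        blocks.append((block_start, ref))
    return blocks, aligned, aligned + clipped


def _merge_blocks(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Sort and union overlapping/adjacent-overlap blocks."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(blocks):
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class ReferenceLookup:
    """Uppercased random access into a genome FASTA via pysam."""

    def __init__(self, fasta_path: str):
        self._fa = pysam.FastaFile(fasta_path)

    def has(self, chrom: str) -> bool:
        return chrom in self._fa.references

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._fa.fetch(chrom, start, end).upper()

    def lengths(self) -> Dict[str, int]:
        return dict(zip(self._fa.references, self._fa.lengths))

    def close(self) -> None:
        self._fa.close()


def _line_match_counts_ref(
    pos: int, cigar: str, seq: str, chrom: str, ref: ReferenceLookup
) -> Tuple[int, int]:
    """(matching, total) aligned M/=/X bases of one SAM line vs the reference."""
    ops = parse_cigar(cigar)
    ref_cursor = pos - 1
    ref_end = ref_cursor + sum(l for l, op in ops if op in _REF_OPS)
    refseq = ref.fetch(chrom, ref_cursor, ref_end)
    qi = 0
    ri = 0
    matches = 0
    total = 0
    for length, op in ops:
        if op in ("M", "=", "X"):
            for k in range(length):
                if seq[qi + k].upper() == refseq[ri + k]:
                    matches += 1
            total += length
            qi += length
            ri += length
        elif op in ("I", "S"):
            qi += length
        elif op in ("D", "N"):
            ri += length
    return matches, total


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def match_counts_from_md(md: str) -> Tuple[int, int]:
    """(matching, total) aligned bases from an MD tag.

    Numbers are runs of matches; bare letters are substituted reference
    bases; ``^``-prefixed runs are deletions (no query base, excluded).
    """
    matches = 0
    mismatches = 0
    for m in _MD_TOKEN.finditer(md):
        if m.group(1) is not None:
            matches += int(m.group(1))
        elif m.group(3) is not None:
            mismatches += 1
    return matches, matches + mismatches


def match_rate(
    lines: Sequence[pysam.AlignedSegment],
    ref: Optional[ReferenceLookup],
) -> Optional[float]:
    """Match rate over the given SAM lines of one read.

    Prefers direct reference comparison; falls back to MD tags when no FASTA
    is supplied (or lacks the chromosome). Returns None when neither route
    is available.
    """
    matches = 0
    total = 0
    for line in lines:
        chrom = line.reference_name
        seq = line.query_sequence
        if ref is not None and ref.has(chrom) and seq is not None:
            m, t = _line_match_counts_ref(
                line.reference_start + 1, line.cigarstring, seq, chrom, ref
            )
        elif line.has_tag("MD"):
            m, t = match_counts_from_md(line.get_tag("MD"))
        else:
            return None
        matches += m
        total += t
    if total == 0:
        return None
    return matches / total


def is_split(record: AlignmentRecord) -> bool:
    """True iff the read is placed on >=2 non-contiguous genomic blocks."""
    return len(record.blocks) >= 2


def assemble_read_alignments(
    sam_path: str, reference: Optional[ReferenceLookup] = None
) -> Tuple[List[AlignmentRecord], int]:
    """Group SAM lines by read and build one AlignmentRecord per read.

    Secondary lines (0x100) are ignored. Supplementary lines (0x800) on the
    primary's chromosome and strand merge into its block list; on a different
    chromosome or strand the record is flagged chimeric and scored on its
    primary blocks. Returns (records, n_input_reads) where n_input_reads
    counts distinct read names including unaligned ones.
    """
    primary: Dict[str, pysam.AlignedSegment] = {}
    supplementary: Dict[str, List[pysam.AlignedSegment]] = {}
    order: List[str] = []
    seen: set = set()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for line in sam:
            qname = line.query_name
            if qname not in seen:
                seen.add(qname)
                order.append(qname)
            if line.is_secondary:
                continue
            if line.is_supplementary:
                supplementary.setdefault(qname, []).append(line)
                continue
            if qname in primary:
                logger.warning("duplicate primary line for read %s; keeping first", qname)
                continue
            primary[qname] = line

    records: List[AlignmentRecord] = []
    for qname in order:
        line = primary.get(qname)
        if line is None or line.is_unmapped:
            records.append(AlignmentRecord(read_id=qname, is_aligned=False))
            continue
        strand = "-" if line.is_reverse else "+"
        chrom = line.reference_name
        blocks, aligned, read_len = blocks_from_cigar(
            line.reference_start + 1, line.cigarstring
        )
        used_lines = [line]
        chimeric = False
        for supp in supplementary.get(qname, []):
            supp_strand = "-" if supp.is_reverse else "+"
            if supp.reference_name == chrom and supp_strand == strand:
                sblocks, saligned, _ = blocks_from_cigar(
                    supp.reference_start + 1, supp.cigarstring
                )
                blocks = _merge_blocks(list(blocks) + sblocks)
                aligned += saligned
                used_lines.append(supp)
            else:
                chimeric = True
        rate = match_rate(used_lines, reference)
        frac = min(1.0, aligned / read_len) if read_len else 0.0
        records.append(
            AlignmentRecord(
                read_id=qname,
                is_aligned=True,
                chrom=chrom,
                strand=strand,
                blocks=tuple(GenomicInterval(chrom, s, e) for s, e in _merge_blocks(blocks)),
                aligned_query_fraction=frac,
                match_rate=rate,
                read_len=read_len,
                is_chimeric=chimeric,
            )
        )
    return records, len(order)
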