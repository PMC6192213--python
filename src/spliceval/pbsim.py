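"""PBSIM-style ground truth: MAF parsing and transcript-to-genome liftover.

PBSIM simulates reads from individual transcript sequences and records each
read's true source interval in a MAF file. To know where a read *should*
align on the genome, that transcript-space interval is lifted through the
transcript's exon chain into a list of genomic blocks (one per exon piece).

Folder convention (one subfolder per transcript, named by transcript_id):

    <dir>/<transcript_id>/<transcript_id>.ref.fa     transcript sequence
    <dir>/<transcript_id>/<transcript_id>.fastq      simulated reads
    <dir>/<transcript_id>/<transcript_id>.maf        read-origin alignments
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Tuple

import pysam

from .annotation import TranscriptModel
from .intervals import ContractError, GenomicInterval, ParseError


@dataclass(frozen=True)
class MafOrigin:
    """One simulated read's source interval in transcript coordinates.

    ``src_start`` is on the transcript's forward (5'->3') orientation;
    ``src_strand`` is the read's strand relative to the transcript.
    """

    read_id: str
    source_name: str
    src_start: int
    src_size: int
    src_strand: str

    def __post_init__(self) -> None:
        if self.src_start < 0 or self.src_size < 1:
            raise ContractError(
                f"read {self.read_id}: bad MAF interval "
                f"start={self.src_start} size={self.src_size}"
            )
        if self.src_strand not in ("+", "-"):
            raise ContractError(f"read {self.read_id}: bad strand {self.src_strand!r}")


@dataclass(frozen=True)
class ReadOrigin:
    """A read's true genomic origin: an exon-block chain on the genome."""

    read_id: str
    transcript_id: str
    chrom: str
    genomic_strand: str
    origin_blocks: Tuple[GenomicInterval, ...]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.origin_blocks[0].start, self.origin_blocks[-1].end
        )


def _parse_s_line(fields: List[str], path: str, lineno: int):
    # s name start size strand srcSize text
    if len(fields) < 7:
        raise ParseError(f"{path}:{lineno}: MAF s-line with {len(fields)} fields")
    name = fields[1]
    try:
        start, size, src_size = int(fields[2]), int(fields[3]), int(fields[5])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer MAF coordinate") from exc
    strand = fields[4]
    if strand not in ("+", "-"):
        raise ParseError(f"{path}:{lineno}: bad MAF strand {strand!r}")
    return name, start, size, strand, src_size


def parse_maf(path: str) -> List[MafOrigin]:
    """Parse a PBSIM-dialect MAF: per ``a`` block, the first ``s`` line is
    the source transcript, the second the read.

    MAF starts are relative to the 5' end of the stated strand; minus-strand
    source coordinates are converted to forward-strand coordinates here.
    """
    origins: List[MafOrigin] = []
    pending: List[Tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "a":
                pending = []
                continue
            if tok[0] != "s":
                continue
            pending.append(_parse_s_line(tok, path, lineno))
            if len(pending) == 2:
                (src_name, s_start, s_size, s_strand, s_total) = pending[0]
                (read_name, _, _, r_strand, _) = pending[1]
                fwd_start = s_start if s_strand == "+" else s_total - s_start - s_size
                rel_strand = "+" if s_strand == r_strand else "-"
                origins.append(
                    MafOrigin(
                        read_id=read_name,
                        source_name=src_name,
                        src_start=fwd_start,
                        src_size=s_size,
                        src_strand=rel_strand,
                    )
                )
                pending = []
    return origins


def parse_pbsim_folder(path: str) -> List[MafOrigin]:
    """Collect MafOrigins from every transcript subfolder under ``path``.

    A subfolder holding a FASTQ without a matching MAF, or a FASTQ read
    missing from the MAF, is an error: ground truth would be incomplete.
    """
    if not os.path.isdir(path):
        raise ParseError(f"PBSIM folder {path} does not exist")
    origins: List[MafOrigin] = []
    for entry in sorted(os.listdir(path)):
        sub = os.path.join(path, entry)
        if not os.path.isdir(sub):
            continue
        maf_path = os.path.join(sub, f"{entry}.maf")
        fastq_path = os.path.join(sub, f"{entry}.fastq")
        if not os.path.exists(maf_path):
            if os.path.exists(fastq_path):
                raise ParseError(f"transcript {entry}: FASTQ present but no MAF file")
            continue
        folder_origins = parse_maf(maf_path)
        maf_ids = {o.read_id for o in folder_origins}
        if os.path.exists(fastq_path):
            with pysam.FastxFile(fastq_path) as fq:
                for rec in fq:
                    if rec.name not in maf_ids:
                        raise ParseError(
                            f"transcript {entry}: read {rec.name} in FASTQ "
                            "but absent from MAF"
                        )
        origins.extend(folder_origins)
    return origins


def lift_interval(
    t: TranscriptModel, start: int, size: int
) -> List[GenomicInterval]:
    """Lift transcript-space ``[start, start+size)`` to genomic blocks.

    Transcript coordinate 0 is the genomically first exon base on '+'
    transcripts and the genomically last exon base on '-' transcripts; the
    returned blocks are always in genomic order.
    """
    if start < 0 or size < 1 or start + size > t.spliced_length:
        raise ContractError(
            f"interval [{start},{start + size}) outside transcript "
            f"{t.transcript_id} of spliced length {t.spliced_length}"
        )
    # offset from the genomically first spliced base
    offset = start if t.strand == "+" else t.spliced_length - (start + size)
    blocks: List[GenomicInterval] = []
    skip = offset
    remaining = size
    for exon in t.exons:
        elen = len(exon)
        if skip >= elen:
            skip -= elen
            continue
        s = exon.start + skip
        take = min(elen - skip, remaining)
        blocks.append(GenomicInterval(t.chrom, s, s + take))
        remaining -= take
        skip = 0
        if remaining == 0:
            break
    return blocks


def lift_origin(m: MafOrigin, t: TranscriptModel) -> ReadOrigin:
    """Map a MAF source interval through ``t``'s exon chain.

    The read's genomic strand composes the transcript's genomic strand with
    the read-vs-transcript strand (equal -> '+', different -> '-').
    """
    if m.source_name != t.transcript_id:
        raise ContractError(
            f"read {m.read_id}: MAF source {m.source_name} does not match "
            f"transcript {t.transcript_id}"
        )
    blocks = lift_interval(t, m.src_start, m.src_size)
    genomic_strand = "+" if t.strand == m.src_strand else "-"
    return ReadOrigin(
        read_id=m.read_id,
        transcript_id=t.transcript_id,
        chrom=t.chrom,
        genomic_strand=genomic_strand,
        origin_blocks=tuple(blocks),
    )


def lift_origins(
    origins: List[MafOrigin], transcripts: Dict[str, TranscriptModel]
) -> Dict[str, ReadOrigin]:
    """Lift every MafOrigin; unknown transcript names are an error."""
    out: Dict[str, ReadOrigin] = {}
    for m in origins:
        t = transcripts.get(m.source_name)
        if t is None:
            raise ParseError(
                f"MAF source transcript {m.source_name} absent from annotation"
            )
        out[m.read_id] = lift_origin(m, t)
    return out
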