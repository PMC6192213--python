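"""Synthetic long-read RNA-seq fixture generator.

Emulates the PBSIM-on-transcripts simulation design used to benchmark
splice-aware aligners: a random genome with non-overlapping multi-exon
genes, expression-weighted transcript selection, reads drawn as contiguous
transcript-space substrings corrupted by per-base substitution / insertion
/ deletion draws, a PBSIM-style per-transcript folder with MAF ground
truth, and a truth SAM that places each read at its exact genomic origin
with an N-gapped CIGAR reconstructing every simulated error (plus NM/MD
tags so match rate can be recomputed without the genome FASTA).

Everything is driven by a single integer seed: the same config and seed
produce byte-identical FASTA/GTF/FASTQ/MAF/SAM output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .annotation import GeneModel, TranscriptModel, write_gtf
from .intervals import ContractError, GenomicInterval
from .pbsim import lift_interval

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates and a read-length model.

    Rates are independent per-base probabilities of a substitution (to a
    uniformly random different base), a single-base insertion after the
    position, or a deletion of the base. ``read_length_model`` is
    (mean bp, sd bp, min bp) for a normal draw clamped below at min and
    above at the transcript's spliced length.
    """

    name: str = "custom"
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    read_length_model: Tuple[float, float, int] = (500.0, 150.0, 50)

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 0.5:
                raise ContractError(f"profile {self.name}: rate {r} outside [0,0.5)")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1.0:
            raise ContractError(f"profile {self.name}: rates sum to >= 1")


#: Presets loosely matching PacBio reads-of-insert (~2-3% error) and ONT 2D
#: (~12-20% error) regimes; simulation studies set these from real data.
PROFILES: Dict[str, ErrorProfile] = {
    "error-free": ErrorProfile(name="error-free"),
    "pacbio-roi-like": ErrorProfile(
        name="pacbio-roi-like", sub_rate=0.01, ins_rate=0.01, del_rate=0.01,
        read_length_model=(1500.0, 500.0, 100),
    ),
    "ont-2d-like": ErrorProfile(
        name="ont-2d-like", sub_rate=0.05, ins_rate=0.04, del_rate=0.06,
        read_length_model=(2000.0, 800.0, 100),
    ),
}


@dataclass(frozen=True)
class SimConfig:
    """Fixture geometry and sampling design.

    Defaults give a small but structurally complete dataset: multi-exon
    genes on both strands, skewed expression weights, a few thousand reads.
    """

    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (1, 5)
    exon_length: Tuple[int, int] = (50, 300)
    intron_length: Tuple[int, int] = (50, 500)
    intergenic_length: Tuple[int, int] = (200, 1000)
    pct_minus_genes: float = 0.5
    expression_weights: Optional[Tuple[float, ...]] = None
    n_reads: int = 2000
    seed: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_reads < 1:
            raise ContractError("n_genes and n_reads must be >= 1")
        for lo, hi in (self.exons_per_gene, self.exon_length,
                       self.intron_length, self.intergenic_length):
            if lo < 1 or hi < lo:
                raise ContractError(f"bad range ({lo},{hi})")
        if not 0.0 <= self.pct_minus_genes <= 1.0:
            raise ContractError("pct_minus_genes outside [0,1]")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def generate_genome_and_annotation(
    cfg: SimConfig,
) -> Tuple[Dict[str, str], List[GeneModel]]:
    """Build a random genome and non-overlapping single-transcript genes."""
    rng = np.random.default_rng(cfg.seed)
    genes: List[GeneModel] = []
    cursor = int(rng.integers(cfg.intergenic_length[0], cfg.intergenic_length[1] + 1))
    for i in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons: List[GenomicInterval] = []
        p = cursor
        for j in range(n_exons):
            if j > 0:
                p += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            elen = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append(GenomicInterval(cfg.chrom_name, p, p + elen))
            p = exons[-1].end
        strand = "-" if rng.random() < cfg.pct_minus_genes else "+"
        gid = f"G{i + 1:04d}"
        tid = f"T{i + 1:04d}"
        t = TranscriptModel(transcript_id=tid, gene_id=gid, chrom=cfg.chrom_name,
                            strand=strand, exons=tuple(exons))
        genes.append(GeneModel(gene_id=gid, chrom=cfg.chrom_name, strand=strand,
                               transcripts=(t,)))
        cursor = p + int(
            rng.integers(cfg.intergenic_length[0], cfg.intergenic_length[1] + 1)
        )
    genome_len = cursor
    genome = {cfg.chrom_name: _random_seq(rng, genome_len)}
    return genome, genes


def spliced_sequence(t: TranscriptModel, genome: Dict[str, str]) -> str:
    """Transcript 5'->3' sequence: exon concatenation, revcomp on '-'."""
    seq = "".join(genome[t.chrom][ex.start:ex.end] for ex in t.exons)
    return revcomp(seq) if t.strand == "-" else seq.upper()


@dataclass
class SimulatedRead:
    """Book-keeping for one simulated read (returned for in-memory checks)."""

    read_id: str
    transcript_id: str
    gene_id: str
    src_start: int          # transcript-space, forward orientation
    src_size: int
    src_strand: str         # read vs transcript
    genomic_strand: str     # composed with transcript strand
    chrom: str
    pos: int                # 1-based SAM POS of the truth alignment
    cigar: str
    md: str
    nm: int
    sam_seq: str            # genome-forward corrupted sequence
    fastq_seq: str          # read's own 5'->3' sequence
    n_sub: int
    n_ins: int
    n_del: int

    @property
    def is_spliced(self) -> bool:
        return "N" in _split_ops(self.cigar)


def _split_ops(cigar: str) -> str:
    return "".join(ch for ch in cigar if ch.isalpha())


def _corrupt_blocks(
    rng: np.random.Generator,
    genome_seq: str,
    blocks: Sequence[GenomicInterval],
    profile: ErrorProfile,
) -> Tuple[str, str, str, int, int, int, str, str]:
    """Corrupt the genomic sequence of ``blocks`` left to right.

    Returns (cigar, md, sam_seq, n_sub, n_ins, n_del, gapped_ref,
    gapped_read). The CIGAR includes N operations for the gaps between
    consecutive blocks; MD covers matches/mismatches/deletions per the SAM
    tag convention (N gaps do not appear in MD).
    """
    ops: List[Tuple[str, int]] = []
    md_parts: List[str] = []
    md_run = 0
    read_chars: List[str] = []
    gapped_ref: List[str] = []
    gapped_read: List[str] = []
    n_sub = n_ins = n_del = 0
    p_sub, p_ins, p_del = profile.sub_rate, profile.ins_rate, profile.del_rate

    def push(op: str, length: int = 1) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    last_deleted = False
    for bi, block in enumerate(blocks):
        if bi > 0:
            gap = block.start - blocks[bi - 1].end
            push("N", gap)
        for gpos in range(block.start, block.end):
            base = genome_seq[gpos].upper()
            u = rng.random()
            if u < p_sub:
                alt = _BASES[int(rng.integers(4))].decode()
                while alt == base:
                    alt = _BASES[int(rng.integers(4))].decode()
                push("M")
                read_chars.append(alt)
                gapped_ref.append(base)
                gapped_read.append(alt)
                md_parts.append(str(md_run)); md_parts.append(base)
                md_run = 0
                n_sub += 1
                last_deleted = False
            elif u < p_sub + p_ins:
                ins = _BASES[int(rng.integers(4))].decode()
                push("M")
                read_chars.append(base)
                gapped_ref.append(base)
                gapped_read.append(base)
                md_run += 1
                push("I")
                read_chars.append(ins)
                gapped_ref.append("-")
                gapped_read.append(ins)
                n_ins += 1
                last_deleted = False
            elif u < p_sub + p_ins + p_del:
                push("D")
                gapped_ref.append(base)
                gapped_read.append("-")
                if last_deleted:
                    md_parts.append(base)
                else:
                    md_parts.append(str(md_run)); md_parts.append("^" + base)
                    md_run = 0
                n_del += 1
                last_deleted = True
                continue
            else:
                push("M")
                read_chars.append(base)
                gapped_ref.append(base)
                gapped_read.append(base)
                md_run += 1
                last_deleted = False
    md_parts.append(str(md_run))
    cigar = "".join(f"{l}{op}" for op, l in ops)
    return (
        cigar,
        "".join(md_parts),
        "".join(read_chars),
        n_sub,
        n_ins,
        n_del,
        "".join(gapped_ref),
        "".join(gapped_read),
    )


def simulate_reads(
    cfg: SimConfig,
    profile: ErrorProfile,
    genes: Sequence[GeneModel],
    genome: Dict[str, str],
) -> List[SimulatedRead]:
    """Draw reads from transcripts with expression weights and corrupt them.

    Transcript selection uses ``cfg.expression_weights`` (normalized) or, by
    default, weights drawn once from an exponential distribution to mimic
    skewed expression. Reads are antisense to their transcript with
    probability 0.5, as a strand-symmetric simulator produces.
    """
    transcripts = [t for g in genes for t in g.transcripts]
    if not transcripts:
        raise ContractError("no transcripts to simulate from")
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.expression_weights is not None:
        if len(cfg.expression_weights) != len(transcripts):
            raise ContractError(
                f"{len(cfg.expression_weights)} weights for "
                f"{len(transcripts)} transcripts"
            )
        w = np.asarray(cfg.expression_weights, dtype=float)
    else:
        w = rng.exponential(size=len(transcripts))
    w = w / w.sum()
    mean_len, sd_len, min_len = profile.read_length_model

    reads: List[SimulatedRead] = []
    counters: Dict[str, int] = {}
    tx_index = rng.choice(len(transcripts), size=cfg.n_reads, p=w)
    for i in range(cfg.n_reads):
        t = transcripts[int(tx_index[i])]
        sp_len = t.spliced_length
        L = int(np.clip(round(rng.normal(mean_len, sd_len)), min_len, sp_len))
        L = max(1, L)
        s = int(rng.integers(0, sp_len - L + 1))
        src_strand = "+" if rng.random() < 0.5 else "-"
        blocks = lift_interval(t, s, L)
        cigar, md, sam_seq, n_sub, n_ins, n_del, gref, gread = _corrupt_blocks(
            rng, genome[t.chrom], blocks, profile
        )
        genomic_strand = "+" if t.strand == src_strand else "-"
        fastq_seq = sam_seq if genomic_strand == "+" else revcomp(sam_seq)
        n = counters.get(t.transcript_id, 0) + 1
        counters[t.transcript_id] = n
        reads.append(
            SimulatedRead(
                read_id=f"{t.transcript_id}_{n:06d}",
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                src_start=s,
                src_size=L,
                src_strand=src_strand,
                genomic_strand=genomic_strand,
                chrom=t.chrom,
                pos=blocks[0].start + 1,
                cigar=cigar,
                md=md,
                nm=n_sub + n_ins + n_del,
                sam_seq=sam_seq,
                fastq_seq=fastq_seq,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
            )
        )
    return reads


def _write_fasta(path: str, records: Sequence[Tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_sam(
    path: str, reads: Sequence[SimulatedRead], genome: Dict[str, str]
) -> None:
    """Emit the ground-truth alignment of every read (SAM text, MD/NM tags)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        tid_of = {name: i for i, name in enumerate(genome)}
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.genomic_strand == "-" else 0
            seg.reference_id = tid_of[r.chrom]
            seg.reference_start = r.pos - 1
            seg.mapping_quality = 60
            seg.cigarstring = r.cigar
            seg.query_sequence = r.sam_seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.sam_seq))
            seg.set_tag("NM", r.nm)
            seg.set_tag("MD", r.md)
            out.write(seg)


def write_pbsim_folder(
    out_dir: str,
    reads: Sequence[SimulatedRead],
    genes: Sequence[GeneModel],
    genome: Dict[str, str],
) -> None:
    """Write per-transcript subfolders: <id>.ref.fa, <id>.fastq, <id>.maf."""
    by_tx: Dict[str, List[SimulatedRead]] = {}
    for r in reads:
        by_tx.setdefault(r.transcript_id, []).append(r)
    tx_lookup = {t.transcript_id: t for g in genes for t in g.transcripts}
    os.makedirs(out_dir, exist_ok=True)
    for tid in sorted(by_tx):
        t = tx_lookup[tid]
        sub = os.path.join(out_dir, tid)
        os.makedirs(sub, exist_ok=True)
        tseq = spliced_sequence(t, genome)
        _write_fasta(os.path.join(sub, f"{tid}.ref.fa"), [(tid, tseq)])
        with open(os.path.join(sub, f"{tid}.fastq"), "w") as fq, \
                open(os.path.join(sub, f"{tid}.maf"), "w") as maf:
            for r in by_tx[tid]:
                fq.write(f"@{r.read_id}\n{r.fastq_seq}\n+\n{'I' * len(r.fastq_seq)}\n")
                # alignment text oriented transcript-forward; source line '+'
                gref, gread = _maf_texts(r, t, genome)
                rl = len(r.fastq_seq)
                maf.write("a\n")
                maf.write(
                    f"s {tid} {r.src_start} {r.src_size} + {t.spliced_length} {gref}\n"
                )
                maf.write(f"s {r.read_id} 0 {rl} {r.src_strand} {rl} {gread}\n\n")


def _maf_texts(r: SimulatedRead, t: TranscriptModel, genome: Dict[str, str]):
    """Reconstruct gapped MAF alignment texts in transcript orientation."""
    # rebuild gapped pair by walking the truth CIGAR over the genome
    from .alignment import parse_cigar

    gref: List[str] = []
    gread: List[str] = []
    gpos = r.pos - 1
    qi = 0
    seq = genome[r.chrom]
    for length, op in parse_cigar(r.cigar):
        if op == "M":
            for k in range(length):
                gref.append(seq[gpos + k].upper())
                gread.append(r.sam_seq[qi + k])
            gpos += length
            qi += length
        elif op == "I":
            for k in range(length):
                gref.append("-")
                gread.append(r.sam_seq[qi + k])
            qi += length
        elif op == "D":
            for k in range(length):
                gref.append(seq[gpos + k].upper())
                gread.append("-")
            gpos += length
        elif op == "N":
            gpos += length
    ref_txt = "".join(gref)
    read_txt = "".join(gread)
    if t.strand == "-":
        ref_txt = _revcomp_gapped(ref_txt)
        read_txt = _revcomp_gapped(read_txt)
    return ref_txt, read_txt


def _revcomp_gapped(txt: str) -> str:
    return "".join("-" if c == "-" else _COMP[c] for c in reversed(txt))


def simulate_dataset(
    cfg: SimConfig, profile: ErrorProfile, out_dir: str
) -> Tuple[List[GeneModel], List[SimulatedRead]]:
    """Full fixture: genome.fa, genes.gtf, reads/ (PBSIM layout), truth.sam,
    reads.fastq (all reads combined, aligner-ready)."""
    os.makedirs(out_dir, exist_ok=True)
    genome, genes = generate_genome_and_annotation(cfg)
    reads = simulate_reads(cfg, profile, genes, genome)
    _write_fasta(os.path.join(out_dir, "genome.fa"), sorted(genome.items()))
    write_gtf(genes, os.path.join(out_dir, "genes.gtf"))
    write_pbsim_folder(os.path.join(out_dir, "reads"), reads, genes, genome)
    write_truth_sam(os.path.join(out_dir, "truth.sam"), reads, genome)
    with open(os.path.join(out_dir, "reads.fastq"), "w") as fq:
        for r in reads:
            fq.write(f"@{r.read_id}\n{r.fastq_seq}\n+\n{'I' * len(r.fastq_seq)}\n")
    return genes, reads


def perturb_truth_sam(in_sam: str, out_sam: str, shift: int) -> int:
    """Shift every alignment's POS by ``shift`` bp, CIGAR unchanged.

    Records pushed outside chromosome bounds are dropped with a warning.
    Returns the number of records written. Used to probe the boundary
    tolerance of the simulated-mode evaluator.
    """
    import logging

    logger = logging.getLogger(__name__)
    n = 0
    with pysam.AlignmentFile(in_sam, "r", check_sq=False) as src:
        lengths = dict(zip(src.references, src.lengths))
        with pysam.AlignmentFile(out_sam, "w", template=src) as out:
            for seg in src:
                if seg.is_unmapped:
                    out.write(seg)
                    n += 1
                    continue
                new_start = seg.reference_start + shift
                ref_span = seg.reference_length or 0
                if new_start < 0 or new_start + ref_span > lengths[seg.reference_name]:
                    logger.warning(
                        "read %s shifted outside %s; dropped",
                        seg.query_name, seg.reference_name,
                    )
                    continue
                seg.reference_start = new_start
                out.write(seg)
                n += 1
    return n
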