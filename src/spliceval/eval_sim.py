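"""Scoring of alignments against known simulated read origins.

Per read, the aligner's placement is compared with the lifted genomic
origin. The flags form a strict chain:

* **correct** — same chromosome, same number of blocks, and every block
  boundary (start and end, matched in order) within ``tol`` bp of the
  corresponding origin boundary. 5 bp of slack is tolerated at every
  boundary by default.
* **hit_all** — same chromosome and every origin block overlapped by at
  least ``min_overlap`` bp by some alignment block (an origin block shorter
  than the threshold counts as hit when fully covered).
* **hit_one** — same chromosome and at least one origin block overlapped
  by at least ``min_overlap`` bp.

Dataset percentages are all relative to the number of reads in the input,
matching how aligner benchmarks usually report them; split-read
sub-statistics restrict the numerator to spliced/chimeric placements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .alignment import AlignmentRecord, is_split
from .intervals import ContractError
from .pbsim import ReadOrigin

DEFAULT_TOL = 5
DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class ReadEvaluation:
    read_id: str
    aligned: bool
    chrom_ok: bool = False
    strand_ok: bool = False
    correct: bool = False
    hit_all: bool = False
    hit_one: bool = False
    is_split: bool = False
    match_rate: Optional[float] = None
    aligned_query_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.hit_all and not self.hit_one:
            raise ContractError(f"read {self.read_id}: hit_all without hit_one")
        if self.hit_one and not (self.aligned and self.chrom_ok):
            raise ContractError(f"read {self.read_id}: hit_one without aligned chrom")
        if not self.aligned and (self.chrom_ok or self.strand_ok or self.hit_one):
            raise ContractError(f"read {self.read_id}: flags set on unaligned read")


@dataclass(frozen=True)
class EvalSummary:
    """Dataset-level counters; percentages are of ``n_input_reads``."""

    n_input_reads: int
    n_aligned: int
    n_correct: int
    n_hit_all: int
    n_hit_one: int
    n_split: int
    n_correct_split: int
    n_split_hit_all: int
    n_split_hit_one: int
    n_strand_ok: int
    mean_match_rate: Optional[float]  # percentage over aligned reads, or None

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_input_reads

    @property
    def pct_aligned(self) -> float:
        return self._pct(self.n_aligned)

    @property
    def pct_correct(self) -> float:
        return self._pct(self.n_correct)

    @property
    def pct_hit_all(self) -> float:
        return self._pct(self.n_hit_all)

    @property
    def pct_hit_one(self) -> float:
        return self._pct(self.n_hit_one)

    @property
    def pct_split(self) -> float:
        return self._pct(self.n_split)

    @property
    def pct_correct_split(self) -> float:
        return self._pct(self.n_correct_split)

    @property
    def pct_split_hit_all(self) -> float:
        return self._pct(self.n_split_hit_all)

    @property
    def pct_split_hit_one(self) -> float:
        return self._pct(self.n_split_hit_one)

    @property
    def pct_strand_ok(self) -> float:
        return self._pct(self.n_strand_ok)


def _boundaries_within(a_blocks, o_blocks, tol: int) -> bool:
    if len(a_blocks) != len(o_blocks):
        return False
    for ab, ob in zip(a_blocks, o_blocks):
        if abs(ab.start - ob.start) > tol or abs(ab.end - ob.end) > tol:
            return False
    return True


def compare_read(
    a: AlignmentRecord,
    o: ReadOrigin,
    tol: int = DEFAULT_TOL,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ReadEvaluation:
    """Score one read's alignment against its genomic origin.

    Tolerances are inclusive: a boundary exactly ``tol`` bp off still counts
    as correct, and an overlap of exactly ``min_overlap`` bp counts as a hit.
    """
    if a.read_id != o.read_id:
        raise ContractError(f"read id mismatch: {a.read_id} vs {o.read_id}")
    if not a.is_aligned:
        return ReadEvaluation(read_id=a.read_id, aligned=False)
    chrom_ok = a.chrom == o.chrom
    strand_ok = chrom_ok and a.strand == o.genomic_strand
    hit_one = False
    hit_all = False
    correct = False
    if chrom_ok:
        covered = []
        for ob in o.origin_blocks:
            best = max((ob.overlap_length(ab) for ab in a.blocks), default=0)
            # an origin exon piece shorter than the threshold is hit when
            # fully covered; otherwise the threshold would be unsatisfiable
            covered.append(best >= min(min_overlap, len(ob)))
        hit_one = any(covered)
        hit_all = all(covered)
        correct = _boundaries_within(a.blocks, o.origin_blocks, tol)
    return ReadEvaluation(
        read_id=a.read_id,
        aligned=True,
        chrom_ok=chrom_ok,
        strand_ok=strand_ok,
        correct=correct,
        hit_all=hit_all,
        hit_one=hit_one,
        is_split=is_split(a),
        match_rate=a.match_rate,
        aligned_query_fraction=a.aligned_query_fraction,
    )


def summarize(evals: Sequence[ReadEvaluation], n_input_reads: int) -> EvalSummary:
    """Aggregate per-read flags into dataset counters and percentages."""
    if n_input_reads <= 0:
        raise ContractError("n_input_reads must be positive")
    if n_input_reads < len(evals):
        raise ContractError(
            f"n_input_reads={n_input_reads} smaller than number of "
            f"evaluated reads {len(evals)}"
        )
    rates = [e.match_rate for e in evals if e.aligned and e.match_rate is not None]
    mean_rate = 100.0 * sum(rates) / len(rates) if rates else None
    return EvalSummary(
        n_input_reads=n_input_reads,
        n_aligned=sum(e.aligned for e in evals),
        n_correct=sum(e.correct for e in evals),
        n_hit_all=sum(e.hit_all for e in evals),
        n_hit_one=sum(e.hit_one for e in evals),
        n_split=sum(e.is_split for e in evals),
        n_correct_split=sum(e.correct and e.is_split for e in evals),
        n_split_hit_all=sum(e.hit_all and e.is_split for e in evals),
        n_split_hit_one=sum(e.hit_one and e.is_split for e in evals),
        n_strand_ok=sum(e.strand_ok for e in evals),
        mean_match_rate=mean_rate,
    )


def evaluate_simulated(
    sam_path: str,
    annotation_path: str,
    pbsim_dir: str,
    reference_path: Optional[str] = None,
    tol: int = DEFAULT_TOL,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[List[ReadEvaluation], EvalSummary]:
    """Full simulated-mode pipeline: SAM + annotation + PBSIM truth -> metrics."""
    from .alignment import ReferenceLookup, assemble_read_alignments
    from .annotation import GeneIndex, parse_annotation
    from .pbsim import lift_origins, parse_pbsim_folder

    genes = parse_annotation(annotation_path)
    transcripts = GeneIndex(genes).transcript_lookup()
    origins = lift_origins(parse_pbsim_folder(pbsim_dir), transcripts)
    ref = ReferenceLookup(reference_path) if reference_path else None
    try:
        records, n_input = assemble_read_alignments(sam_path, ref)
    finally:
        if ref is not None:
            ref.close()
    evals: List[ReadEvaluation] = []
    for rec in records:
        origin = origins.get(rec.read_id)
        if origin is None:
            raise ContractError(
                f"read {rec.read_id} in SAM has no ground-truth origin"
            )
        evals.append(compare_read(rec, origin, tol=tol, min_overlap=min_overlap))
    return evals, summarize(evals, n_input)
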