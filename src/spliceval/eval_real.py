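"""Scoring of alignments against gene annotations alone (origin unknown).

When reads come from a real sample there is no per-read truth, so each
alignment is judged by how well it matches annotated gene structure:

* **exon_hit** — some alignment block overlaps some exon of an overlapping
  gene by at least ``min_overlap`` bp.
* **contiguous** — the alignment blocks, in genomic order, can be paired
  one-to-one (each overlap >= ``min_overlap`` bp) with a run of consecutive
  exons of a single annotated transcript. This is the annotation-concordant
  spliced-alignment pattern: block k on exon i+k for some window start i.
* **best_gene** — the overlapping gene with the largest total exonic
  overlap; expressed-gene counting attributes each read to its best gene so
  reads spanning overlapping genes are not double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .alignment import AlignmentRecord
from .annotation import GeneIndex, GeneModel, TranscriptModel
from .intervals import ContractError, GenomicInterval

DEFAULT_MIN_OVERLAP = 5


@dataclass(frozen=True)
class RealReadEvaluation:
    read_id: str
    aligned: bool
    exon_hit: bool = False
    contiguous: bool = False
    best_gene: Optional[str] = None
    aligned_query_fraction: float = 0.0
    match_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.contiguous and not self.exon_hit:
            raise ContractError(f"read {self.read_id}: contiguous without exon_hit")
        if self.exon_hit and not self.aligned:
            raise ContractError(f"read {self.read_id}: exon_hit on unaligned read")


@dataclass(frozen=True)
class RealEvalSummary:
    n_input_reads: int
    n_aligned: int
    n_exon_hit: int
    n_contiguous: int
    n_expressed_genes: int
    mean_match_rate: Optional[float]  # percentage over aligned reads, or None

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_input_reads

    @property
    def pct_aligned(self) -> float:
        return self._pct(self.n_aligned)

    @property
    def pct_exon_hit(self) -> float:
        return self._pct(self.n_exon_hit)

    @property
    def pct_contiguous(self) -> float:
        return self._pct(self.n_contiguous)


def _merged_exons(gene: GeneModel) -> List[GenomicInterval]:
    """Union of the gene's exons across transcripts (for overlap totals)."""
    ivs = sorted(
        (ex.start, ex.end) for t in gene.transcripts for ex in t.exons
    )
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [GenomicInterval(gene.chrom, s, e) for s, e in merged]


def _is_contiguous_on(
    blocks: Sequence[GenomicInterval], t: TranscriptModel, min_overlap: int
) -> bool:
    k = len(blocks)
    exons = t.exons
    if k > len(exons):
        return False
    for i in range(len(exons) - k + 1):
        if all(
            blocks[j].overlap_length(exons[i + j]) >= min_overlap for j in range(k)
        ):
            return True
    return False


def evaluate_real_read(
    a: AlignmentRecord,
    index: GeneIndex,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> RealReadEvaluation:
    """Judge one alignment against the annotation (no per-read truth)."""
    if not a.is_aligned or not a.blocks:
        return RealReadEvaluation(read_id=a.read_id, aligned=a.is_aligned,
                                  aligned_query_fraction=a.aligned_query_fraction,
                                  match_rate=a.match_rate)
    candidates = index.find_overlapping_genes(a.span)
    exon_hit = False
    contiguous = False
    best_gene: Optional[str] = None
    best_overlap = 0
    for gene in candidates:
        gene_exons = _merged_exons(gene)
        total = sum(
            b.overlap_length(ex) for b in a.blocks for ex in gene_exons
        )
        hit = any(
            b.overlap_length(ex) >= min_overlap
            for b in a.blocks
            for ex in gene_exons
        )
        if hit:
            exon_hit = True
        if total > best_overlap or (
            total == best_overlap and total > 0 and (best_gene is None or gene.gene_id < best_gene)
        ):
            best_overlap = total
            best_gene = gene.gene_id
        if not contiguous:
            contiguous = any(
                _is_contiguous_on(a.blocks, t, min_overlap) for t in gene.transcripts
            )
    return RealReadEvaluation(
        read_id=a.read_id,
        aligned=True,
        exon_hit=exon_hit,
        contiguous=contiguous and exon_hit,
        best_gene=best_gene,
        aligned_query_fraction=a.aligned_query_fraction,
        match_rate=a.match_rate,
    )


def summarize_real(
    evals: Sequence[RealReadEvaluation], n_input_reads: int
) -> RealEvalSummary:
    """Aggregate real-mode flags; expressed genes are distinct best genes of
    exon-hit reads."""
    if n_input_reads <= 0:
        raise ContractError("n_input_reads must be positive")
    if n_input_reads < len(evals):
        raise ContractError(
            f"n_input_reads={n_input_reads} smaller than number of "
            f"evaluated reads {len(evals)}"
        )
    rates = [e.match_rate for e in evals if e.aligned and e.match_rate is not None]
    mean_rate = 100.0 * sum(rates) / len(rates) if rates else None
    expressed = {e.best_gene for e in evals if e.exon_hit and e.best_gene}
    return RealEvalSummary(
        n_input_reads=n_input_reads,
        n_aligned=sum(e.aligned for e in evals),
        n_exon_hit=sum(e.exon_hit for e in evals),
        n_contiguous=sum(e.contiguous for e in evals),
        n_expressed_genes=len(expressed),
        mean_match_rate=mean_rate,
    )


def evaluate_real(
    sam_path: str,
    annotation_path: str,
    reference_path: Optional[str] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[List[RealReadEvaluation], RealEvalSummary]:
    """Full real-mode pipeline: SAM + annotation (+ genome FASTA) -> metrics."""
    from .alignment import ReferenceLookup, assemble_read_alignments
    from .annotation import parse_annotation

    genes = parse_annotation(annotation_path)
    index = GeneIndex(genes)
    ref = ReferenceLookup(reference_path) if reference_path else None
    try:
        records, n_input = assemble_read_alignments(sam_path, ref)
    finally:
        if ref is not None:
            ref.close()
    evals = [evaluate_real_read(r, index, min_overlap=min_overlap) for r in records]
    return evals, summarize_real(evals, n_input)
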