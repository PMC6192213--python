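"""Gene annotation model: GTF/BED12 parsing and interval queries.

Transcripts are kept as ordered exon chains on a genome; genes group
transcripts and carry a covering span used for fast overlap queries.
GTF coordinates (1-based inclusive) and BED12 coordinates (0-based
half-open) are both normalized to the package-wide 0-based half-open
convention at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .intervals import ContractError, GenomicInterval, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated isoform: an ordered, non-overlapping exon chain.

    ``exons`` are sorted ascending by genomic start regardless of strand;
    transcript (spliced) coordinate 0 is the genomically first base on '+'
    transcripts and the genomically last base on '-' transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ContractError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ContractError(f"transcript {self.transcript_id}: no exons")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ContractError(
                    f"transcript {self.transcript_id}: exon on {ex.chrom}, expected {self.chrom}"
                )
            if ex.start < prev_end:
                raise ContractError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing a gene_id and chromosome."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Tuple[TranscriptModel, ...]

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end)


def _group_into_genes(transcripts: Iterable[TranscriptModel]) -> List[GeneModel]:
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = []
    for gid in sorted(by_gene):
        ts = sorted(by_gene[gid], key=lambda t: (t.exons[0].start, t.transcript_id))
        genes.append(GeneModel(gene_id=gid, chrom=ts[0].chrom, strand=ts[0].strand,
                               transcripts=tuple(ts)))
    return genes


def parse_gtf(path: str) -> List[GeneModel]:
    """Parse a GTF file (Ensembl/UCSC attribute dialects) into GeneModels.

    Only ``exon`` features are used; each distinct transcript_id becomes one
    TranscriptModel. 1-based inclusive coordinates are converted to 0-based
    half-open. A transcript feature with no exon lines is skipped with a
    warning; a malformed line raises :class:`ParseError` naming the line.
    """
    exons_by_tx: Dict[str, List[Tuple[str, str, int, int]]] = {}
    tx_gene: Dict[str, str] = {}
    declared_tx: Dict[str, Tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 GTF columns, found {len(cols)}"
                )
            try:
                int(cols[3]), int(cols[4])
                feat = feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            ftype = feat.featuretype
            if ftype not in ("exon", "transcript"):
                continue
            attrs = feat.attributes
            tx_ids = attrs.get("transcript_id", [])
            if not tx_ids:
                raise ParseError(f"{path}:{lineno}: {ftype} feature lacks transcript_id")
            tx_id = tx_ids[0]
            gene_id = attrs.get("gene_id", [tx_id])[0]
            if ftype == "transcript":
                declared_tx[tx_id] = (gene_id, feat.seqid)
                continue
            if feat.strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: exon with undefined strand")
            # GTF is 1-based inclusive
            exons_by_tx.setdefault(tx_id, []).append(
                (feat.seqid, feat.strand, feat.start - 1, feat.end)
            )
            tx_gene[tx_id] = gene_id

    for tx_id in declared_tx:
        if tx_id not in exons_by_tx:
            logger.warning("transcript %s has zero exons; excluded", tx_id)

    transcripts = []
    for tx_id in sorted(exons_by_tx):
        rows = sorted(exons_by_tx[tx_id], key=lambda r: r[2])
        chrom, strand = rows[0][0], rows[0][1]
        exons = tuple(GenomicInterval(chrom, s, e) for _, _, s, e in rows)
        transcripts.append(
            TranscriptModel(transcript_id=tx_id, gene_id=tx_gene[tx_id],
                            chrom=chrom, strand=strand, exons=exons)
        )
    return _group_into_genes(transcripts)


def parse_bed12(path: str) -> List[GeneModel]:
    """Parse a 12-column BED file into GeneModels (one transcript per line).

    BED has no gene field: the name column is used as transcript_id and as
    gene_id, so each line forms its own gene unless names repeat.
    """
    transcripts = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 BED columns, found {len(cols)}"
                )
            try:
                chrom = cols[0]
                chrom_start = int(cols[1])
                name = cols[3]
                strand = cols[5]
                block_count = int(cols[9])
                block_sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 field: {exc}") from exc
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount={block_count} does not match "
                    "blockSizes/blockStarts"
                )
            if any(b >= a for a, b in zip(block_starts[1:], block_starts[:-1])):
                raise ParseError(f"{path}:{lineno}: blockStarts not strictly ascending")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            exons = tuple(
                GenomicInterval(chrom, chrom_start + off, chrom_start + off + size)
                for off, size in zip(block_starts, block_sizes)
            )
            transcripts.append(
                TranscriptModel(transcript_id=name, gene_id=name, chrom=chrom,
                                strand=strand, exons=exons)
            )
    return _group_into_genes(transcripts)


def parse_annotation(path: str) -> List[GeneModel]:
    """Dispatch on file extension: .bed -> BED12, otherwise GTF."""
    if str(path).endswith((".bed", ".bed12")):
        return parse_bed12(path)
    return parse_gtf(path)


def write_gtf(genes: Sequence[GeneModel], path: str, source: str = "spliceval") -> None:
    """Write gene/transcript/exon GTF lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for t in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                ts = t.span
                fh.write(f"{t.chrom}\t{source}\ttranscript\t{ts.start + 1}\t{ts.end}\t.\t"
                         f"{t.strand}\t.\t{tattrs}\n")
                for ex in t.exons:
                    fh.write(f"{t.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                             f"{t.strand}\t.\t{tattrs}\n")


def write_bed12(genes: Sequence[GeneModel], path: str) -> None:
    """Write one BED12 line per transcript."""
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                start = t.exons[0].start
                end = t.exons[-1].end
                sizes = ",".join(str(len(ex)) for ex in t.exons)
                offs = ",".join(str(ex.start - start) for ex in t.exons)
                fh.write(
                    f"{t.chrom}\t{start}\t{end}\t{t.transcript_id}\t0\t{t.strand}\t"
                    f"{start}\t{end}\t0\t{len(t.exons)}\t{sizes}\t{offs}\n"
                )


class GeneIndex:
    """Per-chromosome interval index over gene spans."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: Dict[str, IntervalTree] = {}
        self._warned_chroms: set = set()
        for g in self.genes:
            span = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(span.start, span.end, g)

    def find_overlapping_genes(self, iv: GenomicInterval) -> List[GeneModel]:
        """Genes whose span shares >=1 bp with ``iv`` (sorted by gene_id)."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            if iv.chrom not in self._warned_chroms:
                logger.info("chromosome %s absent from annotation", iv.chrom)
                self._warned_chroms.add(iv.chrom)
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        return sorted(hits, key=lambda g: g.gene_id)

    def transcript_lookup(self) -> Dict[str, TranscriptModel]:
        out: Dict[str, TranscriptModel] = {}
        for g in self.genes:
            for t in g.transcripts:
                out[t.transcript_id] = t
        return out


def find_overlapping_genes(iv: GenomicInterval, index: GeneIndex) -> List[GeneModel]:
    """Module-level convenience wrapper over :meth:`GeneIndex.find_overlapping_genes`."""
    return index.find_overlapping_genes(iv)
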