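import os

import pytest

from spliceval import GeneModel, GenomicInterval, TranscriptModel
from spliceval.simulate import PROFILES, SimConfig, simulate_dataset


def make_transcript(
    exons, strand="+", chrom="chr1", tid="T0001", gid="G0001"
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


def make_gene(exons, strand="+", chrom="chr1", gid="G0001", tid=None) -> GeneModel:
    t = make_transcript(exons, strand=strand, chrom=chrom,
                        tid=tid or gid.replace("G", "T"), gid=gid)
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand, transcripts=(t,))


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Error-free simulated dataset: truth SAM must score perfectly."""
    out = tmp_path_factory.mktemp("sim_clean")
    cfg = SimConfig(n_genes=10, n_reads=300, seed=11)
    genes, reads = simulate_dataset(cfg, PROFILES["error-free"], str(out))
    return {
        "dir": str(out),
        "cfg": cfg,
        "genes": genes,
        "reads": reads,
        "sam": str(out / "truth.sam"),
        "gtf": str(out / "genes.gtf"),
        "fasta": str(out / "genome.fa"),
        "pbsim": str(out / "reads"),
    }


@pytest.fixture(scope="session")
def noisy_dataset(tmp_path_factory):
    """Dataset with a realistic error profile for match-rate checks."""
    out = tmp_path_factory.mktemp("sim_noisy")
    cfg = SimConfig(n_genes=10, n_reads=300, seed=12)
    genes, reads = simulate_dataset(cfg, PROFILES["pacbio-roi-like"], str(out))
    return {
        "dir": str(out),
        "cfg": cfg,
        "genes": genes,
        "reads": reads,
        "sam": str(out / "truth.sam"),
        "gtf": str(out / "genes.gtf"),
        "fasta": str(out / "genome.fa"),
        "pbsim": str(out / "reads"),
    }


def write_sam(path, lines, chrom_lengths=None):
    """Write a minimal SAM file from (qname, flag, rname, pos, cigar, seq) tuples."""
    chrom_lengths = chrom_lengths or {"chr1": 100000}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        for name, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for qname, flag, rname, pos, cigar, seq in lines:
            qual = "*" if seq == "*" else "I" * len(seq)
            fh.write(
                f"{qname}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )
    return path
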