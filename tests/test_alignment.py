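"""CIGAR block algebra, match rate, and SAM read assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from spliceval import (
    ParseError,
    ReferenceLookup,
    assemble_read_alignments,
    blocks_from_cigar,
    is_split,
)
from spliceval.alignment import match_counts_from_md

from conftest import write_sam


@pytest.mark.parametrize(
    "pos,cigar,blocks,aligned,read_len",
    [
        (100, "50M1000N50M", [(99, 149), (1149, 1199)], 100, 100),
        (100, "100M", [(99, 199)], 100, 100),
        (100, "10S90M", [(99, 189)], 90, 100),
        (100, "10M5I10M", [(99, 119)], 25, 25),
        (100, "10M5D10M", [(99, 124)], 20, 20),  # D extends, never splits
        (100, "5H20M3S", [(99, 119)], 20, 28),
        (1, "10M10N10M10N10M", [(0, 10), (20, 30), (40, 50)], 30, 30),
    ],
)
def test_blocks_from_cigar(pos, cigar, blocks, aligned, read_len):
    got_blocks, got_aligned, got_read_len = blocks_from_cigar(pos, cigar)
    assert got_blocks == blocks
    assert got_aligned == aligned
    assert got_read_len == read_len


@pytest.mark.parametrize("cigar", ["", "*", "10M5", "M10", "10Q"])
def test_blocks_from_cigar_rejects_invalid(cigar):
    with pytest.raises(ParseError):
        blocks_from_cigar(1, cigar)


_OPS = ["M", "I", "D", "N", "S", "=", "X"]


def brute_force_ref_positions(pos, ops):
    """Per-base reference walk: the set of aligned reference positions,
    grouped into runs split only at N gaps."""
    ref = pos - 1
    runs = []
    current = []
    for length, op in ops:
        if op in ("M", "=", "X", "D"):
            current.extend(range(ref, ref + length))
            ref += length
        elif op == "N":
            if current:
                runs.append((current[0], current[-1] + 1))
            current = []
            ref += length
    if current:
        runs.append((current[0], current[-1] + 1))
    return runs


@settings(max_examples=200, deadline=None)
@given(
    pos=st.integers(1, 1000),
    ops=st.lists(
        st.tuples(st.integers(1, 50), st.sampled_from(_OPS)), min_size=1, max_size=12
    ),
)
def test_blocks_agree_with_per_base_walk(pos, ops):
    """Block extraction equals a brute-force per-base reference walk."""
    cigar = "".join(f"{l}{op}" for l, op in ops)
    blocks, aligned, read_len = blocks_from_cigar(pos, cigar)
    assert blocks == brute_force_ref_positions(pos, ops)
    assert aligned == sum(l for l, op in ops if op in ("M", "=", "X", "I"))
    assert read_len == aligned + sum(l for l, op in ops if op == "S")


def _write_ref(tmp_path, seq, chrom="chr1"):
    p = tmp_path / "ref.fa"
    with open(p, "w") as fh:
        fh.write(f">{chrom}\n{seq}\n")
    return str(p)


def test_match_rate_reference_comparison(tmp_path):
    ref_seq = "ACGTACGTACGTACGTACGT"
    fasta = _write_ref(tmp_path, ref_seq)
    # read identical to ref[4:14]
    sam = write_sam(
        tmp_path / "a.sam",
        [
            ("perfect", 0, "chr1", 5, "10M", ref_seq[4:14]),
            ("one_mm", 0, "chr1", 5, "10M", "T" + ref_seq[5:14]),
            ("with_ins", 0, "chr1", 5, "5M3I5M", ref_seq[4:9] + "AAA" + ref_seq[9:14]),
        ],
        {"chr1": len(ref_seq)},
    )
    ref = ReferenceLookup(fasta)
    records, n = assemble_read_alignments(str(sam), ref)
    by_id = {r.read_id: r for r in records}
    assert n == 3
    assert by_id["perfect"].match_rate == 1.0
    assert by_id["one_mm"].match_rate == pytest.approx(0.9)
    # insertions excluded from numerator and denominator
    assert by_id["with_ins"].match_rate == 1.0


def test_match_rate_md_fallback(tmp_path):
    sam = tmp_path / "a.sam"
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n")
        fh.write("r1\t0\tchr1\t10\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\tMD:Z:4C5\n")
    records, _ = assemble_read_alignments(str(sam), reference=None)
    assert records[0].match_rate == pytest.approx(0.9)


@pytest.mark.parametrize(
    "md,expect",
    [("100", (100, 100)), ("4C5", (9, 10)), ("10^ACG10", (20, 20)), ("0A0C8", (8, 10))],
)
def test_match_counts_from_md(md, expect):
    assert match_counts_from_md(md) == expect


def test_assemble_groups_and_flags(tmp_path):
    sam = write_sam(
        tmp_path / "a.sam",
        [
            ("supp_read", 0, "chr1", 100, "50M50S", "A" * 100),
            ("supp_read", 2048, "chr1", 10100, "50H50M", "A" * 50),
            ("unmapped", 4, "*", 0, "*", "A" * 30),
            ("with_secondary", 0, "chr1", 200, "20M", "A" * 20),
            ("with_secondary", 256, "chr1", 900, "20M", "A" * 20),
            ("chimeric", 0, "chr1", 300, "30M10S", "A" * 40),
            ("chimeric", 2064, "chr1", 5000, "30H10M", "A" * 10),
        ],
    )
    records, n = assemble_read_alignments(str(sam))
    by_id = {r.read_id: r for r in records}
    assert n == 4
    # supplementary on same chrom+strand merges into the block list
    supp = by_id["supp_read"]
    assert [(b.start, b.end) for b in supp.blocks] == [(99, 149), (10099, 10149)]
    assert is_split(supp)
    assert supp.aligned_query_fraction == 1.0
    assert not by_id["unmapped"].is_aligned
    # secondary line ignored: single block remains
    assert len(by_id["with_secondary"].blocks) == 1
    # opposite-strand supplementary: chimeric, scored on primary blocks
    chim = by_id["chimeric"]
    assert chim.is_chimeric
    assert [(b.start, b.end) for b in chim.blocks] == [(299, 329)]
    assert not is_split(chim)


def test_split_classification(tmp_path):
    sam = write_sam(
        tmp_path / "a.sam",
        [
            ("spliced", 0, "chr1", 100, "50M100N50M", "A" * 100),
            ("plain", 0, "chr1", 100, "100M", "A" * 100),
        ],
    )
    records, _ = assemble_read_alignments(str(sam))
    by_id = {r.read_id: r for r in records}
    assert is_split(by_id["spliced"])
    assert not is_split(by_id["plain"])


def test_error_free_truth_sam_has_unit_match_rate(clean_dataset):
    """Reconstructed error-free truth alignments match the genome exactly."""
    ref = ReferenceLookup(clean_dataset["fasta"])
    records, n = assemble_read_alignments(clean_dataset["sam"], ref)
    assert n == len(clean_dataset["reads"])
    assert all(r.match_rate == 1.0 for r in records)
    assert all(r.aligned_query_fraction == 1.0 for r in records)
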