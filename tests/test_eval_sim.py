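"""Simulated-mode scoring: Correct / Hit all / Hit one and summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from spliceval import (
    AlignmentRecord,
    GenomicInterval,
    ReadOrigin,
    compare_read,
    evaluate_simulated,
    summarize,
)
from spliceval.eval_sim import ReadEvaluation
from spliceval.intervals import ContractError


def make_origin(blocks, chrom="chr1", strand="+", read_id="r1"):
    return ReadOrigin(
        read_id=read_id,
        transcript_id="T1",
        chrom=chrom,
        genomic_strand=strand,
        origin_blocks=tuple(GenomicInterval(chrom, s, e) for s, e in blocks),
    )


def make_alignment(blocks, chrom="chr1", strand="+", read_id="r1", aligned=True):
    return AlignmentRecord(
        read_id=read_id,
        is_aligned=aligned,
        chrom=chrom if aligned else None,
        strand=strand if aligned else None,
        blocks=tuple(GenomicInterval(chrom, s, e) for s, e in blocks),
        aligned_query_fraction=1.0 if aligned else 0.0,
        read_len=sum(e - s for s, e in blocks),
    )


ORIGIN = [(100, 200), (300, 400), (500, 600)]


def shift(blocks, d):
    return [(s + d, e + d) for s, e in blocks]


def test_identical_blocks_are_correct():
    ev = compare_read(make_alignment(ORIGIN), make_origin(ORIGIN))
    assert ev.correct and ev.hit_all and ev.hit_one and ev.strand_ok


@pytest.mark.parametrize("d,correct", [(5, True), (-5, True), (6, False), (-6, False)])
def test_boundary_tolerance_is_inclusive_five(d, correct):
    """A 5-nt boundary error is tolerated; 6 nt is not."""
    ev = compare_read(make_alignment(shift(ORIGIN, d)), make_origin(ORIGIN))
    assert ev.correct is correct
    assert ev.hit_all  # 100-bp blocks still overlap well past the threshold


def test_start_shift_only():
    blocks = [(105, 200), (300, 400), (500, 600)]
    assert compare_read(make_alignment(blocks), make_origin(ORIGIN)).correct
    blocks = [(106, 200), (300, 400), (500, 600)]
    ev = compare_read(make_alignment(blocks), make_origin(ORIGIN))
    assert not ev.correct and ev.hit_all


def test_block_count_mismatch_is_not_correct():
    # merged junction: one block spanning the origin's two
    ev = compare_read(make_alignment([(100, 400)]), make_origin([(100, 200), (300, 400)]))
    assert not ev.correct
    assert ev.hit_all  # both origin blocks overlapped >= 5 bp


def test_wrong_chromosome_fails_everything():
    ev = compare_read(make_alignment(ORIGIN, chrom="chr2"), make_origin(ORIGIN))
    assert not (ev.correct or ev.hit_all or ev.hit_one or ev.chrom_ok)


def test_wrong_strand_tracked_separately():
    ev = compare_read(make_alignment(ORIGIN, strand="-"), make_origin(ORIGIN))
    assert ev.correct and not ev.strand_ok


def test_hit_one_vs_hit_all():
    # only the first origin block is recovered
    ev = compare_read(make_alignment([(100, 200)]), make_origin(ORIGIN))
    assert ev.hit_one and not ev.hit_all and not ev.correct


@pytest.mark.parametrize("ov,hit", [(5, True), (4, False)])
def test_min_overlap_threshold_inclusive(ov, hit):
    ev = compare_read(
        make_alignment([(200 - ov, 290)]), make_origin([(100, 200)])
    )
    assert ev.hit_one is hit


def test_unaligned_read_has_all_flags_false():
    ev = compare_read(make_alignment([], aligned=False), make_origin(ORIGIN))
    assert not any([ev.chrom_ok, ev.strand_ok, ev.correct, ev.hit_all, ev.hit_one])


def test_read_id_mismatch_is_contract_error():
    with pytest.raises(ContractError):
        compare_read(make_alignment(ORIGIN, read_id="a"), make_origin(ORIGIN, read_id="b"))


def test_summarize_arithmetic():
    evals = [
        ReadEvaluation("r1", aligned=True, chrom_ok=True, strand_ok=True,
                       correct=True, hit_all=True, hit_one=True, is_split=True,
                       match_rate=0.9),
        ReadEvaluation("r2", aligned=True, chrom_ok=True, hit_one=True,
                       match_rate=0.7),
        ReadEvaluation("r3", aligned=False),
    ]
    s = summarize(evals, n_input_reads=10)
    assert s.pct_aligned == 20.0
    assert s.pct_correct == 10.0
    assert s.pct_hit_one == 20.0
    assert s.pct_split == 10.0
    assert s.pct_correct_split == 10.0
    assert s.mean_match_rate == pytest.approx(80.0)


def test_summarize_rejects_bad_input_count():
    with pytest.raises(ContractError):
        summarize([], 0)
    with pytest.raises(ContractError):
        summarize([ReadEvaluation("r", aligned=False)] * 3, 2)


def test_summarize_zero_aligned():
    s = summarize([ReadEvaluation("r", aligned=False)], 5)
    assert s.pct_aligned == 0.0 and s.mean_match_rate is None


@settings(max_examples=150, deadline=None)
@given(st.data())
def test_metric_chain_monotone_on_random_alignments(data):
    """pct_correct <= pct_hit_all <= pct_hit_one <= pct_aligned always."""
    n = data.draw(st.integers(1, 20))
    evals = []
    for i in range(n):
        origin = make_origin(ORIGIN, read_id=f"r{i}")
        aligned = data.draw(st.booleans())
        if not aligned:
            evals.append(compare_read(make_alignment([], aligned=False,
                                                     read_id=f"r{i}"), origin))
            continue
        k = data.draw(st.integers(1, 4))
        starts = sorted(data.draw(st.lists(st.integers(0, 700), min_size=k,
                                           max_size=k, unique=True)))
        blocks = []
        last = -1
        for s in starts:
            s = max(s, last + 1)
            e = s + data.draw(st.integers(1, 120))
            blocks.append((s, e))
            last = e
        chrom = data.draw(st.sampled_from(["chr1", "chr2"]))
        evals.append(compare_read(make_alignment(blocks, chrom=chrom,
                                                 read_id=f"r{i}"), origin))
    s = summarize(evals, n_input_reads=n + data.draw(st.integers(0, 5)))
    assert s.pct_correct <= s.pct_hit_all <= s.pct_hit_one <= s.pct_aligned
    assert s.pct_correct_split <= s.pct_split_hit_all <= s.pct_split_hit_one <= s.pct_split


def test_end_to_end_error_free_recovery(clean_dataset):
    """Truth SAM of an error-free run scores 100% on every metric."""
    evals, s = evaluate_simulated(
        clean_dataset["sam"], clean_dataset["gtf"], clean_dataset["pbsim"],
        reference_path=clean_dataset["fasta"],
    )
    assert s.pct_aligned == s.pct_correct == s.pct_hit_all == s.pct_hit_one == 100.0
    assert s.pct_strand_ok == 100.0
    assert s.mean_match_rate == pytest.approx(100.0)


def test_eval_sim_works_from_md_tags_without_fasta(noisy_dataset):
    """Match rate via MD fallback equals the reference-based computation."""
    _, with_ref = evaluate_simulated(
        noisy_dataset["sam"], noisy_dataset["gtf"], noisy_dataset["pbsim"],
        reference_path=noisy_dataset["fasta"],
    )
    _, no_ref = evaluate_simulated(
        noisy_dataset["sam"], noisy_dataset["gtf"], noisy_dataset["pbsim"],
    )
    assert no_ref.mean_match_rate == pytest.approx(with_ref.mean_match_rate)
    assert no_ref.n_correct == with_ref.n_correct
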