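"""Read processing: pair merging, quality filtering, demultiplexing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdseq.reads import (
    LayoutSpec,
    ReadRecord,
    ReadRejected,
    merge_pairs,
    demultiplex_and_trim,
    process_reads,
    process_simulated,
    quality_filter,
)
from mdseq.refmodel import reverse_complement
from mdseq.simulate import SimulationConfig, simulate_library


def _rec(seq, q=30, rid="r"):
    quals = [q] * len(seq) if isinstance(q, int) else list(q)
    return ReadRecord(rid, seq, quals)


# ------------------------------------------------------------------ merging


def test_perfect_overlap_merge_arithmetic():
    left = "ACGTACGTACGTACGTACGT"
    overlap = "GGATCCGGATCCGGATCCGGATCCGGATCC"  # 30 nt
    right = "TTGACCTTGACCTTGACC"
    r1 = _rec(left + overlap)
    r2 = _rec(reverse_complement(overlap + right))
    merged = merge_pairs(r1, r2, min_overlap=30)
    assert merged.sequence == left + overlap + right
    assert len(merged.sequence) == len(r1.sequence) + len(r2.sequence) - 30


def test_overlap_mismatch_resolved_to_higher_quality_base():
    base = "ACGTACGTACGTACGTACGTACGTACGTAC"
    altered = "T" + base[1:]  # disagreement at overlap position 0
    r1 = _rec(base, q=30)
    r2 = _rec(reverse_complement(altered), q=10)
    merged = merge_pairs(r1, r2, min_overlap=30)
    assert merged.sequence[0] == "A"  # r1 wins on quality
    assert merged.qualities[0] == 10  # disagreement keeps the lower quality
    # reversed qualities: r2 wins
    merged2 = merge_pairs(_rec(base, q=10), _rec(reverse_complement(altered), q=30),
                          min_overlap=30)
    assert merged2.sequence[0] == "T"


def test_short_overlap_rejected():
    r1 = _rec("AAAAAAAAAACCCCC")
    r2 = _rec(reverse_complement("CCCCCGGGGGGGGGG"))
    with pytest.raises(ReadRejected, match="no_overlap"):
        merge_pairs(r1, r2, min_overlap=10)


# ----------------------------------------------------------- quality filter


@pytest.mark.parametrize(
    "n_good,expected", [(100, True), (90, True), (89, False)],
)
def test_quality_filter_boundary_is_inclusive(n_good, expected):
    quals = [30] * n_good + [10] * (100 - n_good)
    assert quality_filter(_rec("A" * 100, q=quals)) is expected


def test_empty_read_fails_quality_filter():
    assert quality_filter(_rec("")) is False


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    quals=st.lists(st.integers(0, 41), min_size=1, max_size=60),
    pos=st.integers(0, 59),
    bump=st.integers(1, 20),
)
def test_quality_filter_is_monotone(quals, pos, bump):
    """Raising any base quality never flips pass -> fail."""
    pos = pos % len(quals)
    read = _rec("A" * len(quals), q=quals)
    before = quality_filter(read)
    raised = list(quals)
    raised[pos] = min(41, raised[pos] + bump)
    after = quality_filter(_rec("A" * len(quals), q=raised))
    assert after or not before


# ----------------------------------------------------------- demultiplexing

PRIMER = "TGACCATGATTACGCCAAGC"


def _layout(**kw):
    defaults = dict(
        index_assignments={"sA": "ACGT", "s0": ""},
        primer=PRIMER,
        target_len=12,
        barcode_len=14,
        primer_max_mismatch=2,
    )
    defaults.update(kw)
    return LayoutSpec(**defaults)


def test_demultiplex_extracts_barcode_and_target():
    barcode = "GGGGCCCCAAAATT"
    target = "ACGTACGTACGT"
    read = _rec("ACGT" + barcode + PRIMER + target)
    sample, bc, tg = demultiplex_and_trim(read, _layout())
    assert (sample, bc, tg) == ("sA", barcode, target)


def test_zero_length_index_is_fallback_only():
    barcode = "A" * 14
    target = "C" * 12
    layout = _layout(index_assignments={"s7": "ACGTACG", "s0": ""})
    # primer anchors at offset barcode_len only -> the zero-index sample
    read0 = _rec(barcode + PRIMER + target)
    assert demultiplex_and_trim(read0, layout)[0] == "s0"
    # primer anchors after the 7-nt index -> the longer index wins
    read7 = _rec("ACGTACG" + barcode + PRIMER + target)
    assert demultiplex_and_trim(read7, layout)[0] == "s7"


def test_target_length_must_be_exact():
    read = _rec("ACGT" + "A" * 14 + PRIMER + "ACGTACGTACG")  # one short
    with pytest.raises(ReadRejected, match="length_fail"):
        demultiplex_and_trim(read, _layout())


def test_unanchored_read_is_unassigned():
    read = _rec("ACGT" + "A" * 14 + "GGGGGGGGGGGGGGGGGGGG" + "A" * 12)
    with pytest.raises(ReadRejected, match="unassigned"):
        demultiplex_and_trim(read, _layout())


def test_demultiplexing_is_order_independent():
    reads = [
        _rec("ACGT" + "G" * 14 + PRIMER + "ACGTACGTACGT", rid=f"r{i}")
        for i in range(3)
    ] + [_rec("A" * 14 + PRIMER + "TTTTACGTACGT", rid="z")]
    fwd = process_reads(reads, _layout())
    rev = process_reads(reads[::-1], _layout())
    assert {s: sorted(v) for s, v in fwd.by_sample.items()} == {
        s: sorted(v) for s, v in rev.by_sample.items()
    }
    assert fwd.counts == rev.counts


# -------------------------------------------- agreement with simulated data


def test_zero_error_simulated_library_demultiplexes_perfectly(kras_ex2_nt):
    cfg = SimulationConfig(
        amplicon=kras_ex2_nt, n_templates=300, p_linear_error=0, p_seq_error=0,
        index_assignments={"sA": "ACGT", "sB": "GTCAGTC"}, seed=5,
    )
    readset, manifest = simulate_library(cfg)
    layout = LayoutSpec(
        index_assignments=cfg.index_assignments, primer=cfg.primer,
        target_len=kras_ex2_nt.length,
    )
    records = [
        ReadRecord(f"r{i}", readset.read_sequence(i), readset.read_qualities(i))
        for i in range(len(readset))
    ]
    processed = process_reads(records, layout)
    assert processed.counts["passed"] == len(readset)
    truth = manifest.set_index("barcode")["sample"]
    for sample, recs in processed.by_sample.items():
        for bc, _ in recs:
            assert truth[bc] == sample


def test_vectorised_processing_matches_record_path(kras_ex2_nt):
    cfg = SimulationConfig(
        amplicon=kras_ex2_nt, n_templates=200, seed=6, quality_mean=22, quality_sd=4,
        index_assignments={"sA": "ACGT", "sB": "GTCAGTC"},
    )
    readset, _ = simulate_library(cfg)
    layout = LayoutSpec(
        index_assignments=cfg.index_assignments, primer=cfg.primer,
        target_len=kras_ex2_nt.length,
    )
    records = (
        ReadRecord(f"r{i}", readset.read_sequence(i), readset.read_qualities(i))
        for i in range(len(readset))
    )
    slow = process_reads(records, layout)
    fast = process_simulated(readset, layout)
    assert slow.counts == fast.counts
    for sample in layout.index_assignments:
        slow_set = sorted(slow.by_sample[sample])
        bcs, codes = fast.by_sample[sample]
        from mdseq._codes import decode

        fast_set = sorted((bcs[i], decode(codes[i])) for i in range(len(bcs)))
        assert slow_set == fast_set
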