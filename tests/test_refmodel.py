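"""Reference model: coordinates, variant libraries, codon consequences."""

import itertools

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from mdseq.refmodel import (
    DEFAULT_HOTSPOTS,
    MutationKey,
    ReferenceAmplicon,
    annotate_codon_change,
    build_variant_library,
    classify_substitution,
    enumerate_hotspot_mutations,
    reverse_complement,
)

BASES = "ACGT"


# ---------------------------------------------------------------- coordinates


def test_strand_mapping_is_an_involution(amplicons):
    for amp in amplicons.values():
        for p in range(1, amp.length + 1):
            assert amp.cdna_to_read(amp.read_to_cdna(p)) == p


def test_transcribed_read_base_is_complement_of_coding_base(kras_ex2_t):
    for p in range(1, kras_ex2_t.length + 1):
        cdna = kras_ex2_t.read_to_cdna(p)
        read_base = kras_ex2_t.sequence[p - 1]
        assert kras_ex2_t.coding_base(cdna) == reverse_complement(read_base)


def test_non_acgt_reference_rejected_with_position():
    with pytest.raises(ValueError, match="position 3"):
        ReferenceAmplicon("x", "g", 1, "non_transcribed", "ACNT", 1)


# ------------------------------------------------------------ variant library


def test_variant_library_has_3l_distinct_entries():
    amp = ReferenceAmplicon("t", "g", 1, "non_transcribed", "ACGTACGTAC", 1)
    lib = build_variant_library(amp)
    seqs = [s for s, _ in lib]
    assert len(lib) == 30
    assert len(set(seqs)) == 30
    assert amp.sequence not in seqs


def test_variant_library_exactness():
    """Matching any library sequence to the reference recovers exactly the
    annotated single substitution."""
    amp = ReferenceAmplicon("t", "g", 1, "non_transcribed", "ACGTACGTACGT", 4)
    for variant, key in build_variant_library(amp):
        diffs = [i for i in range(len(variant)) if variant[i] != amp.sequence[i]]
        assert len(diffs) == 1
        assert amp.read_to_cdna(diffs[0] + 1) == key.cdna_pos
        assert variant[diffs[0]] == key.alt_base  # non-transcribed: read == coding


def test_a182t_variant_is_q61l(kras_ex2_nt):
    lib = {k.label: k for _, k in build_variant_library(kras_ex2_nt)}
    assert lib["A182>T"].aa_change == "Q61L"
    assert lib["A182>T"].context5 == "C"


def test_both_orientations_yield_identical_key_sets(kras_ex2_nt, kras_ex2_t):
    """Coding-strand normalisation: assaying either strand of the same span
    gives the same mutation key space."""
    keys_nt = {k for _, k in build_variant_library(kras_ex2_nt)}
    keys_t = {k for _, k in build_variant_library(kras_ex2_t)}
    assert keys_nt == keys_t


# ------------------------------------------------------------ codon changes


@pytest.mark.parametrize(
    "cdna_pos,alt,expected",
    [(182, "T", "Q61L"), (182, "G", "Q61R"), (183, "T", "Q61H")],
)
def test_hotspot_codon_consequences(kras_ex2_nt, cdna_pos, alt, expected):
    key = kras_ex2_nt.mutation_key(cdna_pos, alt)
    assert key.aa_change == expected
    # and through the standalone annotator
    assert annotate_codon_change(key, kras_ex2_nt.codon_annotations()) == expected


def test_silent_nonsense_and_out_of_span(kras_ex2_nt):
    codons = kras_ex2_nt.codon_annotations()
    # CAA -> CAG is still Gln
    assert annotate_codon_change(kras_ex2_nt.mutation_key(183, "G"), codons) == "silent"
    # CAA -> TAA is a stop gain
    assert annotate_codon_change(kras_ex2_nt.mutation_key(181, "T"), codons) == "nonsense"
    with pytest.raises(ValueError):
        bad = MutationKey(cdna_pos=1, ref_base="A", alt_base="C")
        annotate_codon_change(bad, codons)


# ------------------------------------------------------------ classification


def test_can_to_ctn_classification(kras_ex2_nt):
    cls = classify_substitution(kras_ex2_nt.mutation_key(182, "T"))
    assert cls["substitution"] == "A>T"
    assert cls["tri_class"] == "CAN>CTN"
    assert cls["complement_class"] == "NTG>NAG"


@settings(derandomize=True, max_examples=200, deadline=None)
@given(data=st.data())
def test_complement_class_equals_class_of_reverse_complemented_key(data):
    ref = data.draw(st.sampled_from(BASES))
    alt = data.draw(st.sampled_from([b for b in BASES if b != ref]))
    c5 = data.draw(st.sampled_from(BASES))
    c3 = data.draw(st.sampled_from(BASES))
    key = MutationKey(10, ref, alt, c5, c3)
    rc = key.reverse_complemented()
    assert classify_substitution(key)["complement_class"] == classify_substitution(rc)["tri3_class"]
    # the mapping is itself an involution
    assert rc.reverse_complemented() == key


def test_g34_substitutions_never_can_pattern(kras_ex1_nt):
    """Codon 12 starts with G at cDNA 34; no substitution there fits the
    CAN>CTN pattern in either strand orientation."""
    for alt in "ACT":
        key = kras_ex1_nt.mutation_key(34, alt)
        for k in (key, key.reverse_complemented()):
            cls = classify_substitution(k)
            assert cls["tri_class"] != "CAN>CTN"
            assert cls["tri3_class"] != "NTG>NAG"


def test_edge_position_has_undefined_context_but_classified_substitution(kras_ex2_nt):
    lo, _ = kras_ex2_nt.cdna_span
    key = kras_ex2_nt.mutation_key(lo, "T")
    cls = classify_substitution(key)
    assert cls["tri_class"] == "undefined"
    assert ">" in cls["substitution"]


def test_a_to_t_and_a_to_g_are_two_of_three_changes():
    changes = {alt for alt in BASES if alt != "A"}
    assert {"T", "G"} < changes and len(changes) == 3


# ------------------------------------------------------------ hotspot census


def _oracle_hotspot_counts(hotspots, n_genes):
    """Independent brute force straight through a genetic-code table."""
    n_point = 0
    distinct = set()
    per_codon = {}
    for label, (_, codon) in hotspots.items():
        aas = set()
        for pos, alt in itertools.product(range(3), BASES):
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            aa = str(Seq(mut).translate())
            if aa in ("*", str(Seq(codon).translate())):
                continue
            n_point += n_genes
            aas.add(aa)
            for g in range(n_genes):
                distinct.add((g, label, aa))
        per_codon[label] = aas
    return n_point, len(distinct), per_codon


def test_enumeration_agrees_with_brute_force_oracle():
    summary = enumerate_hotspot_mutations()
    n_point, n_distinct, per_codon = _oracle_hotspot_counts(DEFAULT_HOTSPOTS, 3)
    assert summary.n_point_mutations == n_point == 57
    assert summary.n_distinct_substitutions == n_distinct == 54
    assert {k: set(v) for k, v in summary.per_codon_missense.items()} == per_codon


def test_q61_missense_set_and_stop_exclusion():
    summary = enumerate_hotspot_mutations()
    assert summary.per_codon_missense["Q61"] == frozenset("LRKHEP")
    # CAA -> TAA is a stop and must not appear anywhere
    assert "*" not in set().union(*summary.per_codon_missense.values())
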