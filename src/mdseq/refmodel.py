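"""Reference amplicons, coordinate conventions and variant libraries.

Maximum-depth sequencing (MDS) assays read a short exon-sized target either
from the non-transcribed (coding) strand or from the transcribed strand.
All mutation bookkeeping in this package is normalised to 1-based cDNA
coordinates on the coding strand, the convention used for Ras hotspot
notation such as G12 (cDNA 34-36), G13 (37-39) and Q61 (181-183); codon
``i`` spans cDNA positions ``3i-2 .. 3i``.

A :class:`ReferenceAmplicon` stores the sequence in *read orientation* (the
strand the sequencer actually reports) together with the mapping back to
coding-strand cDNA coordinates, so assays of either strand merge into one
coding-strand mutation space while the originating read strand is retained
for strand-bias analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

TRANSCRIBED = "transcribed"
NON_TRANSCRIBED = "non_transcribed"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"

#: Default oncogenic hotspot codons (label -> (codon index, reference codon)).
DEFAULT_HOTSPOTS: Mapping[str, tuple[int, str]] = {
    "G12": (12, "GGT"),
    "G13": (13, "GGC"),
    "Q61": (61, "CAA"),
}

#: The three Ras paralogs carrying identical hotspot codons.
DEFAULT_HOTSPOT_GENES = ("Hras", "Kras", "Nras")


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_codon(codon: str) -> str:
    """Translate a codon with the standard genetic code; '*' for stop."""
    return standard_dna_table.forward_table.get(codon, "*")


@dataclass(frozen=True)
class MutationKey:
    """A single-nucleotide substitution in coding-strand cDNA notation.

    ``context5``/``context3`` are the coding-strand flanking bases (``None``
    at an amplicon edge).  ``aa_change`` is e.g. ``"Q61L"``, ``"silent"``,
    ``"nonsense"`` or ``None`` outside annotated codons.
    """

    cdna_pos: int
    ref_base: str
    alt_base: str
    context5: str | None = None
    context3: str | None = None
    codon_index: int | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in _BASES:
                raise ValueError(f"invalid base {b!r}")

    @property
    def label(self) -> str:
        return f"{self.ref_base}{self.cdna_pos}>{self.alt_base}"

    def reverse_complemented(self) -> "MutationKey":
        """The same physical change read from the opposite strand."""
        return MutationKey(
            cdna_pos=self.cdna_pos,
            ref_base=complement(self.ref_base),
            alt_base=complement(self.alt_base),
            context5=None if self.context3 is None else complement(self.context3),
            context3=None if self.context5 is None else complement(self.context5),
            codon_index=self.codon_index,
            aa_change=self.aa_change,
        )


@dataclass(frozen=True)
class CodonAnnotation:
    codon_index: int
    ref_codon: str
    ref_aa: str

    @property
    def cdna_span(self) -> tuple[int, int]:
        return (3 * self.codon_index - 2, 3 * self.codon_index)


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A sequenced MDS target with its strand and coordinate conventions.

    ``sequence`` is in read orientation.  ``cdna_start`` is the coding-strand
    cDNA coordinate of the read's *first* base; on a transcribed-strand
    amplicon the read runs 3'->5' along the coding strand, so cDNA
    coordinates decrease along the read.
    """

    name: str
    gene: str
    exon: int
    read_strand: str
    sequence: str
    cdna_start: int

    def __post_init__(self) -> None:
        if self.read_strand not in (TRANSCRIBED, NON_TRANSCRIBED):
            raise ValueError(f"unknown read_strand {self.read_strand!r}")
        for i, b in enumerate(self.sequence):
            if b not in _BASES:
                raise ValueError(
                    f"{self.name}: non-ACGT reference base {b!r} at read position {i + 1}"
                )
        if self.cdna_span[0] < 1:
            raise ValueError("cDNA span extends below position 1")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cdna_span(self) -> tuple[int, int]:
        """(lowest, highest) coding-strand cDNA coordinate covered."""
        if self.read_strand == NON_TRANSCRIBED:
            return (self.cdna_start, self.cdna_start + self.length - 1)
        return (self.cdna_start - self.length + 1, self.cdna_start)

    # -- coordinate mapping (a bijection; applying read->cdna->read is id) --

    def read_to_cdna(self, read_pos: int) -> int:
        """Map a 1-based read position to its coding-strand cDNA position."""
        if not 1 <= read_pos <= self.length:
            raise ValueError(f"read position {read_pos} outside 1..{self.length}")
        if self.read_strand == NON_TRANSCRIBED:
            return self.cdna_start + read_pos - 1
        return self.cdna_start - read_pos + 1

    def cdna_to_read(self, cdna_pos: int) -> int:
        lo, hi = self.cdna_span
        if not lo <= cdna_pos <= hi:
            raise ValueError(f"cDNA position {cdna_pos} outside span {lo}..{hi}")
        if self.read_strand == NON_TRANSCRIBED:
            return cdna_pos - self.cdna_start + 1
        return self.cdna_start - cdna_pos + 1

    @property
    def coding_sequence(self) -> str:
        """Coding-strand sequence over the covered span, low to high cDNA."""
        if self.read_strand == NON_TRANSCRIBED:
            return self.sequence
        return reverse_complement(self.sequence)

    def coding_base(self, cdna_pos: int) -> str:
        lo, _ = self.cdna_span
        return self.coding_sequence[cdna_pos - lo]

    def coding_context(self, cdna_pos: int) -> tuple[str | None, str | None]:
        """Coding-strand 5'/3' neighbours; ``None`` past an amplicon edge."""
        lo, hi = self.cdna_span
        c5 = self.coding_base(cdna_pos - 1) if cdna_pos - 1 >= lo else None
        c3 = self.coding_base(cdna_pos + 1) if cdna_pos + 1 <= hi else None
        return c5, c3

    def read_base_for(self, cdna_pos: int, coding_base: str) -> str:
        """The read-orientation base representing ``coding_base`` at a position."""
        return coding_base if self.read_strand == NON_TRANSCRIBED else complement(coding_base)

    def codon_annotations(self) -> dict[int, CodonAnnotation]:
        """Annotations for every codon fully contained in the covered span."""
        lo, hi = self.cdna_span
        coding = self.coding_sequence
        out: dict[int, CodonAnnotation] = {}
        # first codon index i with 3i-2 >= lo
        i = (lo - 1) // 3 + 1
        if 3 * i - 2 < lo:
            i += 1
        while 3 * i <= hi:
            start = 3 * i - 2
            codon = coding[start - lo : start - lo + 3]
            out[i] = CodonAnnotation(i, codon, translate_codon(codon))
            i += 1
        return out

    def mutation_key(self, cdna_pos: int, alt_coding_base: str) -> MutationKey:
        """Build the fully annotated key for a coding-strand substitution."""
        ref = self.coding_base(cdna_pos)
        c5, c3 = self.coding_context(cdna_pos)
        codons = self.codon_annotations()
        idx = (cdna_pos + 2) // 3
        ann = codons.get(idx)
        key = MutationKey(cdna_pos, ref, alt_coding_base, c5, c3,
                          ann.codon_index if ann else None, None)
        if ann is not None:
            key = replace(key, aa_change=annotate_codon_change(key, codons))
        return key


def annotate_codon_change(key: MutationKey, codons: Mapping[int, CodonAnnotation]) -> str:
    """Amino-acid consequence of a substitution under the standard code.

    Returns e.g. ``"Q61L"`` for a missense change, ``"silent"`` when the
    amino acid is unchanged and ``"nonsense"`` for a stop gain.
    """
    idx = (key.cdna_pos + 2) // 3
    if idx not in codons:
        raise ValueError(f"cDNA position {key.cdna_pos} outside annotated codons")
    ann = codons[idx]
    offset = key.cdna_pos - (3 * idx - 2)
    if ann.ref_codon[offset] != key.ref_base:
        raise ValueError(
            f"reference mismatch at cDNA {key.cdna_pos}: codon says "
            f"{ann.ref_codon[offset]}, key says {key.ref_base}"
        )
    mut_codon = ann.ref_codon[:offset] + key.alt_base + ann.ref_codon[offset + 1 :]
    alt_aa = translate_codon(mut_codon)
    if alt_aa == ann.ref_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsense"
    return f"{ann.ref_aa}{idx}{alt_aa}"


def build_variant_library(amplicon: ReferenceAmplicon) -> list[tuple[str, MutationKey]]:
    """All single-substitution variants of an amplicon, in read orientation.

    Returns exactly ``3 * length`` (variant sequence, coding-strand key)
    pairs, each differing from the reference at one read position.  Family
    consensi are exact-matched against this library downstream.
    """
    out: list[tuple[str, MutationKey]] = []
    seq = amplicon.sequence
    for p in range(1, amplicon.length + 1):
        read_ref = seq[p - 1]
        cdna = amplicon.read_to_cdna(p)
        for read_alt in _BASES:
            if read_alt == read_ref:
                continue
            coding_alt = (
                read_alt if amplicon.read_strand == NON_TRANSCRIBED else complement(read_alt)
            )
            key = amplicon.mutation_key(cdna, coding_alt)
            variant = seq[: p - 1] + read_alt + seq[p:]
            out.append((variant, key))
    return out


def classify_substitution(key: MutationKey) -> dict[str, str]:
    """Substitution / trinucleotide class labels for a coding-strand key.

    ``substitution``: e.g. ``"A>T"``.
    ``tri_class``: 5'-anchored pattern, e.g. ``"CAN>CTN"`` (A>T with a 5' C),
    or ``"undefined"`` when the 5' flank is missing.
    ``tri3_class``: 3'-anchored pattern, e.g. ``"NTG>NAG"``.
    ``complement_class``: the 3'-anchored class of the reverse-complemented
    key — the label the same change carries when read from the other strand.
    """
    sub = f"{key.ref_base}>{key.alt_base}"
    c5, c3 = key.context5, key.context3
    tri5 = f"{c5}{key.ref_base}N>{c5}{key.alt_base}N" if c5 else "undefined"
    tri3 = f"N{key.ref_base}{c3}>N{key.alt_base}{c3}" if c3 else "undefined"
    if c5:
        comp_cls = (
            f"N{complement(key.ref_base)}{complement(c5)}>"
            f"N{complement(key.alt_base)}{complement(c5)}"
        )
    else:
        comp_cls = "undefined"
    return {
        "substitution": sub,
        "tri_class": tri5,
        "tri3_class": tri3,
        "complement_class": comp_cls,
    }


@dataclass(frozen=True)
class HotspotSummary:
    n_point_mutations: int
    n_distinct_substitutions: int
    per_codon_missense: dict[str, frozenset[str]] = field(hash=False)


def enumerate_hotspot_mutations(
    hotspots: Mapping[str, tuple[int, str]] | None = None,
    genes: Iterable[str] = DEFAULT_HOTSPOT_GENES,
) -> HotspotSummary:
    """Exhaustively enumerate oncogenic hotspot point mutations.

    Every single-nucleotide substitution of each hotspot codon is translated
    with the standard genetic code; synonymous and nonsense changes are
    excluded.  ``n_point_mutations`` counts missense point mutations over all
    genes; ``n_distinct_substitutions`` counts distinct
    (gene, codon, target amino acid) outcomes, collapsing point mutations
    that reach the same amino acid (e.g. CAA 182A>C and 183A>T/C all give
    His).  With the canonical G12/G13/Q61 codons over the three Ras paralogs
    this yields 57 point mutations and 54 distinct substitutions.
    """
    hotspots = dict(hotspots) if hotspots is not None else dict(DEFAULT_HOTSPOTS)
    genes = tuple(genes)
    n_point = 0
    distinct: set[tuple[str, str, str]] = set()
    per_codon: dict[str, set[str]] = {}
    for label, (codon_index, codon) in hotspots.items():
        if len(codon) != 3 or any(b not in _BASES for b in codon):
            raise ValueError(f"hotspot {label}: invalid codon {codon!r}")
        ref_aa = translate_codon(codon)
        aa_set: set[str] = set()
        for offset, alt in itertools.product(range(3), _BASES):
            if alt == codon[offset]:
                continue
            mut = codon[:offset] + alt + codon[offset + 1 :]
            alt_aa = translate_codon(mut)
            if alt_aa in ("*", ref_aa):
                continue  # nonsense / synonymous: not oncogenic missense
            aa_set.add(alt_aa)
            n_point += len(genes)
            for g in genes:
                distinct.add((g, label, alt_aa))
        per_codon[label] = aa_set
    return HotspotSummary(
        n_point_mutations=n_point,
        n_distinct_substitutions=len(distinct),
        per_codon_missense={k: frozenset(v) for k, v in per_codon.items()},
    )
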