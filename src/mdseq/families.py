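"""Barcode-family grouping, consensus calling and sample-level QC.

Reads sharing one random barcode descend from one template molecule, so a
true template mutation appears in every family member while amplification
and sequencing errors do not.  Two calling modes mirror the two study
designs:

* ``carcinogen`` — families with >= 3 reads and a unique consensus (one
  base carried by >= 90% of members at *every* position) are exact-matched
  against the reference and its single-substitution variant library and
  classified WT / SINGLE / OTHER; for family sizes <= 9 the 90% rule equals
  unanimity.
* ``spikein`` — families with >= 2 reads where >= 90% of members carry the
  engineered alternate base at *each* engineered position count as detected
  spike-in families.

Samples recovering fewer than 1.5e5 barcode families are excluded outright;
below that floor frequency estimates lose both sensitivity and accuracy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import decode, encode
from .refmodel import MutationKey, ReferenceAmplicon

#: Minimum barcode families for a sample to enter downstream analysis.
SAMPLE_QC_THRESHOLD = 1.5e5


class FamilyStatus(str, Enum):
    WT = "WT"
    SINGLE = "SINGLE"
    OTHER = "OTHER"
    NO_CONSENSUS = "NO_CONSENSUS"
    TOO_SMALL = "TOO_SMALL"
    SPIKEIN = "SPIKEIN"  # spike-in mode: engineered mutations detected


@dataclass
class BarcodeFamily:
    barcode: str
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusCall:
    barcode: str
    size: int
    status: FamilyStatus
    mutation: MutationKey | None = None
    consensus_seq: str | None = None


@dataclass
class CallParams:
    min_size_carcinogen: int = 3
    min_size_spikein: int = 2
    agreement: float = 0.90


def group_by_barcode(records: Iterable[tuple[str, str]]) -> list[BarcodeFamily]:
    """Exact-match grouping of (barcode, target) records into families."""
    groups: dict[str, list[str]] = defaultdict(list)
    for barcode, target in records:
        groups[barcode].append(target)
    return [BarcodeFamily(bc, members) for bc, members in groups.items()]


@lru_cache(maxsize=16)
def _library_lookup(amplicon: ReferenceAmplicon) -> dict[tuple[int, int], MutationKey]:
    """(read position 0-based, read alt code) -> coding-strand key."""
    from .refmodel import build_variant_library

    out = {}
    ref = amplicon.sequence
    for variant, key in build_variant_library(amplicon):
        diff = [i for i in range(len(ref)) if variant[i] != ref[i]]
        (i,) = diff
        out[(i, int(encode(variant[i])[0]))] = key
    return out


def call_family(
    family: BarcodeFamily,
    mode: str,
    amplicon: ReferenceAmplicon,
    params: CallParams | None = None,
    spikein_mutations: Sequence[MutationKey] = (),
) -> ConsensusCall:
    """Call one barcode family (reference implementation, one family at a time).

    The bulk path :func:`call_families` is the vectorised equivalent; the two
    are required to agree and are cross-checked in the test suite.
    """
    params = params or CallParams()
    lengths = {len(m) for m in family.members}
    if len(lengths) > 1:
        return ConsensusCall(family.barcode, family.size, FamilyStatus.NO_CONSENSUS)
    if lengths and lengths != {amplicon.length}:
        return ConsensusCall(family.barcode, family.size, FamilyStatus.NO_CONSENSUS)

    if mode == "spikein":
        if family.size < params.min_size_spikein:
            return ConsensusCall(family.barcode, family.size, FamilyStatus.TOO_SMALL)
        ok = True
        for key in spikein_mutations:
            rp = amplicon.cdna_to_read(key.cdna_pos) - 1
            alt_read = amplicon.read_base_for(key.cdna_pos, key.alt_base)
            frac = sum(m[rp] == alt_read for m in family.members) / family.size
            if frac < params.agreement:
                ok = False
                break
        status = FamilyStatus.SPIKEIN if ok else FamilyStatus.NO_CONSENSUS
        return ConsensusCall(family.barcode, family.size, status)

    if mode != "carcinogen":
        raise ValueError(f"unknown calling mode {mode!r}")
    if family.size < params.min_size_carcinogen:
        return ConsensusCall(family.barcode, family.size, FamilyStatus.TOO_SMALL)

    mat = np.stack([encode(m) for m in family.members])
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    top = counts.max(axis=0)
    if (top < params.agreement * family.size).any():
        return ConsensusCall(family.barcode, family.size, FamilyStatus.NO_CONSENSUS)
    consensus = counts.argmax(axis=0).astype(np.uint8)
    cons_seq = decode(consensus)

    ref = encode(amplicon.sequence)
    diffs = np.flatnonzero(consensus != ref)
    if len(diffs) == 0:
        return ConsensusCall(family.barcode, family.size, FamilyStatus.WT,
                             consensus_seq=cons_seq)
    if len(diffs) == 1:
        i = int(diffs[0])
        key = _library_lookup(amplicon)[(i, int(consensus[i]))]
        return ConsensusCall(family.barcode, family.size, FamilyStatus.SINGLE,
                             mutation=key, consensus_seq=cons_seq)
    return ConsensusCall(family.barcode, family.size, FamilyStatus.OTHER,
                         consensus_seq=cons_seq)


def call_families(
    barcodes: np.ndarray,
    codes: np.ndarray,
    mode: str,
    amplicon: ReferenceAmplicon,
    params: CallParams | None = None,
    spikein_mutations: Sequence[MutationKey] = (),
) -> pd.DataFrame:
    """Vectorised family grouping + calling over per-read code matrices.

    ``barcodes`` is a per-read string array, ``codes`` the matching
    (n_reads, L) base-code matrix.  Returns one row per family with columns
    barcode, size, status, cdna_pos, ref, alt, aa_change.
    """
    params = params or CallParams()
    L = codes.shape[1]
    if L != amplicon.length:
        raise ValueError("read length does not match amplicon length")
    if len(barcodes) == 0:
        return pd.DataFrame(
            columns=["barcode", "size", "status", "cdna_pos", "ref", "alt", "aa_change"]
        )
    order = np.argsort(barcodes, kind="stable")
    sorted_bc = barcodes[order]
    boundary = np.ones(len(sorted_bc), dtype=bool)
    boundary[1:] = sorted_bc[1:] != sorted_bc[:-1]
    fam_idx = np.cumsum(boundary) - 1  # family id per sorted read
    n_fam = int(fam_idx[-1]) + 1
    fam_barcode = sorted_bc[boundary]
    sizes = np.bincount(fam_idx, minlength=n_fam)
    sorted_codes = codes[order]
    fam_base = fam_idx * 4  # flat index base for per-position base tallies

    def _position_tally(p: int) -> np.ndarray:
        """(n_fam, 4) base counts at read position p."""
        return np.bincount(fam_base + sorted_codes[:, p], minlength=n_fam * 4).reshape(
            n_fam, 4
        )

    status = np.empty(n_fam, dtype=object)
    cdna_pos = np.full(n_fam, -1, dtype=np.int64)
    ref_b = np.full(n_fam, "", dtype=object)
    alt_b = np.full(n_fam, "", dtype=object)
    aa = np.full(n_fam, "", dtype=object)

    if mode == "spikein":
        min_size = params.min_size_spikein
        detected = sizes >= min_size
        for key in spikein_mutations:
            rp = amplicon.cdna_to_read(key.cdna_pos) - 1
            alt_code = int(encode(amplicon.read_base_for(key.cdna_pos, key.alt_base))[0])
            alt_count = np.bincount(fam_idx[sorted_codes[:, rp] == alt_code], minlength=n_fam)
            detected &= alt_count / np.maximum(sizes, 1) >= params.agreement
        status[:] = FamilyStatus.NO_CONSENSUS.value
        status[detected] = FamilyStatus.SPIKEIN.value
        status[sizes < min_size] = FamilyStatus.TOO_SMALL.value
    elif mode == "carcinogen":
        min_size = params.min_size_carcinogen
        consensus = np.empty((n_fam, L), dtype=np.uint8)
        unique_cons = np.ones(n_fam, dtype=bool)
        need = params.agreement * sizes
        for p in range(L):
            cnt = _position_tally(p)
            consensus[:, p] = cnt.argmax(axis=1)
            unique_cons &= cnt.max(axis=1) >= need
        ref = encode(amplicon.sequence)
        ndiff = (consensus != ref).sum(axis=1)
        status[:] = FamilyStatus.NO_CONSENSUS.value
        status[unique_cons & (ndiff == 0)] = FamilyStatus.WT.value
        status[unique_cons & (ndiff == 1)] = FamilyStatus.SINGLE.value
        status[unique_cons & (ndiff > 1)] = FamilyStatus.OTHER.value
        status[sizes < min_size] = FamilyStatus.TOO_SMALL.value
        lookup = _library_lookup(amplicon)
        singles = np.flatnonzero(status == FamilyStatus.SINGLE.value)
        for f in singles:
            i = int(np.flatnonzero(consensus[f] != ref)[0])
            key = lookup[(i, int(consensus[f, i]))]
            cdna_pos[f] = key.cdna_pos
            ref_b[f] = key.ref_base
            alt_b[f] = key.alt_base
            aa[f] = key.aa_change or ""
    else:
        raise ValueError(f"unknown calling mode {mode!r}")

    return pd.DataFrame(
        {
            "barcode": fam_barcode,
            "size": sizes,
            "status": status,
            "cdna_pos": cdna_pos,
            "ref": ref_b,
            "alt": alt_b,
            "aa_change": aa,
        }
    )


def sample_qc(n_families: int, threshold: float = SAMPLE_QC_THRESHOLD) -> bool:
    """True (include) iff the sample recovered >= ``threshold`` families."""
    if n_families < 0:
        raise ValueError("family count cannot be negative")
    return not n_families < threshold


def family_size_histogram(calls: pd.DataFrame) -> pd.DataFrame:
    hist = calls["size"].value_counts().sort_index()
    return pd.DataFrame({"size": hist.index, "n_families": hist.values})
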