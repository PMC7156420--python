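"""Per-mutation frequencies, detection-limit correction and heatmap matrices.

The mutation frequency (MF) of a key is the number of families whose
consensus carries exactly that substitution divided by the total number of
consensus-passing families in the sample.  Before log transformation every
frequency is corrected by adding the detection limit at the barcode-QC
floor, ``1 / 1.5e5 ~= 6.67e-6``, so unobserved keys contribute a finite
floor rather than log(0).  Heatmap matrices sum corrected frequencies
within a grouping (nucleotide position, substitution class, or individual
A>T keys), then express urethane-treated samples as fold change over the
arithmetic mean of PBS-treated samples, log10-transformed.

Strand-artifact masking: C>T and G>T changes *as read* are inflated by
cytosine deamination and guanine oxidation during library preparation, so
their coding-strand frequencies are taken from the assay of the opposite
strand, where the same change reads as G>A or C>A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import key_record
from .refmodel import (
    NON_TRANSCRIBED,
    TRANSCRIBED,
    MutationKey,
    ReferenceAmplicon,
    build_variant_library,
    complement,
)

#: Detection-limit pseudo-frequency at the 1.5e5 barcode-family QC floor.
DETECTION_LIMIT = 1.0 / 1.5e5

_KEY_COLS = ["cdna_pos", "ref", "alt"]


@dataclass
class SampleMeta:
    treatment: str = "UR"  # "UR" or "PBS"
    tissue: str = "lung"
    week: int = 1


@dataclass
class FrequencyTable:
    """Per-sample mutation frequencies over a full variant-library key space."""

    sample_id: str
    amplicon: ReferenceAmplicon
    data: pd.DataFrame  # one row per MutationKey
    total_families: int
    meta: SampleMeta = field(default_factory=SampleMeta)


def compute_frequencies(
    calls: pd.DataFrame,
    total_families: int,
    amplicon: ReferenceAmplicon,
    sample_id: str = "sample1",
    meta: SampleMeta | None = None,
    correction: float = DETECTION_LIMIT,
) -> FrequencyTable:
    """Mutation frequencies from a calls table (one row per family).

    Every key of the amplicon's single-substitution library gets an explicit
    row; keys never observed get ``mf = 0`` (and ``mf_corrected`` equal to
    the correction constant).
    """
    if total_families <= 0:
        raise ValueError("total_families must be positive")
    rows = [key_record(key) for _, key in build_variant_library(amplicon)]
    table = pd.DataFrame(rows)
    singles = calls[calls["status"] == "SINGLE"]
    if len(singles):
        counts = (
            singles.groupby(_KEY_COLS, sort=False).size().rename("n_families").reset_index()
        )
        table = table.merge(counts, on=_KEY_COLS, how="left")
        table["n_families"] = table["n_families"].fillna(0).astype(int)
    else:
        table["n_families"] = 0
    table["total_families"] = total_families
    table["mf"] = table["n_families"] / total_families
    table["mf_corrected"] = table["mf"] + correction
    return FrequencyTable(
        sample_id=sample_id,
        amplicon=amplicon,
        data=table,
        total_families=total_families,
        meta=meta or SampleMeta(),
    )


def _group_column(table: FrequencyTable, group_by: str) -> pd.Series:
    df = table.data
    if group_by == "position":
        return df["cdna_pos"].astype(str)
    if group_by == "subst":
        return df["substitution_class"]
    if group_by == "a2t":
        sel = df["substitution_class"] == "A>T"
        lab = df["context5"].fillna("") + "A" + df["context3"].fillna("") + "_" + df[
            "cdna_pos"
        ].astype(str)
        return lab.where(sel, other=None)
    raise ValueError(f"unknown group_by {group_by!r}")


def correct_and_fold_change(
    ur_tables: Sequence[FrequencyTable],
    pbs_tables: Sequence[FrequencyTable],
    group_by: str = "subst",
    norm: str = "pbs",
    constant: float = DETECTION_LIMIT,
) -> pd.DataFrame:
    """Heatmap matrix of log10 values, samples as rows, group keys as columns.

    ``norm="pbs"``: per group key, sum corrected frequencies within each
    sample and divide each urethane sample's sum by the arithmetic mean of
    the PBS sums, log10-transformed (rows = UR then PBS samples, the latter
    normalised against their own cohort mean).  ``norm="none"``: log10 of
    the corrected sums without normalisation.
    """
    if norm not in ("pbs", "none"):
        raise ValueError(f"unknown norm {norm!r}")
    if norm == "pbs" and not pbs_tables:
        raise ValueError("fold-change normalisation requires >= 1 PBS sample")
    all_tables = list(ur_tables) + list(pbs_tables)
    if not all_tables:
        raise ValueError("no samples")
    amp_names = {t.amplicon.name for t in all_tables}
    if len(amp_names) > 1:
        raise ValueError(f"samples span multiple amplicons: {sorted(amp_names)}")

    def corrected_sums(t: FrequencyTable) -> pd.Series:
        groups = _group_column(t, group_by)
        df = t.data.assign(_g=groups).dropna(subset=["_g"])
        mf = df["mf"] + constant
        return mf.groupby(df["_g"]).sum()

    sums = pd.DataFrame({t.sample_id: corrected_sums(t) for t in all_tables}).T
    if norm == "none":
        return np.log10(sums)
    pbs_ids = [t.sample_id for t in pbs_tables]
    pbs_mean = sums.loc[pbs_ids].mean(axis=0)
    return np.log10(sums.divide(pbs_mean, axis=1))


def _as_read_class(row: pd.Series, read_strand: str) -> str:
    """Substitution class in the orientation the assay actually read."""
    if read_strand == NON_TRANSCRIBED:
        return f"{row['ref']}>{row['alt']}"
    return f"{complement(row['ref'])}>{complement(row['alt'])}"

#: As-read substitution classes inflated by library-preparation artifacts.
ARTIFACT_CLASSES = ("C>T", "G>T")


def mask_strand_artifacts(
    table_nt: FrequencyTable,
    table_t: FrequencyTable | None = None,
) -> pd.DataFrame:
    """Merge opposite-strand assays into one coding-strand table.

    For keys whose change reads as C>T or G>T on a given strand, the
    reported frequency is taken from the assay of the other strand (where
    the same change reads as G>A or C>A); all other keys pass through from
    the non-transcribed assay.  With only one assay available, artifact-
    prone keys are flagged ``masked`` and should be excluded from sums.
    The provenance read strand is recorded per key.
    """
    nt = table_nt.data.copy()
    if table_nt.amplicon.read_strand != NON_TRANSCRIBED:
        raise ValueError("table_nt must come from a non-transcribed-strand assay")
    nt["as_read"] = nt.apply(_as_read_class, axis=1, read_strand=NON_TRANSCRIBED)
    artifact = nt["as_read"].isin(ARTIFACT_CLASSES)
    nt["source_strand"] = NON_TRANSCRIBED
    nt["masked"] = False
    if table_t is None:
        nt.loc[artifact, "masked"] = True
        return nt.drop(columns=["as_read"])
    if table_t.amplicon.read_strand != TRANSCRIBED:
        raise ValueError("table_t must come from a transcribed-strand assay")
    t = table_t.data.set_index(_KEY_COLS)
    nt_idx = nt.set_index(_KEY_COLS)
    missing = nt_idx.index.difference(t.index)
    if len(missing):
        raise ValueError("opposite-strand table does not cover the same key space")
    for col in ("n_families", "total_families", "mf", "mf_corrected"):
        nt_idx.loc[artifact.values, col] = t.loc[nt_idx.index[artifact.values], col].values
    nt_idx.loc[artifact.values, "source_strand"] = TRANSCRIBED
    return nt_idx.reset_index().drop(columns=["as_read"])


def tidy_export(table: FrequencyTable) -> pd.DataFrame:
    """Long-format TSV-ready view with sample metadata columns."""
    df = table.data.copy()
    df.insert(0, "sample", table.sample_id)
    df.insert(1, "treatment", table.meta.treatment)
    df.insert(2, "tissue", table.meta.tissue)
    df.insert(3, "week", table.meta.week)
    df.insert(4, "read_strand", table.amplicon.read_strand)
    return df
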