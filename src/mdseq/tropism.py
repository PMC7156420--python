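"""Strand-asymmetry summaries and the expression-quartile bias analysis.

Urethane's signature CAN>CTN transversions accumulate preferentially on the
non-transcribed strand of expressed genes.  Two views of that asymmetry:

* :func:`strand_bias_summary` — within one MDS assay, the mean corrected
  frequency over the positions belonging to a trinucleotide class versus
  its reverse-complement class (e.g. CAN>CTN vs NTG>NAG as read), averaged
  across samples (mean +/- SEM).
* :func:`expression_quartile_bias` — over exome-wide mutation tables, genes
  are ranked by mean FPKM, split into quartiles, and CAN>CTN counts are
  summed per tumor, per quartile and per annotated strand; the cohort
  mean +/- SEM per quartile/strand is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frequency import FrequencyTable


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


@dataclass
class StrandBiasSummary:
    per_class: pd.DataFrame  # class, mean, sem, n_samples, n_positions


def strand_bias_summary(
    tables: Sequence[FrequencyTable],
    class_pair: tuple[str, str] = ("CAN>CTN", "NTG>NAG"),
) -> StrandBiasSummary:
    """Per-class position-averaged frequencies, mean +/- SEM across samples.

    The first class of the pair is matched against the 5'-anchored
    trinucleotide pattern of each key (as stored, i.e. as read on the
    amplicon's coding-strand representation), the second against the
    3'-anchored pattern — the orientation in which the reverse-complement
    class appears in the same assay.
    """
    if not tables:
        raise ValueError("no samples")
    amp_names = {t.amplicon.name for t in tables}
    if len(amp_names) > 1:
        raise ValueError("samples span multiple amplicons")
    rows = []
    for cls, col in zip(class_pair, ("tri_class", "tri3_class")):
        per_sample = []
        n_positions = 0
        for t in tables:
            sel = t.data[t.data[col] == cls]
            n_positions = sel["cdna_pos"].nunique()
            if len(sel) == 0:
                continue
            per_sample.append(sel["mf_corrected"].mean())
        if n_positions == 0:
            rows.append({"class": cls, "mean": np.nan, "sem": np.nan,
                         "n_samples": 0, "n_positions": 0})
            continue
        vals = np.array(per_sample)
        rows.append(
            {
                "class": cls,
                "mean": float(vals.mean()),
                "sem": _sem(vals),
                "n_samples": len(vals),
                "n_positions": n_positions,
            }
        )
    return StrandBiasSummary(per_class=pd.DataFrame(rows))


@dataclass
class ExpressionBinTable:
    gene_quartile: pd.DataFrame  # gene, mean_fpkm, quartile (1..4)
    per_tumor: pd.DataFrame  # tumor, quartile, strand, count
    summary: pd.DataFrame  # quartile, strand, mean, sem, n_tumors
    dropped_genes: list[str]


def assign_quartiles(expression: pd.DataFrame) -> pd.DataFrame:
    """Quartile assignment by mean FPKM (1 = lowest expression).

    Stable sort on (mean FPKM, gene id); equal-size bins with any remainder
    going to the lower quartiles, so sizes differ by at most one.
    """
    fpkm_cols = [c for c in expression.columns if c.startswith("fpkm")]
    if not fpkm_cols:
        raise ValueError("expression table has no fpkm_* columns")
    if len(expression) < 4:
        raise ValueError("need >= 4 genes to define quartiles")
    df = expression.copy()
    df["mean_fpkm"] = df[fpkm_cols].mean(axis=1)
    df = df.sort_values(["mean_fpkm", "gene"], kind="stable").reset_index(drop=True)
    parts = np.array_split(np.arange(len(df)), 4)
    q = np.empty(len(df), dtype=int)
    for i, idx in enumerate(parts, start=1):
        q[idx] = i
    df["quartile"] = q
    return df[["gene", "mean_fpkm", "quartile"]]


def expression_quartile_bias(
    expression: pd.DataFrame,
    mutations: pd.DataFrame,
    mutation_class: str = "CAN>CTN",
) -> ExpressionBinTable:
    """Strand-wise mutation burden per expression quartile.

    ``expression``: gene, fpkm_rep1..K.  ``mutations``: tumor, gene, strand,
    class, count (strand relative to each gene's annotated coding strand).
    Mutation records for genes without expression data are dropped and
    reported.
    """
    gq = assign_quartiles(expression)
    muts = mutations[mutations["class"] == mutation_class].copy()
    known = muts["gene"].isin(set(gq["gene"]))
    dropped = sorted(muts.loc[~known, "gene"].unique())
    muts = muts[known]
    merged = muts.merge(gq[["gene", "quartile"]], on="gene", how="left")

    tumors = sorted(mutations["tumor"].unique())
    strands = sorted(mutations["strand"].unique()) or ["non_transcribed", "transcribed"]
    full_index = pd.MultiIndex.from_product(
        [tumors, [1, 2, 3, 4], strands], names=["tumor", "quartile", "strand"]
    )
    per_tumor = (
        merged.groupby(["tumor", "quartile", "strand"])["count"]
        .sum()
        .reindex(full_index, fill_value=0)
        .reset_index()
    )
    summary = (
        per_tumor.groupby(["quartile", "strand"])["count"]
        .agg(mean="mean", sem=lambda v: _sem(np.asarray(v)), n_tumors="size")
        .reset_index()
    )
    return ExpressionBinTable(
        gene_quartile=gq, per_tumor=per_tumor, summary=summary, dropped_genes=dropped
    )
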