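"""Poisson-corrected mutant allele fraction from droplet digital PCR counts.

Droplets receive template molecules at random, so the fraction of positive
droplets underestimates concentration once co-occupancy becomes likely.
With ``n`` total droplets, ``nmu`` mutant-probe-positive droplets and
``ndna`` droplets positive for mutant and/or wild-type probe, Poisson
occupancy gives

    Mmu      = -ln(1 - nmu/n)        (mutant copies per droplet)
    MDNAconc = -ln(1 - ndna/n)       (total template copies per droplet)
    MAF      = Mmu / MDNAconc        (mutant allele fraction)

Multiple wells of one sample are pooled by summing droplet counts before
the transform, the maximum-likelihood combination when the wells share one
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class DdpcrWell:
    """Droplet counts from one well."""

    n: int  # total droplets
    nmu: int  # droplets positive for the mutant probe
    ndna: int  # droplets positive for mutant and/or wild-type probe

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("a well must contain droplets")
        if not 0 <= self.nmu <= self.ndna <= self.n:
            raise ValueError(
                f"inconsistent droplet counts: need 0 <= nmu ({self.nmu}) "
                f"<= ndna ({self.ndna}) <= n ({self.n})"
            )


@dataclass(frozen=True)
class MafResult:
    mmu: float  # mutant copies per droplet
    mdnaconc: float  # total copies per droplet
    maf: float  # mutant allele fraction
    n_wells: int = 1


class DdpcrError(ValueError):
    pass


def _poisson_conc(positive: int, total: int) -> float:
    return -math.log(1.0 - positive / total)


def poisson_maf(
    wells: DdpcrWell | Sequence[DdpcrWell],
    pooling: str = "sum_droplets",
) -> MafResult:
    """Mutant allele fraction from one or more wells of the same sample."""
    if isinstance(wells, DdpcrWell):
        wells = [wells]
    if not wells:
        raise DdpcrError("no wells supplied")
    if pooling != "sum_droplets":
        raise DdpcrError(f"unknown pooling mode {pooling!r}")
    n = sum(w.n for w in wells)
    nmu = sum(w.nmu for w in wells)
    ndna = sum(w.ndna for w in wells)
    if ndna == n:
        raise DdpcrError("saturated: every droplet is DNA-positive, concentration undefined")
    if ndna == 0:
        raise DdpcrError("no template: no DNA-positive droplets")
    mmu = _poisson_conc(nmu, n)
    mdna = _poisson_conc(ndna, n)
    return MafResult(mmu=mmu, mdnaconc=mdna, maf=mmu / mdna, n_wells=len(wells))


def maf_table(wells_df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample pooled MAF from a (sample, well, n, nmu, ndna) table.

    Per-well estimates are included alongside the pooled value.
    """
    rows = []
    for sample, grp in wells_df.groupby("sample", sort=True):
        wells = [DdpcrWell(int(r.n), int(r.nmu), int(r.ndna)) for r in grp.itertuples()]
        pooled = poisson_maf(wells)
        rows.append(
            {
                "sample": sample,
                "well": "pooled",
                "mmu": pooled.mmu,
                "mdnaconc": pooled.mdnaconc,
                "maf": pooled.maf,
            }
        )
        for r, w in zip(grp.itertuples(), wells):
            try:
                res = poisson_maf(w)
            except DdpcrError:
                continue
            rows.append(
                {"sample": sample, "well": str(r.well), "mmu": res.mmu,
                 "mdnaconc": res.mdnaconc, "maf": res.maf}
            )
    return pd.DataFrame(rows)
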