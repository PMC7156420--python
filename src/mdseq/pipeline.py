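"""End-to-end orchestration: FASTQ -> calls -> frequencies -> report.

The pipeline stages are the library functions of :mod:`mdseq.reads`,
:mod:`mdseq.families` and :mod:`mdseq.frequency`; this module wires them
together, enforces the sample-level barcode QC, and emits an auditable JSON
report carrying per-stage counts and every effective threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import families, frequency, io, reads, simulate
from ._codes import encode
from .families import CallParams, call_families, sample_qc
from .refmodel import MutationKey, ReferenceAmplicon

logger = logging.getLogger("mdseq")


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Input data unusable at run time (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run; defaults are the
    published thresholds and are echoed verbatim into the run report."""

    amplicon: ReferenceAmplicon
    layout: reads.LayoutSpec
    mode: str = "carcinogen"
    min_size_carcinogen: int = 3
    min_size_spikein: int = 2
    agreement: float = 0.90
    qc_threshold: float = families.SAMPLE_QC_THRESHOLD
    correction: float = frequency.DETECTION_LIMIT
    quality_min_frac: float = 0.90
    quality_min_q: int = 20
    spikein_mutations: tuple[MutationKey, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("carcinogen", "spikein"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "spikein" and not self.spikein_mutations:
            raise ConfigError("spikein mode requires spikein_mutations")

    @property
    def call_params(self) -> CallParams:
        return CallParams(
            min_size_carcinogen=self.min_size_carcinogen,
            min_size_spikein=self.min_size_spikein,
            agreement=self.agreement,
        )

    def effective_parameters(self) -> dict:
        return {
            "amplicon": self.amplicon.name,
            "mode": self.mode,
            "min_size_carcinogen": self.min_size_carcinogen,
            "min_size_spikein": self.min_size_spikein,
            "agreement": self.agreement,
            "qc_threshold": self.qc_threshold,
            "correction": self.correction,
            "quality_min_frac": self.quality_min_frac,
            "quality_min_q": self.quality_min_q,
            "spikein_mutations": [k.label for k in self.spikein_mutations],
        }


def parse_mutation_label(label: str, amplicon: ReferenceAmplicon) -> MutationKey:
    """Parse coding-strand notation like ``"A182>T"`` into a full key."""
    try:
        left, alt = label.split(">")
        ref, pos = left[0], int(left[1:])
    except (ValueError, IndexError) as err:
        raise ConfigError(f"cannot parse mutation label {label!r}") from err
    if amplicon.coding_base(pos) != ref:
        raise ConfigError(
            f"{label}: reference base at cDNA {pos} is {amplicon.coding_base(pos)}"
        )
    return amplicon.mutation_key(pos, alt)


def _status_counts(calls: pd.DataFrame) -> dict[str, int]:
    return {k: int(v) for k, v in calls["status"].value_counts().items()}


def run_pipeline(
    config: RunConfig,
    fastq: str | Path,
    fastq2: str | Path | None = None,
    out_dir: str | Path | None = None,
    merge_min_overlap: int = 10,
    merge_max_mismatch_frac: float = 0.1,
) -> dict:
    """Run FASTQ -> calls -> frequencies; returns the run report dict.

    With ``fastq2`` given, pairs are merged first; otherwise reads are
    treated as pre-merged/single-end.  Samples failing the barcode-count QC
    are excluded from frequency tables but reported.  Deterministic for
    fixed inputs and configuration.
    """
    record_stream = reads.parse_fastq(fastq)
    merge_counts = {"pairs_in": 0, "merge_fail": 0}
    if fastq2 is not None:
        def merged():
            for r1, r2 in zip(reads.parse_fastq(fastq), reads.parse_fastq(fastq2)):
                merge_counts["pairs_in"] += 1
                try:
                    yield reads.merge_pairs(
                        r1, r2, min_overlap=merge_min_overlap,
                        max_mismatch_frac=merge_max_mismatch_frac,
                    )
                except reads.ReadRejected:
                    merge_counts["merge_fail"] += 1
        record_stream = merged()

    processed = reads.process_reads(
        record_stream, config.layout,
        min_frac=config.quality_min_frac, min_q=config.quality_min_q,
    )
    if processed.counts["reads_in"] == 0:
        raise DataError(f"no reads in {fastq}")

    report: dict = {
        "parameters": config.effective_parameters(),
        "read_counts": {**merge_counts, **processed.counts},
        "samples": {},
    }
    out = Path(out_dir) if out_dir is not None else None
    for sample, records in processed.by_sample.items():
        if not records:
            report["samples"][sample] = {"n_records": 0, "qc_pass": False}
            continue
        fams = families.group_by_barcode(records)
        barcodes = np.array([f.barcode for f in fams for _ in f.members], dtype=object)
        codes = np.stack([encode(m) for f in fams for m in f.members])
        calls = call_families(
            barcodes, codes, config.mode, config.amplicon,
            params=config.call_params, spikein_mutations=config.spikein_mutations,
        )
        n_families = len(calls)
        qc_pass = sample_qc(n_families, config.qc_threshold)
        entry = {
            "n_records": len(records),
            "n_families": n_families,
            "n_families_min_size": int(
                (calls["size"] >= (config.min_size_carcinogen
                                   if config.mode == "carcinogen"
                                   else config.min_size_spikein)).sum()
            ),
            "status_counts": _status_counts(calls),
            "qc_pass": bool(qc_pass),
        }
        report["samples"][sample] = entry
        if out is not None:
            io.write_tsv(calls, out / f"{sample}.calls.tsv")
            io.write_tsv(families.family_size_histogram(calls), out / f"{sample}.famsize.tsv")
        if qc_pass and config.mode == "carcinogen":
            table = frequency.compute_frequencies(
                calls, n_families, config.amplicon,
                sample_id=sample, correction=config.correction,
            )
            if out is not None:
                io.write_tsv(frequency.tidy_export(table), out / f"{sample}.frequencies.tsv")
        logger.info(json.dumps({"stage": "sample_done", "sample": sample, **{
            k: v for k, v in entry.items() if k != "status_counts"}}))

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


@dataclass
class BenchmarkResult:
    table: pd.DataFrame  # present_frequency, detected_frequency, ratio, flags


def run_benchmark(
    dilution_series: Sequence[float],
    amplicon: ReferenceAmplicon,
    spikein_mutations: Sequence[MutationKey],
    n_templates: int = 100_000,
    seed: int = 0,
    params: CallParams | None = None,
    **sim_kwargs,
) -> BenchmarkResult:
    """Spike-in dilution series: detected vs present frequency per level.

    For every dilution a library is simulated with the engineered 2-3
    co-occurring mutations at that template frequency, processed, and
    called in spike-in mode.  ``present`` is the manifest truth
    (mutant families / total families); ``detected`` is the caller's
    SPIKEIN family count over total families.  Levels whose expected mutant
    family count is below one are flagged ``sub_poisson`` but still run.
    """
    params = params or CallParams()
    rows = []
    for level_idx, freq in enumerate(dilution_series):
        design = simulate.SpikeInDesign(
            mutations=tuple(spikein_mutations), present_frequency=freq
        )
        config = simulate.SimulationConfig(
            amplicon=amplicon,
            n_templates=n_templates,
            spikeins=(design,),
            seed=seed + level_idx,
            **sim_kwargs,
        )
        readset, manifest = simulate.simulate_library(config)
        layout = reads.LayoutSpec(
            index_assignments=config.index_assignments,
            primer=config.primer,
            target_len=amplicon.length,
            barcode_len=config.barcode_len,
        )
        processed = reads.process_simulated(readset, layout)
        barcodes = np.concatenate(
            [b for b, _ in processed.by_sample.values()]
        )
        codes = np.concatenate([c for _, c in processed.by_sample.values()])
        calls = call_families(
            barcodes, codes, "spikein", amplicon,
            params=params, spikein_mutations=design.mutations,
        )
        n_fam = len(calls)
        detected = int((calls["status"] == "SPIKEIN").sum()) / n_fam if n_fam else np.nan
        present = simulate.manifest_present_frequency(manifest, design)
        rows.append(
            {
                "present_frequency": present,
                "detected_frequency": detected,
                "nominal_frequency": freq,
                "ratio": detected / present if present else np.nan,
                "n_families": n_fam,
                "sub_poisson": freq * n_templates < 1,
            }
        )
    return BenchmarkResult(table=pd.DataFrame(rows))
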