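"""Seeded generative models for every input the pipeline consumes.

The library simulator follows the two facts MDS exploits: a true mutation is
present on the template before barcoding and therefore appears in *every*
read of its barcode family, whereas amplification and sequencing errors do
not.  Amplification is modelled in two stages rather than as a full
branching PCR:

* each template receives ``Poisson(lambda_linear)`` (truncated at >= 1)
  linear copies; each copy independently acquires substitution errors at
  ``p_linear_error`` per base, and those errors are inherited by exactly the
  reads descending from that copy;
* each template yields ``Poisson(lambda_reads)`` sequenced reads, each read
  picking its ancestral linear copy uniformly and then acquiring independent
  sequencing errors at ``p_seq_error`` per base.

Reads are emitted in the MDS layout ``[sample index][14-nt barcode]
[gene-specific primer][target]`` with Phred+33 qualities.  Per-base
qualities for the target are drawn from a clipped normal quality model and
are independent of where errors land (downstream filters use them only as
thresholds); the technical prefix is emitted at a fixed Q40.

Identical config + seed gives byte-identical FASTQ output and manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._codes import COMP, decode, decode_rows, encode
from .ddpcr import DdpcrWell
from .refmodel import NON_TRANSCRIBED, MutationKey, ReferenceAmplicon

DEFAULT_BARCODE_LEN = 14
DEFAULT_PRIMER = "TGACCATGATTACGCCAAGC"


@dataclass(frozen=True)
class SpikeInDesign:
    """Engineered template with 2-3 co-occurring substitutions.

    Co-occurrence is what makes spike-ins countable independently of the
    caller: PCR/sequencing errors essentially never reproduce the same
    2-3 exact base changes together.
    """

    mutations: tuple[MutationKey, ...]
    present_frequency: float

    def __post_init__(self) -> None:
        if not 2 <= len(self.mutations) <= 3:
            raise ValueError("spike-in designs carry 2-3 co-occurring mutations")
        if not 0 < self.present_frequency <= 1:
            raise ValueError("present_frequency must be in (0, 1]")

    @property
    def label(self) -> str:
        return ";".join(sorted(k.label for k in self.mutations))


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic MDS library."""

    amplicon: ReferenceAmplicon
    n_templates: int
    barcode_len: int = DEFAULT_BARCODE_LEN
    index_assignments: dict[str, str] = field(default_factory=lambda: {"sample1": "ACGT"})
    primer: str = DEFAULT_PRIMER
    spikeins: tuple[SpikeInDesign, ...] = ()
    background_mutations: tuple[tuple[MutationKey, float], ...] = ()
    lambda_linear: float = 10.0
    p_linear_error: float = 1e-5
    lambda_reads: float = 6.0
    p_seq_error: float = 1e-3
    quality_mean: float = 35.0
    quality_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")
        for p in (self.p_linear_error, self.p_seq_error):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must be in [0, 1]")
        if self.lambda_linear <= 0 or self.lambda_reads <= 0:
            raise ValueError("amplification rates must be > 0")
        idx = list(self.index_assignments.values())
        if len(set(idx)) != len(idx):
            raise ValueError("sample indexes must be unique")
        for s in idx:
            if not 0 <= len(s) <= 7:
                raise ValueError("sample indexes are 0-7 nt")


@dataclass
class SimulatedReads:
    """In-memory read set; ``to_fastq`` renders the canonical FASTQ bytes."""

    samples: np.ndarray  # per-read sample id (str)
    barcodes: np.ndarray  # per-read barcode (str)
    target_codes: np.ndarray  # (R, L) uint8
    target_quals: np.ndarray  # (R, L) uint8 Phred
    index_assignments: dict[str, str]
    primer: str

    PREFIX_Q = 40  # fixed quality emitted for the technical prefix

    def __len__(self) -> int:
        return self.target_codes.shape[0]

    def read_sequence(self, i: int) -> str:
        return (
            self.index_assignments[self.samples[i]]
            + self.barcodes[i]
            + self.primer
            + decode(self.target_codes[i])
        )

    def read_qualities(self, i: int) -> list[int]:
        npre = len(self.index_assignments[self.samples[i]]) + len(self.barcodes[i]) + len(self.primer)
        return [self.PREFIX_Q] * npre + [int(q) for q in self.target_quals[i]]

    def to_fastq(self, path: str | Path | None = None) -> bytes | None:
        """Write (or return) Phred+33 FASTQ for the whole read set."""
        targets = decode_rows(self.target_codes)
        qual_ascii = (self.target_quals + 33).astype(np.uint8)
        L = self.target_codes.shape[1]
        raw_q = qual_ascii.tobytes()
        chunks = []
        for i in range(len(self)):
            prefix = self.index_assignments[self.samples[i]] + self.barcodes[i] + self.primer
            seq = prefix + targets[i]
            qual = chr(self.PREFIX_Q + 33) * len(prefix) + raw_q[i * L : (i + 1) * L].decode()
            chunks.append(f"@read{i}\n{seq}\n+\n{qual}\n")
        blob = "".join(chunks).encode()
        if path is None:
            return blob
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_bytes(blob)
        return None


def _truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    out = rng.poisson(lam, n)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, int(zero.sum()))
        zero = out == 0
    return out


def _barcode_strings(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    return np.array(decode_rows(codes), dtype=object)


def _read_position(amplicon: ReferenceAmplicon, key: MutationKey) -> tuple[int, int]:
    """(0-based read position, read-orientation alt code) for a coding key."""
    if amplicon.coding_base(key.cdna_pos) != key.ref_base:
        raise ValueError(
            f"spike-in/background key {key.label} does not match the reference "
            f"base {amplicon.coding_base(key.cdna_pos)} at cDNA {key.cdna_pos}"
        )
    rp = amplicon.cdna_to_read(key.cdna_pos) - 1
    alt_read = amplicon.read_base_for(key.cdna_pos, key.alt_base)
    return rp, int(encode(alt_read)[0])


def simulate_library(config: SimulationConfig) -> tuple[SimulatedReads, pd.DataFrame]:
    """Simulate one barcoded MDS library.

    Returns the read set and a truth manifest with one row per template:
    ``template_id, sample, barcode, mutations, n_reads`` (``mutations`` is a
    ';'-joined list of coding-strand labels, empty for wild type).
    """
    rng = np.random.default_rng(config.seed)
    amp = config.amplicon
    N = config.n_templates
    L = amp.length
    ref = encode(amp.sequence)

    # -- templates ---------------------------------------------------------
    templates = np.tile(ref, (N, 1))
    mut_labels: dict[int, list[str]] = {}
    available = np.arange(N)
    rng.shuffle(available)
    cursor = 0
    for design in config.spikeins:
        expected = design.present_frequency * N
        n_mut = int(round(expected))
        if expected < 1:
            warnings.warn(
                f"spike-in {design.label}: expected mutant template count "
                f"{expected:.3g} is below one",
                stacklevel=2,
            )
        chosen = available[cursor : cursor + n_mut]
        cursor += n_mut
        for key in design.mutations:
            rp, alt = _read_position(amp, key)
            templates[chosen, rp] = alt
        for t in chosen:
            mut_labels.setdefault(int(t), []).extend(k.label for k in design.mutations)
    for key, prob in config.background_mutations:
        rp, alt = _read_position(amp, key)
        hit = np.flatnonzero(rng.random(N) < prob)
        templates[hit, rp] = alt
        for t in hit:
            mut_labels.setdefault(int(t), []).append(key.label)

    # -- barcodes, samples, family sizes -----------------------------------
    barcodes = _barcode_strings(rng, N, config.barcode_len)
    sample_names = np.array(list(config.index_assignments), dtype=object)
    tmpl_sample = sample_names[rng.integers(0, len(sample_names), N)]
    n_reads = rng.poisson(config.lambda_reads, N)
    R = int(n_reads.sum())
    tid = np.repeat(np.arange(N), n_reads)

    reads = templates[tid]

    # -- linear-copy errors (family-consistent within a copy's descendants) --
    if config.p_linear_error > 0 and R > 0:
        n_copies = _truncated_poisson(rng, config.lambda_linear, N)
        copy_of_read = (rng.random(R) * n_copies[tid]).astype(np.int64)
        pair = tid.astype(np.int64) * (int(n_copies.max()) + 1) + copy_of_read
        uniq, inverse = np.unique(pair, return_inverse=True)
        n_events = rng.binomial(len(uniq) * L, config.p_linear_error)
        if n_events:
            order = np.argsort(inverse, kind="stable")
            offsets = np.zeros(len(uniq) + 1, dtype=np.int64)
            np.cumsum(np.bincount(inverse, minlength=len(uniq)), out=offsets[1:])
            ev_copy = rng.integers(0, len(uniq), n_events)
            ev_pos = rng.integers(0, L, n_events)
            ev_shift = rng.integers(1, 4, n_events).astype(np.uint8)
            for c, p, s in zip(ev_copy, ev_pos, ev_shift):
                rows = order[offsets[c] : offsets[c + 1]]
                reads[rows, p] = (reads[rows, p] + s) % 4

    # -- independent sequencing errors --------------------------------------
    if config.p_seq_error > 0 and R > 0:
        n_err = rng.binomial(R * L, config.p_seq_error)
        if n_err:
            flat = rng.integers(0, R * L, n_err)
            shift = rng.integers(1, 4, n_err).astype(np.uint8)
            reads.flat[flat] = (reads.flat[flat] + shift) % 4

    quals = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd, size=(R, L))), 2, 40
    ).astype(np.uint8)

    perm = rng.permutation(R)
    readset = SimulatedReads(
        samples=tmpl_sample[tid][perm],
        barcodes=barcodes[tid][perm],
        target_codes=reads[perm],
        target_quals=quals[perm],
        index_assignments=dict(config.index_assignments),
        primer=config.primer,
    )

    manifest = pd.DataFrame(
        {
            "template_id": np.arange(N),
            "sample": tmpl_sample,
            "barcode": barcodes,
            "mutations": [
                ";".join(sorted(mut_labels.get(i, []))) for i in range(N)
            ],
            "n_reads": n_reads,
        }
    )
    return readset, manifest


def manifest_present_frequency(manifest: pd.DataFrame, design: SpikeInDesign) -> float:
    """Ground-truth mutant-family fraction among templates with >= 1 read."""
    seen = manifest[manifest["n_reads"] > 0]
    if len(seen) == 0:
        return float("nan")
    return float((seen["mutations"] == design.label).sum() / len(seen))


def simulate_ddpcr_well(
    n_droplets: int,
    mutant_conc: float,
    total_conc: float,
    seed: int | np.random.Generator = 0,
) -> DdpcrWell:
    """Sample one ddPCR well under Poisson droplet occupancy.

    ``mutant_conc``/``total_conc`` are in copies per droplet.  A droplet is
    mutant-positive if it received >= 1 mutant copy and DNA-positive if it
    received >= 1 copy of either species.
    """
    if mutant_conc < 0 or total_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if mutant_conc > total_conc:
        raise ValueError("mutant concentration cannot exceed total concentration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mut = rng.poisson(mutant_conc, n_droplets)
    wt = rng.poisson(total_conc - mutant_conc, n_droplets)
    return DdpcrWell(
        n=n_droplets,
        nmu=int((mut >= 1).sum()),
        ndna=int(((mut + wt) >= 1).sum()),
    )


def linear_strand_rates(rank_frac: float) -> tuple[float, float]:
    """Default expression-dependent CAN>CTN rates per gene per tumor.

    Emulates transcription-coupled asymmetry: the non-transcribed strand
    rate rises with expression rank while the transcribed strand rate falls.
    """
    return 0.05 + 0.30 * rank_frac, 0.35 - 0.30 * rank_frac


def simulate_expression_wes(
    n_genes: int = 2000,
    n_tumors: int = 66,
    strand_rate_model: Callable[[float], tuple[float, float]] = linear_strand_rates,
    seed: int = 0,
    n_reps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic FPKM replicates plus per-tumor strand-wise mutation counts.

    Returns ``(expression, mutations, truth)``:

    * expression — gene, fpkm_rep1..repK (log-normal noise around a
      log-normal true level);
    * mutations — tumor, gene, strand, class, count (Poisson counts of
      CAN>CTN events per gene/strand/tumor; zero-count rows omitted);
    * truth — gene, rank_frac and the generating per-strand rates.
    """
    if n_genes < 4:
        raise ValueError("need >= 4 genes to define expression quartiles")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    true_level = 10 ** rng.normal(1.0, 1.0, n_genes)
    rank = np.empty(n_genes, dtype=np.int64)
    rank[np.argsort(true_level, kind="stable")] = np.arange(n_genes)
    rank_frac = rank / (n_genes - 1)

    expr = {"gene": genes}
    for k in range(n_reps):
        expr[f"fpkm_rep{k + 1}"] = true_level * np.exp(rng.normal(0, 0.2, n_genes))
    expr_df = pd.DataFrame(expr)

    rates = np.array([strand_rate_model(f) for f in rank_frac])  # (n_genes, 2)
    if (rates < 0).any():
        raise ValueError("strand_rate_model produced a negative rate")
    rows = []
    strands = ("non_transcribed", "transcribed")
    for t in range(n_tumors):
        counts = rng.poisson(rates)  # (n_genes, 2)
        for s_i, strand in enumerate(strands):
            nz = np.flatnonzero(counts[:, s_i])
            for g in nz:
                rows.append((f"tumor{t:03d}", genes[g], strand, "CAN>CTN", int(counts[g, s_i])))
    mut_df = pd.DataFrame(rows, columns=["tumor", "gene", "strand", "class", "count"])
    truth = pd.DataFrame(
        {
            "gene": genes,
            "rank_frac": rank_frac,
            "rate_non_transcribed": rates[:, 0],
            "rate_transcribed": rates[:, 1],
        }
    )
    return expr_df, mut_df, truth
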