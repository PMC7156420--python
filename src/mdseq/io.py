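"""Loading amplicon references and tabular exports.

The package ships a small synthetic Ras reference set (FASTA + YAML) whose
sequences carry the documented hotspot features; users can point the same
loaders at their own files.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .refmodel import MutationKey, ReferenceAmplicon, build_variant_library, classify_substitution


def load_amplicons(fasta: str | Path | None = None,
                   config: str | Path | None = None) -> dict[str, ReferenceAmplicon]:
    """Load amplicon definitions; defaults to the bundled synthetic set."""
    if fasta is None or config is None:
        data = resources.files("mdseq") / "data"
        fasta = fasta or data / "synthetic_refs.fasta"
        config = config or data / "amplicons.yaml"
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    with open(config) as fh:
        meta = yaml.safe_load(fh)
    out = {}
    for entry in meta["amplicons"]:
        name = entry["name"]
        if name not in seqs:
            raise KeyError(f"amplicon {name} missing from {fasta}")
        out[name] = ReferenceAmplicon(
            name=name,
            gene=entry["gene"],
            exon=int(entry["exon"]),
            read_strand=entry["read_strand"],
            sequence=seqs[name],
            cdna_start=int(entry["cdna_start"]),
        )
    return out


def key_record(key: MutationKey) -> dict:
    """Flatten a MutationKey plus its class labels into one table row."""
    cls = classify_substitution(key)
    return {
        "cdna_pos": key.cdna_pos,
        "ref": key.ref_base,
        "alt": key.alt_base,
        "context5": key.context5 or "",
        "context3": key.context3 or "",
        "codon_index": key.codon_index if key.codon_index is not None else -1,
        "aa_change": key.aa_change or "",
        "substitution_class": cls["substitution"],
        "tri_class": cls["tri_class"],
        "tri3_class": cls["tri3_class"],
        "complement_class": cls["complement_class"],
    }


def variant_library_table(amplicon: ReferenceAmplicon) -> pd.DataFrame:
    """TSV-ready table of the full single-substitution variant library."""
    rows = []
    for _, key in build_variant_library(amplicon):
        row = {"name": amplicon.name}
        row.update(key_record(key))
        rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
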