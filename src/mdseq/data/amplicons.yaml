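# Bundled amplicon definitions for the synthetic Ras reference set.
# Sequences live in synthetic_refs.fasta (read orientation).  These are
# synthetic stand-ins carrying the documented hotspot features (GGT at
# cDNA 34-36, GGC at 37-39, CAA at 181-183); they are not the real murine
# exon sequences.
amplicons:
  - name: kras_ex1_nt
    gene: Kras
    exon: 1
    read_strand: non_transcribed
    cdna_start: 1
  - name: kras_ex1_t
    gene: Kras
    exon: 1
    read_strand: transcribed
    cdna_start: 111
  - name: kras_ex2_nt
    gene: Kras
    exon: 2
    read_strand: non_transcribed
    cdna_start: 151
  - name: kras_ex2_t
    gene: Kras
    exon: 2
    read_strand: transcribed
    cdna_start: 240
  - name: hras_ex2_nt
    gene: Hras
    exon: 2
    read_strand: non_transcribed
    cdna_start: 151
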