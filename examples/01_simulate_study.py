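"""Generate a self-contained toy study and write it to disk.

The bundle holds a genome, multi-exon gene models on both strands, an
exactly consistent proteome, SCE tables at the three detection resolutions
(9/15/30 codons), an SFBS site table, DisProt-style region annotations, and
ground-truth structural tracks in the external predictors' file dialects.
"""
import tempfile
from pathlib import Path

from scestruct.synthetic_data import SyntheticConfig, generate_study, write_bundle

config = SyntheticConfig(n_genes=50, sce_counts={9: 50, 15: 50, 30: 50}, seed=7)
bundle = generate_study(config)

outdir = Path(tempfile.mkdtemp(prefix="scestruct_study_"))
paths = write_bundle(bundle, outdir)

print(f"study written to {outdir}")
print(f"chromosomes: { {c: len(s) for c, s in bundle.genome.items()} }")
print(f"transcripts: {len(bundle.transcripts)} "
      f"(canonical proteome: {len(bundle.proteome)} proteins)")
for w, records in sorted(bundle.sce_records.items()):
    multi = sum(len(r.intervals) > 1 for r in records)
    print(f"SCEs at {w}-codon resolution: {len(records)} "
          f"({multi} cross an exon junction)")
print(f"SFBS sites: {len(bundle.sfbs_records)} "
      f"(incl. mutant/duplicate/length-edge/dual-frame special cases)")
print(f"DisProt-style annotated proteins: {len(bundle.disprot)}")
# Counts describe the planted world: every downstream number in the other
# examples is recomputed from these files or their in-memory equivalents.
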