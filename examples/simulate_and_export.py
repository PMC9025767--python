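"""Generate a ground-truthed synthetic genome and export standard files.

Writes FASTA (replicons), GFF3 (CDS with marker labels), a per-base
depth TSV and the truth table - the same formats the analysis commands
consume - into ./sim_out.
"""

from pathlib import Path

from repliconkit import (
    default_simulation,
    simulate_genome,
    simulate_reference,
    write_depth,
    write_gff,
    write_replicons,
)

spec = default_simulation(seed=42)
genome, truth = simulate_genome(spec)
reference = simulate_reference(spec)

outdir = Path("sim_out")
outdir.mkdir(exist_ok=True)
write_replicons(genome, outdir / "genome.fasta")
write_replicons(reference, outdir / "reference.fasta")
write_gff(genome.annotations, outdir / "genome.gff3",
          products=genome.annotation_products)
write_gff(reference.annotations, outdir / "reference.gff3")
write_depth(genome.coverage.values(), outdir / "depth.tsv")
truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

for rep in genome.replicons:
    print(f"{rep.id}: {rep.length_bp} bp, GC {rep.gc_percent:.1f}%")
print(f"\nwrote FASTA/GFF3/depth/truth to {outdir}/")

# The exported files can be fed back through the CLI, e.g.
#   repliconkit classify --fasta sim_out/genome.fasta ...
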