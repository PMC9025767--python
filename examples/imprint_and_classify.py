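"""Full chromid/plasmid classification of a simulated genome.

Generates a multipartite genome (host chromosome at GC 60%, an internal
reference genome at GC 66%), profiles codon-usage and tetranucleotide
imprints, screens marker genes, estimates copy numbers and applies the
four-criterion chromid rule.
"""

from repliconkit import (
    classify,
    copy_numbers,
    default_simulation,
    feature_complements,
    imprint_decision,
    report,
    simulate_genome,
    simulate_reference,
    summarize,
)

spec = default_simulation(seed=1)
genome, truth = simulate_genome(spec)
reference = simulate_reference(spec)

results = classify(
    genome,
    copy_numbers(genome),
    imprint_decision(genome, reference),
    feature_complements(genome),
)

print(report(results, genome).to_string(index=False))
print("\nsummary:", summarize(results))
print("truth:  ", dict(zip(truth["replicon_id"], truth["true_class"])))

# p_chromid passes all four criteria (parAB, <2 copies, chromosome-like
# GC and imprint) and is called a chromid; p_foreign fails the GC and
# imprint criteria (it carries the reference genome's signature) and
# p_highcopy fails partitioning and copy number - both are plasmids.
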