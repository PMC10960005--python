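"""Generate a toy RNA-seq benchmark with known intronic polyA truth.

Builds a 30-gene genome in which half the genes carry one intronic
polyadenylation (IPA) event — skipped (novel acceptor + terminal exon) or
composite (upstream exon extended into the intron) — with a canonical
AATAAA signal planted 15-30 nt upstream of every polyA site, then simulates
coordinate-sorted spliced paired-end alignments at 50X coverage.
"""

from ipaforge.simdata import SimConfig, make_toy_reference, simulate_alignments

cfg = SimConfig(n_genes=30, coverage=50, seed=1)
fasta, gtf, truth = make_toy_reference(cfg, "example_output/sim")
realized = simulate_alignments(truth, fasta, "example_output/sim/reads.bam", seed=1)

print(f"genome: {fasta} ({truth.genome_length:,} bp)")
print(f"annotation: {gtf} ({len(truth.genes)} genes)")
print(f"simulated fragments: {sum(realized.values()):,}")
print(f"\nplanted IPA events ({len(truth.ipa_genes())}):")
for g in truth.ipa_genes()[:8]:
    print(f"  {g.gene_id} {g.strand} {g.ipa.kind:<9} site={g.ipa.site:>7} "
          f"usage={g.ipa.usage:.2f}")
print("  ...")
# Each line is one gene's planted event: the genomic cleavage position and
# the fraction of that gene's transcripts ending there (the quantity the
# pipeline must recover).
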