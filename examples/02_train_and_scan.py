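"""Train the CNN polyA-site scanner and scan intronic regions.

The sequence module learns to tell 201-nt windows centered on annotated
polyA sites from random intergenic windows, then slides over every
non-overlapped intronic base to propose candidate IPA sites (threshold 0.5,
local maxima merged within 50 nt). Run 01_simulate_benchmark.py first.
"""

from ipaforge import (
    CnnConfig, build_sequence_training_set, load_annotation, load_genome,
    nonoverlapped_introns, scan_intronic_regions, train_polya_cnn,
)
from ipaforge.simdata import SimConfig, make_toy_reference

# a larger reference provides more annotated ends to learn from
fasta, gtf, _ = make_toy_reference(SimConfig(n_genes=300, seed=42), "example_output/cnn_ref")
genome, genes = load_genome(fasta), load_annotation(gtf)
windows = build_sequence_training_set(genes, genome, seed=3)
print(f"training windows: {len(windows)} ({int(windows.y.sum())} positive)")
cnn = train_polya_cnn(windows, config=CnnConfig(max_epochs=50), seed=7)
print(f"validation AUROC: {cnn.val_auroc_:.3f}")
cnn.save("example_output/cnn.npz")

genome = load_genome("example_output/sim/genome.fa")
genes = load_annotation("example_output/sim/annotation.gtf")
introns = nonoverlapped_introns(genes)
sites = scan_intronic_regions(cnn, genome, introns)
print(f"\nintronic regions scanned: {len(introns)} "
      f"({sum(r.end - r.start for r in introns):,} bases)")
print(f"candidate IPA sites: {len(sites)}")
# Candidates are deliberately permissive: genuine events among them are
# confirmed (and the rest rejected) by the read module in the next example.
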