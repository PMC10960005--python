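"""Confirm IPA events from read evidence, assemble isoforms, quantify usage.

The read module trains sample-specific random-forest classifiers on
annotation-derived terminal/internal/background exons of the same BAM,
accepts putative intronic terminal exons, assembles the IPA isoforms with a
truncated CDS, and estimates each event's relative usage (IPA TPM over gene
TPM). Run examples 01 and 02 first.
"""

import pysam

from ipaforge import load_annotation, load_genome, nonoverlapped_introns, scan_intronic_regions
from ipaforge.seqmodel import PolyACnn
from ipaforge.pipeline import assemble_and_annotate, detect_ipa_events
from ipaforge.isoform import ipa_usage, quantify, retained_cdr_fraction

genome = load_genome("example_output/sim/genome.fa")
genes = load_annotation("example_output/sim/annotation.gtf")
cnn = PolyACnn.load("example_output/cnn.npz")
sites = scan_intronic_regions(cnn, genome, nonoverlapped_introns(genes))

with pysam.AlignmentFile("example_output/sim/reads.bam") as bam:
    events, classifiers, _ = detect_ipa_events(bam, sites, genes, seed=1, min_per_class=5)
    for kind, clf in classifiers.items():
        print(f"{kind} classifier held-out AUROC: {clf.metrics['AUROC']:.3f}")
    isoforms = assemble_and_annotate(events, genes, genome)
    usage = ipa_usage(quantify(bam, genes, isoforms))

by_iso = dict(zip(usage["isoform_id"], usage["usage"]))
by_gene = {g.gene_id: g for g in genes}
print(f"\naccepted IPA events: {len(events)}")
print(f"{'gene':<6} {'kind':<9} {'site':>8} {'prob':>5} {'usage':>6} {'CDR':>5}")
for ev, iso in zip(events, isoforms):
    u = by_iso.get(iso.isoform_id, float("nan"))
    cdr = retained_cdr_fraction(iso, by_gene[ev.gene_id])
    print(f"{ev.gene_id:<6} {ev.kind:<9} {ev.site_pos:>8} {ev.probability:>5.2f} "
          f"{u:>6.2f} {cdr:>5.2f}")
# usage = the isoform's share of its gene's expression; CDR = the fraction
# of the gene's longest annotated coding region retained by the truncated
# isoform (0 means the IPA isoform is non-coding).
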