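# ipaforge

Identification, assembly and quantification of **intronic polyadenylation
(IPA)** events from conventional RNA-seq alignments.

Cleavage and polyadenylation inside an annotated intron truncates a
transcript, producing either a **composite** terminal exon (the upstream
exon extended from its donor splice site to the intronic polyA site) or a
**skipped** terminal exon (a novel exon from a new acceptor to the site).
Such isoforms often lose most of their coding region and are invisible to
3'UTR-focused APA tools, while dedicated 3'-end sequencing data remain
scarce. `ipaforge` recovers these events from ordinary bulk (or pooled
full-length single-cell) RNA-seq, for genomics researchers studying
alternative polyadenylation, transcript truncation, or condition-specific
isoform usage.

## Method at a glance

1. **Sequence module** — a small CNN over one-hot encoded 201-nt windows
   (A=[1,0,0,0], T=[0,1,0,0], G=[0,0,1,0], C=[0,0,0,1]),

   A_f = ReLU(W_f · S + b_f), ReLU(x) = max(0,x), M = max{A_k : k ∈ P},

   trained on annotated polyA sites vs intergenic windows, then slid over
   every non-overlapped intronic base; thresholded local maxima (merged
   within 50 nt) become candidate IPA sites.
2. **Read module** — per candidate, a region back to the closest upstream
   splice donor; putative skipped exons need ≥ 5 spliced reads ending in
   the region (novel acceptor by majority vote), composite exons ≥ 10
   unspliced donor-crossing reads. A sample-specific ensemble of ten
   random forests — trained on the sample's own annotated terminal /
   internal / background exons (80:20 split, held-out TNR/TPR/ACC/
   Precision/F1/MCC/AUROC reported) — accepts genuine terminal exons.
3. **Isoform module** — events are grafted onto the longest-CDS scaffold
   transcript, the CDS is truncated at the first in-frame stop codon, an
   augmented GTF is written, and a built-in equivalence-class EM
   quantifier (or an external Salmon `quant.sf` table) yields TPMs and

   IPA usage = x_ig / Σ_j x_jg

   per gene g, plus each isoform's retained coding-region fraction.
4. **Benchmark module** — 50-nt closest-site matching (Sensitivity =
   TP/Predefined, Precision = TP/(TP+FP)), |ΔPAU| usage-error summaries,
   polyA-signal frequencies/enrichment in 60-nt upstream windows, and
   nucleotide profiles; a seeded generator builds fully self-contained
   toy genomes with planted IPA truth and pre-aligned spliced reads.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

`examples/` holds four short scripts; each prints what it computes. Run in
order from the repository root's `examples/` directory:

```bash
python 01_simulate_benchmark.py   # toy genome + truth + 50X reads
python 02_train_and_scan.py       # train CNN, scan introns
python 03_detect_and_quantify.py  # confirm events, assemble, quantify
python 04_benchmark.py            # score against the planted truth
```

Output of the full run (seed 1):

```
training windows: 600 (300 positive)
validation AUROC: 0.980
intronic regions scanned: 89 (62,416 bases)
candidate IPA sites: 427

skipped classifier held-out AUROC: 1.000
composite classifier held-out AUROC: 1.000
accepted IPA events: 15
gene   kind          site  prob  usage   CDR
G001   skipped       6815  0.98   0.55  0.86
G002   skipped      10231  0.96   0.35  0.51
...
G029   composite   123704  0.81   0.29  0.44

sensitivity: 1.000  precision: 1.000 (15 TP of 15 predictions, 15 planted sites)
|dPAU|: median=0.042  fraction within 0.05/0.10/0.20 = 0.73/1.00/1.00
top upstream signals at predicted sites (vs intronic control):
  AATAAA  freq=0.933 control=0.033 p=2.34e-15
```

Reading this: the scanner proposes 427 permissive candidates across 62 kb
of intronic space; the read module confirms exactly the 15 planted events,
every reported site lands within 50 nt of its true cleavage position, the
estimated usage of each IPA isoform is typically within ~0.04 of the
planted fraction, and the canonical AATAAA signal is found upstream of
93% of calls versus 3% of random intronic positions.

A thin CLI wraps the same library calls:

```bash
ipaforge simulate --out sim --genes 30 --coverage 50 --seed 1
ipaforge seq-train --gtf ref.gtf --genome ref.fa --out cnn.npz
ipaforge seq-scan --model cnn.npz --gtf sim/annotation.gtf --genome sim/genome.fa --out candidates.bed
ipaforge detect --bam sim/reads_rep1.bam --gtf sim/annotation.gtf --genome sim/genome.fa \
    --model cnn.npz --out events.tsv --usage-out usage.tsv --gtf-out augmented.gtf
ipaforge bench --predicted events.bed --truth sim/truth_sites.bed
```

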