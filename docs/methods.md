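# Methods

`ipaforge` identifies intronic polyadenylation (IPA) events from
conventional RNA-seq alignments by combining two trained components — a
sequence scanner and a read-evidence classifier — followed by isoform
assembly and relative-usage quantification. This note records the model,
its tunable parameters, the synthetic benchmark it is validated on, and the
numerical choices made where the design was open.

## Model overview

**Sequence module.** A convolutional network scores 201-nt genomic windows
for the sequence context of a cleavage/polyadenylation site. Input is
one-hot encoded with row order (A, T, G, C); ambiguous bases become uniform
0.25 columns so every column sums to one. The network is two
convolution+ReLU+max-pool pairs followed by one fully connected hidden
layer with dropout and a sigmoid output:

    A_f = ReLU(W_f · S + b_f),   ReLU(x) = max(0, x),   M = max{A_k : k ∈ P}

with convolution filters `W_f` over the one-hot matrix `S` and max-pooling
windows `P`. Positives are windows centered on annotated transcript-end
polyA sites; negatives are size-matched windows sampled uniformly from
intergenic space (never overlapping a gene span). The trained model slides
(stride 1) across every *non-overlapped intronic region* — intron bases of
a gene that no exon of any gene on either strand touches — and positions
scoring ≥ 0.5 are reduced to merged local maxima (radius 50 nt).

**Read module.** Each candidate site defines a *candidate region* back to
the closest upstream splice donor. Regions with ≥ 5 uniquely mapped
fragments are retained ("uniquely mapped" = primary, non-supplementary,
MAPQ ≥ 20, NH = 1 when present; paired mates count as one fragment).
Putative terminal exons are then constructed from the alignments:

- *skipped*: spliced reads whose junction acceptor lands inside the region
  and whose 3' aligned end stays in the region vote for a novel acceptor;
  ≥ 5 supporting reads (majority acceptor, ties toward the donor) yield an
  exon [acceptor, site].
- *composite*: ≥ 10 unspliced reads crossing the donor with ≥ 6 nt aligned
  on both sides yield an exon [donor, site].

A sample-specific classifier decides whether each putative exon behaves
like a real terminal exon in this sample's own alignments. Training
regions come from the annotation: unique last exons with ≥ 5 splice-in
reads (*terminal*, the positive class), unique between-first-and-last exons
with ≥ 5 splice-in reads (*internal*) and unique last exons with < 5
splice-in reads (*background*); internal and background are pooled into the
negative class. The labeled set is split 80:20 (stratified, seeded); ten
random forests, each fit on a random 80% subsample of the training
partition (without replacement), are ensembled by mean probability, and
held-out metrics (TNR, TPR, ACC, Precision, F1, MCC, AUROC) are stored.
Separate classifiers with kind-specific feature schemas score skipped and
composite candidates; exons with ensemble probability ≥ 0.5 are accepted.

**Feature schema.** Shared features: relative length (exon length over the
donor→exon-3'-end container, see below), normalized expression (fragments
per kb per million library fragments), per-base coverage CV, entropy
efficiency (−Σ pᵢ log₂ pᵢ / log₂ L), splice-in and unspliced-cross counts
at the 5' boundary, reads running > 10 nt past the 3' end, the
inside/outside coverage ratio over the terminal 50 nt (capped at 100), and
junction reads splicing out of the exon body. The skipped schema adds
acceptor junction support and the acceptor's offset fraction within the
container; the composite schema adds the donor-crossing count and the
5'-end inside/outside coverage ratio. The container for *relative length*
is defined identically for annotation-derived training exons (previous
splice boundary → exon end) and for putative exons (candidate-region donor
→ site), so the feature means the same thing at train and score time.

**Site-family collapse.** Several candidate sites inside one intron can
build the same exon hypothesis (identical acceptor, or identical donor).
Accepted events sharing that anchor are one cleavage event; the reported
site is the family member nearest the 3' terminus of contiguous coverage
from the exon 5' boundary. The terminus is the last base at ≥ 10% of the
5'-end plateau coverage — coverage tapers over about one read length at a
genuine 3' end, so a low relative cutoff localizes it — and members
upstream of the terminus are excluded first, because reads extending past
a position rule it out as the last transcribed base.

**Isoform assembly and quantification.** Accepted events are grafted onto
a scaffold transcript: the host-intron-containing transcript with the
longest CDS (ties: longer transcript, then lexicographically smaller id).
The coding region is re-derived by translating from the scaffold start
codon through the spliced isoform sequence to the first in-frame stop
(TAA/TAG/TGA); isoforms without one are flagged non-coding. The retained
coding-region fraction is CDS length over the gene's longest annotated CDS
length. Abundance over the augmented annotation comes from a built-in
equivalence-class EM quantifier: each uniquely mapped fragment is assigned
to the set of isoforms whose exon chains contain its aligned blocks with
all junction gaps matching introns exactly; EM over isoform abundances
uses effective length = length − mean fragment length + 1 (floored at 1),
with the mean fragment length measured splice-aware in transcript
coordinates; convergence at max |Δabundance| < 1e−8 or 1,000 iterations.
TPMs normalize to 10⁶; IPA usage of isoform *i* in gene *g* is
x_ig / Σ_j x_jg, undefined (NaN) when the gene total is zero. A reader for
Salmon-format `quant.sf` tables provides a drop-in external alternative.

## Key parameters

| parameter | default | notes |
|---|---|---|
| window length | 201 nt | cis-elements concentrate within ±100 nt of a site |
| scan threshold / stride / merge radius | 0.5 / 1 / 50 nt | merge radius mirrors the 50-nt matching tolerance |
| skipped / composite read bounds | 5 / 10 reads | inclusive (≥) |
| region fragment bound | 5 fragments | smallest stated evidence bound |
| donor-cross flank | 6 nt | guards against terminal soft-clip artifacts |
| splice-in bound for training classes | 5 reads | |
| train/test split | 80:20 | stratified, seeded |
| ensemble | 10 RFs × 100 trees, 80% subsamples | mean probability |
| acceptance probability | 0.5 | |
| CNN | conv 64×10 + pool 4, conv 128×8 + pool 4, FC 64, dropout 0.5 | Adam 1e−3, batch 64, ≤ 50 epochs, patience 5 on validation AUROC (20% stratified) |
| TP matching distance | 50 nt | strand must match |
| signal window | 60 nt upstream | catalog: AATAAA, ATTAAA + standard single-base variants, shipped as text data |

The CNN's output activation, loss, optimizer and layer sizes are declared
package choices within the stated architecture family, not reconstructions;
a random hyperparameter search (`search_hyperparameters`, 10 draws over
filters {32, 64, 128}, kernels {6, 8, 10, 12}, dropout {0.2, 0.5}, lr
{1e−2, 1e−3, 1e−4}) is available but off by default so that routine
training stays at desk scale.

## Synthetic benchmark

`simdata` builds a fully self-contained benchmark: a uniform-background
contig carrying multi-exon coding genes (3–5 exons of 120–300 nt, introns
500–900 nt, every full-length isoform given a start codon, a stop-free
codon body and an in-frame stop), AATAAA planted 15–30 nt upstream of every
polyA site (annotated ends and IPA sites), IPA events in half the genes
(half skipped with a planted AG acceptor + 12-nt polypyrimidine tract, half
composite), sites ≥ 150 nt from intron boundaries, planted usage fractions
drawn from (0.2, 0.7), per-gene expression multipliers in (0.7, 1.3) with
10% of genes at 2% expression (populating the background training class),
and uniform spliced paired-end fragments (100-nt reads, 250 ± 25 fragments)
emitted pre-aligned at the configured coverage, sorted and indexed. Planted
usage is a molar (TPM-sense) fraction: fragment counts split as
usage × effective length, so the quantifier's TPM ratio is directly
comparable to it. Benchmarks run at 10–50X with five replicate seeds;
desk-scale studies use 30-gene replicates, with a 300-gene reference for
CNN training (one scanner trained once, applied to every replicate, as the
sequence model is annotation- not sample-specific).

What the generator does *not* emulate: sequencing errors and quality
variation, positional/GC bias, intron retention and other noise isoforms,
multi-isoform annotations per gene, overlapping genes, and genuine
nucleotide composition around real polyA sites beyond the planted hexamer.
Passing results therefore demonstrate the pipeline's logic — candidate
localization, evidence thresholds, classifier discrimination, EM usage
recovery — under clean conditions, not performance on real libraries.

## Numerical and degenerate-input choices

- Intervals are 0-based half-open internally; GTF I/O is 1-based inclusive,
  BED 0-based half-open. A polyA site is a single base (last transcribed
  nucleotide, strand-aware).
- "Non-overlapped" intronic space excludes exons of either strand
  (configurable), the conservative reading; single-exon and
  ambiguous-strand genes are skipped with a log message.
- Windows with > 10% N are skipped during scanning; N encodes as 0.25.
- Scan peaks are localized to the score-weighted centroid of the
  above-threshold neighborhood (half the merge radius) before a second
  suppression pass; this centers calls on the scanner's response plateau
  rather than its arg-max.
- Zero-coverage regions are excluded before feature extraction (CV and
  entropy are undefined); a zero denominator in any confusion metric gives
  NaN with a warning rather than an exception.
- Training-region minimums are enforced for the terminal and internal
  classes (default 50 each, configurable); background may legitimately be
  scarce in well-covered samples and is allowed to be small or empty.
- Ties everywhere break deterministically (score then coordinate; acceptor
  votes toward the donor; scaffold by CDS length, transcript length, id).
- All randomness (sampling, splits, subsamples, CNN init/shuffles/dropout)
  flows from explicit seeds; CNN training is bit-reproducible on a machine
  because it is pure NumPy.

## Known limitations

- At low usage × coverage (roughly < 10 donor-crossing reads) composite
  events fall below the construction bound by design; sensitivity at 10X
  is accordingly far below 50X.
- The classifier sees only annotation-derived training regions; putative
  exons with pathological coverage shapes are out-of-distribution for it,
  which the family-collapse terminus rule mitigates but does not remove.
- The built-in quantifier ignores sequencing bias and multimapping
  (fragments failing the unique-mapping filter are dropped); for real
  libraries an external Salmon run via the `quant.sf` reader is the better
  route.
- Single-cell support is limited to pooled BAMs and per-sample usage
  tables.
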