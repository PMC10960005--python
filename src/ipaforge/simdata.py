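"""Synthetic benchmark generator: toy genome, annotation, truth and reads.

Emulates the simulated-RNA-seq benchmarking regime the pipeline is
evaluated under: multi-exon coding genes on a random-background contig, a
configurable fraction carrying one intronic polyadenylation event (skipped
with a planted acceptor context, or composite), planted canonical AATAAA
signals 15-30 nt upstream of every polyA site (annotated transcript ends
included), a planted relative-usage fraction per IPA isoform, and
uniform-coverage spliced paired- or single-end reads emitted pre-aligned
(coordinate-sorted, indexed), so the read module is tested without aligner
confounds. Every artifact is deterministic under the seed.

Reads are drawn per isoform proportionally to ``usage x effective length``,
i.e. the planted usage is a molar (TPM-sense) fraction, matching how
relative usage is defined downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pyfaidx
import pysam
import pandas as pd
import yaml

from .reference import GeneModel, TranscriptModel, reverse_complement, write_gtf
from .isoform import _transcript_to_genomic_interval

BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimConfig:
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (500, 900)
    intergenic_gap: tuple[int, int] = (900, 1500)
    ipa_fraction: float = 0.5
    skipped_fraction: float = 0.5
    usage_range: tuple[float, float] = (0.2, 0.7)
    coverage: float = 50.0
    read_length: int = 100
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 25.0
    paired: bool = True
    low_expression_fraction: float = 0.1
    signal_offset: tuple[int, int] = (15, 30)
    site_margin: int = 150  # min distance of an IPA site from intron boundaries
    min_terminal_exon: int = 200
    contig: str = "chrS"
    seed: int = 0

    def __post_init__(self):
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "intergenic_gap", "signal_offset", "usage_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not (0 < self.usage_range[0] and self.usage_range[1] < 1):
            raise ValueError("usage fractions must lie in (0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        needed = self.site_margin + self.min_terminal_exon + 80 + self.site_margin
        if self.intron_length[1] < needed:
            raise ValueError(
                f"max intron length {self.intron_length[1]} too short for site "
                f"placement (needs >= {needed})"
            )


@dataclass
class IPATruth:
    kind: str  # "skipped" | "composite"
    site: int  # genomic position of the last transcribed base
    usage: float
    acceptor: int | None  # genomic first base of the novel exon (skipped only)
    signal_pos: int  # genomic 5' coordinate of the planted AATAAA
    isoform_exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def isoform_id_suffix(self) -> str:
        return f"{self.kind}|{self.site}"


@dataclass
class GeneTruth:
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    expression: float  # relative coverage multiplier
    ipa: IPATruth | None = None

    @property
    def transcript_id(self) -> str:
        return self.gene_id + ".t1"

    @property
    def ipa_isoform_id(self) -> str:
        assert self.ipa is not None
        return f"{self.gene_id}|{self.ipa.isoform_id_suffix}"


@dataclass
class SimTruth:
    config: SimConfig
    contig: str
    genome_length: int
    genes: list[GeneTruth]

    def gene_models(self) -> list[GeneModel]:
        out = []
        for g in self.genes:
            t = TranscriptModel(g.transcript_id, list(g.exons), list(g.cds))
            out.append(GeneModel(g.gene_id, g.contig, g.strand, [t]))
        return out

    def ipa_genes(self) -> list[GeneTruth]:
        return [g for g in self.genes if g.ipa is not None]

    def truth_sites(self) -> list[tuple[str, int, str]]:
        return [(g.contig, g.ipa.site, g.strand) for g in self.ipa_genes()]


def _place(arr: np.ndarray, g5: int, motif: str, strand: str) -> None:
    """Write a transcription-orientation motif whose 5' base sits at ``g5``."""
    if strand == "+":
        arr[g5 : g5 + len(motif)] = list(motif)
    else:
        rc = reverse_complement(motif)
        arr[g5 - len(motif) + 1 : g5 + 1] = list(rc)


def make_toy_reference(config: SimConfig, outdir: str) -> tuple[str, str, SimTruth]:
    """Build genome FASTA (+index), GTF and truth files; fully seeded.

    Returns ``(fasta_path, gtf_path, truth)``; also writes ``truth_sites.bed``,
    ``truth_usage.tsv`` and a YAML echo of the configuration.
    """
    rng = np.random.default_rng(config.seed)
    os.makedirs(outdir, exist_ok=True)
    genes: list[GeneTruth] = []
    layout: list[tuple[int, GeneTruth]] = []
    cursor = 1000
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, n_exons - 1
        )
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + int(elen)))
            pos += int(elen)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        gene_end = pos
        expression = float(rng.uniform(0.7, 1.3))
        if rng.random() < config.low_expression_fraction:
            expression *= 0.02
        gene = GeneTruth(f"G{gi:03d}", config.contig, strand, exons, [], expression)
        genes.append(gene)
        layout.append((cursor, gene))
        cursor = gene_end + int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
    genome_len = cursor + 1000

    arr = BASES[rng.integers(0, 4, genome_len)]

    for gene in genes:
        strand = gene.strand
        exon_order = gene.exons if strand == "+" else list(reversed(gene.exons))
        T = sum(e - s for s, e in gene.exons)
        # coding layout in transcript coordinates: UTR5 - ATG - codons - stop - UTR3
        cds_start = 30
        cds_end = T - 60
        cds_end -= (cds_end - cds_start) % 3
        n_codons = (cds_end - cds_start) // 3 - 2
        body = "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons))
        stop = str(rng.choice(["TAA", "TAG", "TGA"]))
        utr5 = "".join(rng.choice(BASES, cds_start))
        utr3 = "".join(rng.choice(BASES, T - cds_end))
        tx_seq = list(utr5 + "ATG" + body + stop + utr3)
        # polyA signal upstream of the annotated transcript end
        d_end = int(rng.integers(config.signal_offset[0], config.signal_offset[1] + 1))
        tx_seq[T - 1 - d_end : T - 1 - d_end + 6] = list("AATAAA")
        tx_seq = "".join(tx_seq)
        off = 0
        for s, e in exon_order:
            chunk = tx_seq[off : off + (e - s)]
            g5 = s if strand == "+" else e - 1
            _place(arr, g5, chunk, strand)
            off += e - s
        gene.cds = _transcript_to_genomic_interval(cds_start, cds_end, strand, gene.exons)

    # plant IPA events after gene bodies so motifs land in final sequence
    n_ipa = int(round(config.ipa_fraction * len(genes)))
    expressed = [g for g in genes if g.expression > 0.1]
    ipa_idx = rng.choice(len(expressed), size=min(n_ipa, len(expressed)), replace=False)
    for k, gi in enumerate(sorted(ipa_idx)):
        gene = expressed[gi]
        strand = gene.strand
        introns = [
            (gene.exons[i][1], gene.exons[i + 1][0]) for i in range(len(gene.exons) - 1)
        ]
        usable = [iv for iv in introns if iv[1] - iv[0] >= config.site_margin * 2 + config.min_terminal_exon + 80]
        if not usable:
            continue
        iv = usable[int(rng.integers(len(usable)))]
        ilen = iv[1] - iv[0]
        kind = "skipped" if k < round(config.skipped_fraction * len(ipa_idx)) else "composite"
        lo = max(config.site_margin, config.min_terminal_exon + 80)
        ds = int(rng.integers(lo, ilen - config.site_margin + 1))
        site = iv[0] + ds if strand == "+" else iv[1] - 1 - ds
        d = int(rng.integers(config.signal_offset[0], config.signal_offset[1] + 1))
        sig5 = site - d if strand == "+" else site + d
        _place(arr, sig5, "AATAAA", strand)
        acceptor = None
        if kind == "skipped":
            da = int(rng.integers(80, ds - config.min_terminal_exon + 1))
            acceptor = iv[0] + da if strand == "+" else iv[1] - 1 - da
            # canonical acceptor context: polypyrimidine tract + AG immediately 5'
            pyr = "".join(rng.choice(list("CT"), 12))
            ag5 = acceptor - 2 if strand == "+" else acceptor + 2
            _place(arr, ag5, "AG", strand)
            pyr5 = acceptor - 14 if strand == "+" else acceptor + 14
            _place(arr, pyr5, pyr, strand)
        # truth isoform structure
        intron_i = introns.index(iv)
        if strand == "+":
            upstream = gene.exons[: intron_i + 1]
            if kind == "composite":
                iso_exons = upstream[:-1] + [(upstream[-1][0], site + 1)]
            else:
                iso_exons = upstream + [(acceptor, site + 1)]
        else:
            upstream = gene.exons[intron_i + 1 :]
            if kind == "composite":
                iso_exons = [(site, upstream[0][1])] + upstream[1:]
            else:
                iso_exons = [(site, acceptor + 1)] + upstream
        usage = float(rng.uniform(*config.usage_range))
        gene.ipa = IPATruth(kind, site, usage, acceptor, sig5, iso_exons)

    truth = SimTruth(config, config.contig, genome_len, genes)

    fasta_path = os.path.join(outdir, "genome.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{config.contig}\n")
        seq = "".join(arr)
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    pyfaidx.Faidx(fasta_path)
    gtf_path = os.path.join(outdir, "annotation.gtf")
    write_gtf(truth.gene_models(), gtf_path, source="ipaforge_sim")
    write_truth_bed(truth, os.path.join(outdir, "truth_sites.bed"))
    truth_usage_table(truth).to_csv(
        os.path.join(outdir, "truth_usage.tsv"), sep="\t", index=False
    )
    with open(os.path.join(outdir, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    return fasta_path, gtf_path, truth


def _isoform_structures(gene: GeneTruth) -> list[tuple[str, str, list[tuple[int, int]], float]]:
    """(isoform_id, kind, exons, molar usage) for a gene's isoforms."""
    if gene.ipa is None:
        return [(gene.transcript_id, "annotated", gene.exons, 1.0)]
    return [
        (gene.transcript_id, "annotated", gene.exons, 1.0 - gene.ipa.usage),
        (gene.ipa_isoform_id, gene.ipa.kind, gene.ipa.isoform_exons, gene.ipa.usage),
    ]


def simulate_alignments(
    truth: SimTruth,
    genome_fasta: str,
    bam_path: str,
    coverage: float | None = None,
    seed: int | None = None,
    paired: bool | None = None,
    fastq_prefix: str | None = None,
) -> dict[str, int]:
    """Draw uniform fragments per isoform and emit a sorted, indexed BAM.

    Fragment counts target a mean exonic coverage of ``coverage`` per gene
    (scaled by the gene's expression multiplier) and split between isoforms
    in proportion to usage x effective length. Junction-spanning reads get
    N gap CIGAR operations; MAPQ 60, NH:1, proper-pair flags. Returns the
    realized fragment count per isoform.
    """
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, 1 if seed is None else seed])
    coverage = cfg.coverage if coverage is None else coverage
    paired = cfg.paired if paired is None else paired
    genome = pyfaidx.Fasta(genome_fasta, as_raw=True, sequence_always_upper=True)
    contig_seq = str(genome[truth.contig][:])

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": truth.contig, "LN": truth.genome_length}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    realized: dict[str, int] = {}
    fq1, fq2 = [], []
    read_len = cfg.read_length
    bases_per_frag = 2 * read_len if paired else read_len

    for gene in truth.genes:
        isoforms = _isoform_structures(gene)
        union_len = gene.exons[-1][1] - gene.exons[0][0]
        exonic_len = sum(e - s for s, e in gene.exons)
        weights = []
        for _, _, exons, u in isoforms:
            L = sum(e - s for s, e in exons)
            eff = max(1.0, L - cfg.fragment_length_mean + 1.0)
            weights.append(u * eff)
        weights = np.array(weights)
        if weights.sum() <= 0:
            continue
        n_frag_gene = int(round(gene.expression * coverage * exonic_len / bases_per_frag))
        if n_frag_gene == 0:
            realized.update({iso_id: 0 for iso_id, _, _, _ in isoforms})
            continue
        counts = rng.multinomial(n_frag_gene, weights / weights.sum())
        for (iso_id, kind, exons, _), n_i in zip(isoforms, counts):
            realized[iso_id] = int(n_i)
            L = sum(e - s for s, e in exons)
            if L < read_len:
                continue
            for fi in range(n_i):
                flen = int(
                    np.clip(round(rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd)),
                            read_len, L)
                )
                t0 = int(rng.integers(0, L - flen + 1))
                qname = f"{iso_id.replace('|', '_')}:{fi}"
                if paired:
                    spans = [(t0, t0 + read_len), (t0 + flen - read_len, t0 + flen)]
                else:
                    spans = [(t0, t0 + read_len)]
                segs = []
                for t_s, t_e in spans:
                    blocks = _transcript_to_genomic_interval(t_s, t_e, gene.strand, exons)
                    segs.append(blocks)
                recs = _make_records(
                    qname, segs, gene.strand, paired, contig_seq, header, truth.contig
                )
                records.extend(recs)
                if fastq_prefix is not None:
                    _append_fastq(fq1, fq2, qname, recs, paired, gene.strand)
    records.sort(key=lambda r: r.reference_start)
    tmp = bam_path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for r in records:
            out.write(r)
    pysam.sort("-o", bam_path, tmp)
    os.remove(tmp)
    pysam.index(bam_path)
    if fastq_prefix is not None:
        with open(fastq_prefix + "_1.fastq", "w") as fh:
            fh.write("".join(fq1))
        if paired:
            with open(fastq_prefix + "_2.fastq", "w") as fh:
                fh.write("".join(fq2))
    return realized


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return cig


def _make_records(qname, segs, strand, paired, contig_seq, header, contig):
    recs = []
    for mate_i, blocks in enumerate(segs):
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.reference_id = 0
        a.reference_start = blocks[0][0]
        a.cigartuples = _blocks_to_cigar(blocks)
        a.mapping_quality = 60
        seq = "".join(contig_seq[s:e] for s, e in blocks)
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.set_tag("NH", 1)
        recs.append(a)
    if paired:
        r1, r2 = recs
        # genomic-left mate is forward; read1 is the fragment 5' end
        left, right = (r1, r2) if r1.reference_start <= r2.reference_start else (r2, r1)
        for rec, rev, first in ((r1, strand == "-", True), (r2, strand == "+", False)):
            rec.is_paired = True
            rec.is_proper_pair = True
            rec.is_reverse = rev
            rec.mate_is_reverse = not rev
            rec.is_read1 = first
            rec.is_read2 = not first
        r1.next_reference_id = r2.next_reference_id = 0
        r1.next_reference_start = r2.reference_start
        r2.next_reference_start = r1.reference_start
        span = right.reference_end - left.reference_start
        left.template_length = span
        right.template_length = -span
    else:
        recs[0].is_reverse = strand == "-"
    return recs


def _append_fastq(fq1, fq2, qname, recs, paired, strand):
    def oriented(rec):
        seq = rec.query_sequence
        return reverse_complement(seq) if rec.is_reverse else seq

    fq1.append(f"@{qname}\n{oriented(recs[0])}\n+\n{'I' * recs[0].query_length}\n")
    if paired:
        fq2.append(f"@{qname}\n{oriented(recs[1])}\n+\n{'I' * recs[1].query_length}\n")


def truth_usage_table(truth: SimTruth, sample: str = "truth") -> pd.DataFrame:
    """Planted relative usage per isoform, format-matched to ipa_usage output."""
    rows = []
    for g in truth.genes:
        for iso_id, kind, _, u in _isoform_structures(g):
            rows.append(
                {"sample": sample, "gene_id": g.gene_id, "isoform_id": iso_id,
                 "kind": kind, "usage": u}
            )
    return pd.DataFrame(rows)


def write_truth_bed(truth: SimTruth, path: str) -> None:
    """Truth IPA sites as BED6; name = geneID|kind|usage."""
    with open(path, "w") as fh:
        for g in truth.ipa_genes():
            ipa = g.ipa
            fh.write(
                f"{g.contig}\t{ipa.site}\t{ipa.site + 1}\t"
                f"{g.gene_id}|{ipa.kind}|{ipa.usage:.3f}\t0\t{g.strand}\n"
            )
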