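"""IPA isoform assembly, CDS annotation, augmented GTF and quantification.

An accepted IPA event is grafted onto a scaffold transcript (the host
gene's transcript containing the host intron with the longest CDS):
*composite* events extend the intron's 5'-flanking exon to the site,
*skipped* events append a novel terminal exon from the new acceptor to the
site. The coding region is re-annotated by translating from the scaffold's
start codon to the first in-frame stop; isoforms whose truncated sequence
has no in-frame stop are flagged non-coding.

Abundance is estimated either by the built-in equivalence-class EM
quantifier over uniquely mapped fragments, or read from an external
Salmon-format ``quant.sf`` table. IPA usage for isoform i of gene g is
``x_ig / sum_j x_jg`` with x in TPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .reference import GeneModel, GenomeBundle, TranscriptModel, reverse_complement, write_gtf
from .readmodel import IPAEvent, is_unique, _junctions

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class IPAIsoform:
    isoform_id: str
    gene_id: str
    scaffold_id: str
    kind: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    site_pos: int
    cds: list[tuple[int, int]] = field(default_factory=list)
    coding: bool | None = None  # None until annotate_cds has run

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def _pick_scaffold(gene: GeneModel, site: int) -> TranscriptModel:
    hosts = [
        t
        for t in gene.transcripts
        if any(s <= site < e for s, e in t.introns)
    ]
    if not hosts:
        raise ValueError(f"no transcript of {gene.gene_id} has an intron containing {site}")
    return max(hosts, key=lambda t: (t.cds_length, t.length, _neg_str(t.transcript_id)))


def _neg_str(s: str):
    # sort key making lexicographically *smallest* id win under max()
    return tuple(-ord(c) for c in s)


def assemble_ipa_isoform(event: IPAEvent, genes: list[GeneModel]) -> IPAIsoform:
    """Graft the event's terminal exon onto its scaffold transcript."""
    gene = next((g for g in genes if g.gene_id == event.gene_id), None)
    if gene is None:
        raise ValueError(f"unknown gene {event.gene_id}")
    t = _pick_scaffold(gene, event.site_pos)
    site = event.site_pos
    intron = next((s, e) for s, e in t.introns if s <= site < e)
    if gene.strand == "+":
        upstream = [iv for iv in t.exons if iv[1] <= intron[0]]
        if event.kind == "composite":
            exons = upstream[:-1] + [(upstream[-1][0], site + 1)]
        else:
            exons = upstream + [(event.exon_start, site + 1)]
    else:
        upstream = [iv for iv in t.exons if iv[0] >= intron[1]]
        if event.kind == "composite":
            exons = [(site, upstream[0][1])] + upstream[1:]
        else:
            exons = [(site, event.exon_end)] + upstream
    iso = IPAIsoform(
        isoform_id=f"{gene.gene_id}|{event.kind}|{site}",
        gene_id=gene.gene_id,
        scaffold_id=t.transcript_id,
        kind=event.kind,
        contig=gene.contig,
        strand=gene.strand,
        exons=exons,
        site_pos=site,
    )
    for (s1, e1), (s2, e2) in zip(iso.exons, iso.exons[1:]):
        assert e1 <= s2, "assembled exons overlap"
    return iso


def spliced_sequence(genome: GenomeBundle, contig: str, strand: str,
                     exons: list[tuple[int, int]]) -> str:
    """Transcript sequence in transcription orientation."""
    seq = "".join(genome.fetch(contig, s, e) for s, e in exons)
    return reverse_complement(seq) if strand == "-" else seq


def _genomic_to_transcript(pos: int, strand: str, exons: list[tuple[int, int]]) -> int | None:
    """Offset of a genomic base within the spliced transcript, or None."""
    off = 0
    if strand == "+":
        for s, e in exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
    else:
        for s, e in reversed(exons):
            if s <= pos < e:
                return off + (e - 1 - pos)
            off += e - s
    return None


def _transcript_to_genomic_interval(
    t_start: int, t_end: int, strand: str, exons: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval back to genomic intervals."""
    out = []
    off = 0
    ordered = exons if strand == "+" else list(reversed(exons))
    for s, e in ordered:
        elen = e - s
        lo = max(t_start, off)
        hi = min(t_end, off + elen)
        if lo < hi:
            if strand == "+":
                out.append((s + (lo - off), s + (hi - off)))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += elen
    return sorted(out)


def annotate_cds(
    iso: IPAIsoform, genome: GenomeBundle, scaffold: TranscriptModel
) -> IPAIsoform:
    """Translate from the scaffold start codon to the first in-frame stop.

    Flags the isoform non-coding when the scaffold has no CDS, the start
    codon is lost, or no in-frame stop exists before the IPA site.
    """
    if not scaffold.cds:
        iso.coding = False
        return iso
    start_base = scaffold.cds[0][0] if iso.strand == "+" else scaffold.cds[-1][1] - 1
    start_off = _genomic_to_transcript(start_base, iso.strand, iso.exons)
    if start_off is None:
        iso.coding = False
        return iso
    seq = spliced_sequence(genome, iso.contig, iso.strand, iso.exons)
    stop_off = None
    for o in range(start_off, len(seq) - 2, 3):
        if seq[o : o + 3] in STOP_CODONS:
            stop_off = o
            break
    if stop_off is None:
        iso.coding = False
        return iso
    iso.cds = _transcript_to_genomic_interval(start_off, stop_off + 3, iso.strand, iso.exons)
    iso.coding = True
    return iso


def retained_cdr_fraction(iso: IPAIsoform, gene: GeneModel) -> float | None:
    """IPA CDS length over the gene's longest annotated CDS length.

    Non-coding isoforms give 0.0; a gene without any annotated CDS gives
    None (undefined).
    """
    longest = max((t.cds_length for t in gene.transcripts), default=0)
    if longest == 0:
        logger.warning("gene %s has no annotated CDS; fraction undefined", gene.gene_id)
        return None
    if not iso.coding:
        return 0.0
    frac = iso.cds_length / longest
    assert 0.0 <= frac
    return frac


def write_augmented_gtf(
    genes: list[GeneModel], isoforms: list[IPAIsoform], path: str
) -> None:
    """Reference records plus IPA isoforms, re-loadable by load_annotation."""
    write_gtf(genes, path, source="ipaforge")
    with open(path, "a") as fh:
        for iso in isoforms:
            attrs = (
                f'gene_id "{iso.gene_id}"; transcript_id "{iso.isoform_id}"; '
                f'ipa_kind "{iso.kind}";'
            )
            s, e = iso.exons[0][0], iso.exons[-1][1]
            fh.write(
                f"{iso.contig}\tipaforge_ipa\ttranscript\t{s + 1}\t{e}\t.\t"
                f"{iso.strand}\t.\t{attrs}\n"
            )
            for s, e in iso.exons:
                fh.write(
                    f"{iso.contig}\tipaforge_ipa\texon\t{s + 1}\t{e}\t.\t"
                    f"{iso.strand}\t.\t{attrs}\n"
                )
            for s, e in iso.cds:
                fh.write(
                    f"{iso.contig}\tipaforge_ipa\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{iso.strand}\t0\t{attrs}\n"
                )
            if iso.coding:
                # stop codon = last 3 nt of the CDS in transcription orientation
                if iso.strand == "+":
                    cs, ce = iso.cds[-1]
                    fh.write(
                        f"{iso.contig}\tipaforge_ipa\tstop_codon\t{ce - 2}\t{ce}\t.\t"
                        f"+\t0\t{attrs}\n"
                    )
                else:
                    cs, ce = iso.cds[0]
                    fh.write(
                        f"{iso.contig}\tipaforge_ipa\tstop_codon\t{cs + 1}\t{cs + 3}\t.\t"
                        f"-\t0\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# quantification


@dataclass
class _Tx:
    tx_id: str
    gene_id: str
    kind: str  # "annotated" | "skipped" | "composite"
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


def _transcript_index(genes: list[GeneModel], isoforms: list[IPAIsoform]) -> list[_Tx]:
    txs = [
        _Tx(t.transcript_id, g.gene_id, "annotated", g.contig, g.strand, t.exons)
        for g in genes
        for t in g.transcripts
    ]
    txs += [
        _Tx(i.isoform_id, i.gene_id, i.kind, i.contig, i.strand, i.exons)
        for i in isoforms
    ]
    return txs


def _read_compatible(read: pysam.AlignedSegment, tx: _Tx) -> bool:
    intron_set = set(tx.introns)
    for gs, ge in _junctions(read):
        if (gs, ge) not in intron_set:
            return False
    blocks = read.get_blocks()
    for bs, be in blocks:
        if not any(s <= bs and be <= e for s, e in tx.exons):
            return False
    return True


def _fragment_tx_length(span_lo: int, span_hi: int, tx: "_Tx") -> float | None:
    """Fragment length in transcript coordinates (splice-aware)."""
    a = _genomic_to_transcript(span_lo, "+", tx.exons)
    b = _genomic_to_transcript(span_hi - 1, "+", tx.exons)
    if a is None or b is None:
        return None
    return abs(b - a) + 1


def quantify(
    source,
    genes: list[GeneModel],
    isoforms: list[IPAIsoform] | None = None,
    mode: str = "builtin",
    sample: str = "sample1",
    mean_fragment_length: float | None = None,
    em_tol: float = 1e-8,
    em_max_iter: int = 1000,
) -> pd.DataFrame:
    """Transcript-level TPM over the augmented annotation.

    ``mode='builtin'`` runs the equivalence-class EM quantifier on a
    coordinate-sorted indexed BAM/SAM (``source`` = path or AlignmentFile);
    ``mode='external-table'`` reads a Salmon-format quant table from
    ``source`` and joins it to the annotation.
    """
    isoforms = isoforms or []
    txs = _transcript_index(genes, isoforms)
    meta = pd.DataFrame(
        {
            "isoform_id": [t.tx_id for t in txs],
            "gene_id": [t.gene_id for t in txs],
            "kind": [t.kind for t in txs],
            "length": [t.length for t in txs],
        }
    )
    if mode == "external-table":
        tab = read_salmon_table(source)
        out = meta.merge(tab, left_on="isoform_id", right_on="Name", how="left")
        out["TPM"] = out["TPM"].fillna(0.0)
        out["num_reads"] = out["NumReads"].fillna(0.0)
        out["effective_length"] = out["EffectiveLength"].fillna(out["length"])
        out.insert(0, "sample", sample)
        return out[
            ["sample", "gene_id", "isoform_id", "kind", "length", "effective_length",
             "num_reads", "TPM"]
        ]
    if mode != "builtin":
        raise ValueError(f"unknown quantification mode {mode!r}")

    bam = source if isinstance(source, pysam.AlignmentFile) else pysam.AlignmentFile(str(source))
    # group transcripts by contig for fragment assignment
    by_contig: dict[str, list[int]] = {}
    for i, t in enumerate(txs):
        by_contig.setdefault(t.contig, []).append(i)

    # collect fragments (reads grouped by query name) and equivalence classes;
    # fragment lengths are measured in transcript coordinates (splice-aware)
    eq_counts: dict[frozenset[int], int] = {}
    frag_lens: list[float] = []
    unassigned = 0
    for contig in bam.references:
        if contig not in by_contig:
            continue
        frags: dict[str, list[pysam.AlignedSegment]] = {}
        for read in bam.fetch(contig):
            if is_unique(read):
                frags.setdefault(read.query_name, []).append(read)
        cand = by_contig[contig]
        for reads in frags.values():
            span_lo = min(r.reference_start for r in reads)
            span_hi = max(r.reference_end for r in reads)
            compat = frozenset(
                i
                for i in cand
                if txs[i].exons[0][0] <= span_lo
                and span_hi <= txs[i].exons[-1][1]
                and all(_read_compatible(r, txs[i]) for r in reads)
            )
            if compat:
                eq_counts[compat] = eq_counts.get(compat, 0) + 1
                flen = _fragment_tx_length(span_lo, span_hi, txs[min(compat)])
                if flen is not None:
                    frag_lens.append(flen)
            else:
                unassigned += 1
    if unassigned:
        logger.info("%d fragments compatible with no isoform", unassigned)
    if mean_fragment_length is None:
        mean_fragment_length = float(np.mean(frag_lens)) if frag_lens else 100.0

    n = len(txs)
    efflen = np.array([max(1.0, t.length - mean_fragment_length + 1.0) for t in txs])
    total = sum(eq_counts.values())
    est = np.zeros(n)
    if total > 0:
        alpha = np.full(n, 1.0 / n)
        classes = [(np.fromiter(c, dtype=int), cnt) for c, cnt in eq_counts.items()]
        for _ in range(em_max_iter):
            est[:] = 0.0
            for idx, cnt in classes:
                w = alpha[idx] / efflen[idx]
                est[idx] += cnt * w / w.sum()
            new_alpha = est / total
            if np.max(np.abs(new_alpha - alpha)) < em_tol:
                alpha = new_alpha
                break
            alpha = new_alpha
    rate = est / efflen
    tpm = rate / rate.sum() * 1e6 if rate.sum() > 0 else rate
    out = meta.copy()
    out["effective_length"] = efflen
    out["num_reads"] = est
    out["TPM"] = tpm
    out.insert(0, "sample", sample)
    return out


def read_salmon_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"Name", "Length", "EffectiveLength", "TPM", "NumReads"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"malformed quant table; missing columns {sorted(missing)}")
    return tab


def ipa_usage(tpm_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-gene relative usage: TPM_i / sum_j TPM_j.

    Genes with zero total TPM get NaN usage (flagged undefined).
    """
    if "gene_id" not in tpm_table.columns:
        raise ValueError("TPM table lacks gene assignment")
    out = tpm_table.copy()
    totals = out.groupby(["sample", "gene_id"])["TPM"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["usage"] = np.where(totals > 0, out["TPM"] / totals, np.nan)
    return out
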