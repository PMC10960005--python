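"""Genome and annotation access.

Loads a FASTA reference and a Refseq-style GTF into simple strand-aware
models, and derives the interval sets the rest of the pipeline consumes:
non-overlapped intronic regions, unique last/internal exons, splice sites.

Coordinate conventions: everything in memory is 0-based half-open on the
forward genomic strand. GTF I/O converts to/from 1-based inclusive; BED I/O
is 0-based half-open. A polyA site is a single base: the last transcribed
nucleotide, strand-aware.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
import pyfaidx

from ._intervals import merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeBundle:
    """Random access to an indexed FASTA reference.

    Sequences are returned uppercase on the forward strand; out-of-range
    requests raise instead of being silently truncated.
    """

    def __init__(self, fasta_path: str):
        if not os.path.exists(fasta_path):
            raise FileNotFoundError(fasta_path)
        self._fasta = pyfaidx.Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
        self.contig_names = list(self._fasta.keys())
        if len(set(self.contig_names)) != len(self.contig_names):
            raise ValueError("duplicate contig names in FASTA")
        self.contig_lengths = {name: len(self._fasta[name]) for name in self.contig_names}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Forward-strand sequence for ``[start, end)`` (0-based half-open)."""
        if contig not in self.contig_lengths:
            raise KeyError(f"unknown contig {contig!r}")
        if start < 0 or end > self.contig_lengths[contig] or start > end:
            raise ValueError(
                f"interval [{start},{end}) out of range for {contig} "
                f"(length {self.contig_lengths[contig]})"
            )
        seq = str(self._fasta[contig][start:end])
        assert len(seq) == end - start
        return seq


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # sorted genomic order
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def validate(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS [{cs},{ce}) outside exons in {self.transcript_id}")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals([iv for t in self.transcripts for iv in t.exons])

    def intron_union(self) -> list[tuple[int, int]]:
        return merge_intervals([iv for t in self.transcripts for iv in t.introns])

    def last_exon(self, t: TranscriptModel) -> tuple[int, int]:
        """Strand-aware last exon (3'-most in transcription orientation)."""
        return t.exons[-1] if self.strand == "+" else t.exons[0]

    def first_exon(self, t: TranscriptModel) -> tuple[int, int]:
        return t.exons[0] if self.strand == "+" else t.exons[-1]

    def unique_last_exons(self) -> list[tuple[int, int]]:
        return sorted({self.last_exon(t) for t in self.transcripts if len(t.exons) >= 1})

    def unique_internal_exons(self) -> list[tuple[int, int]]:
        """Exons strictly between a transcript's first and last, deduplicated.

        An interval that is also some transcript's last exon is excluded to
        avoid conflicting labels.
        """
        last = set(self.unique_last_exons())
        first = {self.first_exon(t) for t in self.transcripts}
        internal = {
            iv for t in self.transcripts for iv in t.exons[1:-1] if len(t.exons) >= 3
        }
        return sorted(internal - last - first)

    def polya_sites(self) -> list[int]:
        """Distinct annotated transcript 3'-end positions (single base)."""
        sites = set()
        for t in self.transcripts:
            s, e = self.last_exon(t)
            sites.add(e - 1 if self.strand == "+" else s)
        return sorted(sites)

    def donor_sites(self) -> list[int]:
        """Genomic donor boundaries (exon/intron junction 5' of an intron)."""
        donors = set()
        for t in self.transcripts:
            for iv_s, iv_e in t.introns:
                donors.add(iv_s if self.strand == "+" else iv_e)
        return sorted(donors)


@dataclass(frozen=True)
class IntronicRegion:
    """A maximal intronic interval free of exons of any gene.

    ``donor`` is the closest upstream (5' in transcription orientation)
    splice-donor boundary of the host intron: the region start for ``+``
    genes, the region's host-intron end for ``-`` genes.
    """

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    donor: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty intronic region")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def load_genome(fasta_path: str) -> GenomeBundle:
    return GenomeBundle(fasta_path)


def _parse_gtf(gtf_path: str):
    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    return db


def load_annotation(gtf_path: str) -> list[GeneModel]:
    """Parse a GTF into GeneModels (exon and CDS features only are required).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Transcripts lacking exons are dropped with a warning.
    """
    db = _parse_gtf(gtf_path)
    transcripts: dict[str, TranscriptModel] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, contig, strand)
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise ValueError(f"GTF record missing {exc} attribute: {feat}") from exc
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if tid in meta:
            if meta[tid] != (gid, feat.seqid, feat.strand):
                raise ValueError(f"inconsistent gene/contig/strand for transcript {tid}")
        else:
            meta[tid] = (gid, feat.seqid, feat.strand)
            transcripts[tid] = TranscriptModel(tid)
        if feat.featuretype == "exon":
            transcripts[tid].exons.append(iv)
        else:
            transcripts[tid].cds.append(iv)

    genes: dict[str, GeneModel] = {}
    for tid, t in transcripts.items():
        gid, contig, strand = meta[tid]
        if not t.exons:
            logger.warning("transcript %s has no exons; dropped", tid)
            continue
        t.exons = sorted(t.exons)
        t.cds = sorted(t.cds)
        t.validate()
        if gid not in genes:
            genes[gid] = GeneModel(gid, contig, strand)
        gene = genes[gid]
        if gene.contig != contig or gene.strand != strand:
            raise ValueError(f"gene {gid} has transcripts on mixed contig/strand")
        gene.transcripts.append(t)
    return list(genes.values())


def write_gtf(genes: list[GeneModel], path: str, source: str = "ipaforge") -> None:
    """Write gene models as GTF (1-based inclusive), exon + CDS features."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";'
                s, e = t.span
                fh.write(
                    f"{gene.contig}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{gene.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
                for s, e in t.cds:
                    fh.write(
                        f"{gene.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t0\t{attrs}\n"
                    )


def nonoverlapped_introns(
    genes: list[GeneModel], exclude_both_strands: bool = True
) -> list[IntronicRegion]:
    """Maximal intronic intervals not overlapping any annotated exon.

    For each multi-exon gene the union of its transcripts' introns is taken,
    then every exon of every gene (on either strand by default) is subtracted.
    Each resulting piece records the donor boundary of its host intron.
    Single-exon genes contribute nothing and are skipped.
    """
    exons_by_contig: dict[str, list[tuple[int, int]]] = {}
    exons_by_contig_strand: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for gene in genes:
        exons_by_contig.setdefault(gene.contig, []).extend(gene.exon_union())
        exons_by_contig_strand.setdefault((gene.contig, gene.strand), []).extend(
            gene.exon_union()
        )
    exons_by_contig = {c: merge_intervals(v) for c, v in exons_by_contig.items()}
    exons_by_contig_strand = {
        k: merge_intervals(v) for k, v in exons_by_contig_strand.items()
    }

    regions: list[IntronicRegion] = []
    for gene in genes:
        if all(len(t.exons) < 2 for t in gene.transcripts):
            logger.debug("gene %s has no multi-exon transcript; skipped", gene.gene_id)
            continue
        if gene.strand not in ("+", "-"):
            logger.warning("gene %s has ambiguous strand; skipped", gene.gene_id)
            continue
        exonic = (
            exons_by_contig[gene.contig]
            if exclude_both_strands
            else exons_by_contig_strand[(gene.contig, gene.strand)]
        )
        for host_s, host_e in gene.intron_union():
            donor = host_s if gene.strand == "+" else host_e
            for s, e in subtract_intervals([(host_s, host_e)], exonic):
                regions.append(
                    IntronicRegion(gene.contig, s, e, gene.strand, gene.gene_id, donor)
                )
    regions.sort(key=lambda r: (r.contig, r.start))
    return regions


def fetch_window(
    genome: GenomeBundle, contig: str, center: int, flank: int, strand: str
) -> str:
    """``2*flank + 1`` nt window centered on ``center`` in transcription
    orientation (reverse-complemented for ``-``); raises if it leaves the
    contig."""
    seq = genome.fetch(contig, center - flank, center + flank + 1)
    return reverse_complement(seq) if strand == "-" else seq


def read_bed_sites(path: str) -> list[tuple[str, int, str, str]]:
    """Read BED6 single-base site records as (contig, pos, strand, name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), f[5] if len(f) > 5 else "+", f[3] if len(f) > 3 else "."))
    return out


def write_bed_sites(
    records: list[tuple[str, int, str, str]], path: str, score: str = "0"
) -> None:
    """Write single-base sites as BED6; ``records`` are (contig, pos, strand, name)."""
    with open(path, "w") as fh:
        for contig, pos, strand, name in records:
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t{name}\t{score}\t{strand}\n")
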