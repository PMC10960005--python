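"""End-to-end orchestration: scan, classify, assemble, quantify.

Convenience layer tying the sequence module, read module and isoform
module together for a single sample, as the command-line interface and the
benchmark scripts use them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .reference import GenomeBundle, GeneModel, nonoverlapped_introns
from .seqmodel import PolyACnn, CandidateSite, scan_intronic_regions
from . import readmodel as rm
from . import isoform as iso

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    sites: list[CandidateSite]
    events: list[rm.IPAEvent]
    classifiers: dict[str, rm.TerminalExonClassifier]
    library_size: int
    isoforms: list[iso.IPAIsoform] = field(default_factory=list)
    usage: pd.DataFrame | None = None

    def event_sites(self) -> list[tuple[str, int, str]]:
        return sorted({(e.contig, e.site_pos, e.strand) for e in self.events})


def detect_ipa_events(
    bam: pysam.AlignmentFile,
    sites: list[CandidateSite],
    genes: list[GeneModel],
    seed: int = 0,
    min_region_fragments: int = rm.DEFAULT_MIN_REGION_FRAGMENTS,
    min_skipped_reads: int = rm.DEFAULT_MIN_SKIPPED_READS,
    min_composite_reads: int = rm.DEFAULT_MIN_COMPOSITE_READS,
    min_per_class: int = 50,
    probability_threshold: float = 0.5,
    library_size: int | None = None,
    classifiers: dict[str, rm.TerminalExonClassifier] | None = None,
) -> tuple[list[rm.IPAEvent], dict[str, rm.TerminalExonClassifier], int]:
    """Run the read module on candidate sites for one sample.

    Trains the sample-specific classifiers from the same alignments unless
    pre-trained ones are supplied. Events are deduplicated per site,
    keeping the highest-probability kind.
    """
    if library_size is None:
        library_size = rm.count_library_fragments(bam)
    regions = [r for s in sites if (r := rm.define_candidate_region(s)) is not None]
    retained = rm.filter_regions_by_count(regions, bam, min_region_fragments)
    putative: list[tuple[rm.PutativeTerminalExon, rm.FeatureVector]] = []
    for region in retained:
        for exon in rm.construct_putative_exons(
            region, bam, min_skipped_reads, min_composite_reads
        ):
            try:
                fv = rm.extract_features(exon, bam, library_size)
            except ValueError:
                continue
            putative.append((exon, fv))
    if classifiers is None:
        labeled = rm.build_training_regions(
            genes, bam, library_size, min_per_class=min_per_class
        )
        classifiers = rm.train_terminal_classifiers(labeled, seed=seed)
    events = rm.classify(putative, classifiers, probability_threshold)
    best: dict[tuple[str, int, str], rm.IPAEvent] = {}
    for ev in events:
        key = (ev.contig, ev.site_pos, ev.strand)
        if key not in best or ev.probability > best[key].probability:
            best[key] = ev
    events = _collapse_event_families(list(best.values()), bam)
    return sorted(events, key=lambda e: (e.contig, e.site_pos)), classifiers, library_size


def _collapse_event_families(
    events: list[rm.IPAEvent], bam: pysam.AlignmentFile
) -> list[rm.IPAEvent]:
    """Keep one site per terminal-exon family.

    Candidate sites at different depths of the same intron build the same
    exon hypothesis (identical acceptor for skipped, identical donor for
    composite); they describe a single cleavage event. The family's
    representative is the candidate site closest to the 3' terminus of
    contiguous read coverage extending from the exon 5' boundary, i.e.
    where the transcript actually ends.
    """
    families: dict[tuple, list[rm.IPAEvent]] = {}
    for ev in events:
        anchor = ev.acceptor if ev.kind == "skipped" else (
            ev.exon_start if ev.strand == "+" else ev.exon_end
        )
        families.setdefault((ev.contig, ev.strand, ev.gene_id, ev.kind, anchor), []).append(ev)
    out: list[rm.IPAEvent] = []
    for (contig, strand, _, _, anchor), members in families.items():
        if len(members) == 1:
            out.append(members[0])
            continue
        if strand == "+":
            lo, hi = min(e.exon_start for e in members), max(e.site_pos for e in members) + 1
        else:
            lo, hi = min(e.site_pos for e in members), max(e.exon_end for e in members)
        cov = rm._coverage(bam, contig, lo, hi)
        if strand == "-":
            cov = cov[::-1]  # index 0 = exon 5' boundary in transcription orientation
        plateau = cov[: min(100, len(cov))].mean()
        if plateau <= 0:
            out.append(max(members, key=lambda e: e.probability))
            continue
        # coverage tapers over ~one read length at a 3' terminus, so a low
        # cutoff relative to the plateau localizes the end, while staying
        # above sporadic readthrough
        covered = np.flatnonzero(cov >= 0.1 * plateau)
        t_idx = int(covered[-1]) if covered.size else 0
        terminus = lo + t_idx if strand == "+" else hi - 1 - t_idx
        # a genuine cleavage site cannot sit upstream of where coverage ends
        # (reads would extend past it); allow a few nt of slack for noise
        if strand == "+":
            downstream = [e for e in members if e.site_pos >= terminus - 10]
        else:
            downstream = [e for e in members if e.site_pos <= terminus + 10]
        pool = downstream or members
        out.append(
            min(pool, key=lambda e: (abs(e.site_pos - terminus), -e.probability, e.site_pos))
        )
    return out


def run_sample(
    genome: GenomeBundle,
    genes: list[GeneModel],
    bam_path: str,
    cnn: PolyACnn,
    seed: int = 0,
    scan_threshold: float = 0.5,
    min_per_class: int = 50,
    quantify: bool = True,
    sample: str = "sample1",
) -> SampleResult:
    """Full pipeline for one coordinate-sorted indexed alignment file."""
    introns = nonoverlapped_introns(genes)
    sites = scan_intronic_regions(cnn, genome, introns, threshold=scan_threshold)
    with pysam.AlignmentFile(bam_path) as bam:
        events, classifiers, library_size = detect_ipa_events(
            bam, sites, genes, seed=seed, min_per_class=min_per_class
        )
        result = SampleResult(sites, events, classifiers, library_size)
        if quantify and events:
            result.isoforms = assemble_and_annotate(events, genes, genome)
            tpm = iso.quantify(bam, genes, result.isoforms, sample=sample)
            result.usage = iso.ipa_usage(tpm)
    return result


def assemble_and_annotate(
    events: list[rm.IPAEvent], genes: list[GeneModel], genome: GenomeBundle
) -> list[iso.IPAIsoform]:
    isoforms = []
    by_id = {g.gene_id: g for g in genes}
    for ev in events:
        try:
            isoform = iso.assemble_ipa_isoform(ev, genes)
        except ValueError as exc:
            logger.warning("cannot assemble %s:%d: %s", ev.contig, ev.site_pos, exc)
            continue
        scaffold = next(
            t for t in by_id[isoform.gene_id].transcripts
            if t.transcript_id == isoform.scaffold_id
        )
        isoforms.append(iso.annotate_cds(isoform, genome, scaffold))
    return isoforms


def events_table(events: list[rm.IPAEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": e.contig, "site": e.site_pos, "strand": e.strand,
                "kind": e.kind, "exon_start": e.exon_start, "exon_end": e.exon_end,
                "gene_id": e.gene_id, "acceptor": e.acceptor,
                "probability": e.probability, "support": e.support,
            }
            for e in events
        ]
    )


def usage_by_site(
    result: SampleResult,
) -> dict[tuple[str, int, str], float]:
    """Estimated IPA usage keyed by event site (for |dPAU| benchmarking)."""
    if result.usage is None:
        return {}
    usage_by_iso = dict(zip(result.usage["isoform_id"], result.usage["usage"]))
    out = {}
    for ev in result.events:
        iso_id = f"{ev.gene_id}|{ev.kind}|{ev.site_pos}"
        if iso_id in usage_by_iso:
            out[(ev.contig, ev.site_pos, ev.strand)] = float(usage_by_iso[iso_id])
    return out
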