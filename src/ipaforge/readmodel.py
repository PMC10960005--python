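"""Read module: terminal-exon evidence from RNA-seq alignments.

From each candidate intronic polyA site a candidate region is defined back
to the closest upstream splice donor. Putative terminal exons of two kinds
are constructed from the alignments: *skipped* (a novel acceptor inside the
intron, supported by spliced reads ending in the region) and *composite*
(the upstream exon extended into the intron, supported by unspliced reads
crossing the donor). A sample-specific random-forest ensemble, trained on
annotation-derived terminal / internal / background exons from the same
alignments, then decides which putative exons are genuine.

"Uniquely mapped" means MAPQ >= 20, primary, non-supplementary, and
NH == 1 when the tag is present.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .reference import GeneModel
from .seqmodel import CandidateSite, auroc

logger = logging.getLogger(__name__)

DEFAULT_MIN_SKIPPED_READS = 5   # spliced reads with 3' end in the region
DEFAULT_MIN_COMPOSITE_READS = 10  # unspliced reads crossing the donor
DEFAULT_MIN_REGION_FRAGMENTS = 5
DONOR_CROSS_FLANK = 6  # nt required on both sides of a crossed boundary
MIN_MAPQ = 20

SHARED_FEATURES = [
    "relative_length",
    "norm_expression",
    "coverage_cv",
    "entropy_efficiency",
    "five_prime_spliced_in",
    "five_prime_unspliced_cross",
    "three_prime_cross",
    "three_prime_dropoff",
    "downstream_spliced",
]
KIND_FEATURES = {
    "skipped": SHARED_FEATURES + ["acceptor_support", "acceptor_offset_fraction"],
    "composite": SHARED_FEATURES + ["donor_cross_count", "donor_coverage_ratio"],
}


def is_unique(read: pysam.AlignedSegment) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.mapping_quality < MIN_MAPQ:
        return False
    if read.has_tag("NH") and read.get_tag("NH") != 1:
        return False
    return True


def _junctions(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic (gap_start, gap_end) for every N op in the CIGAR."""
    out = []
    pos = read.reference_start
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            pos += length
        elif op == 3:  # N
            out.append((pos, pos + length))
            pos += length
    return out


def blocks_overlap(read: pysam.AlignedSegment, start: int, end: int) -> bool:
    """True when aligned blocks (not N gaps) intersect [start, end)."""
    return any(bs < end and be > start for bs, be in read.get_blocks())


def count_library_fragments(bam: pysam.AlignmentFile) -> int:
    """Uniquely mapped fragments in the whole file (mate pairs counted once)."""
    n = 0
    for read in bam.fetch():
        if is_unique(read) and (not read.is_paired or read.is_read1):
            n += 1
    return max(n, 1)


@dataclass
class CandidateRegion:
    """Interval from the closest upstream splice donor to a candidate site."""

    site: CandidateSite
    start: int
    end: int
    fragment_count: int = 0

    @property
    def contig(self) -> str:
        return self.site.contig

    @property
    def strand(self) -> str:
        return self.site.strand

    @property
    def donor(self) -> int:
        """Genomic donor boundary (5' edge in transcription orientation)."""
        return self.start if self.strand == "+" else self.end


def define_candidate_region(
    site: CandidateSite, introns=None
) -> CandidateRegion | None:
    """Region from the site back to its host intron's donor; None if the
    site lies in no retained intronic region."""
    region = site.region
    if region is None and introns is not None:
        for r in introns:
            if r.contig == site.contig and r.strand == site.strand and r.contains(site.pos):
                region = r
                break
    if region is None or not region.contains(site.pos):
        return None
    if site.strand == "+":
        return CandidateRegion(site, region.donor, site.pos + 1)
    return CandidateRegion(site, site.pos, region.donor)


def filter_regions_by_count(
    regions: list[CandidateRegion],
    bam: pysam.AlignmentFile,
    min_fragments: int = DEFAULT_MIN_REGION_FRAGMENTS,
) -> list[CandidateRegion]:
    """Retain regions overlapped by >= ``min_fragments`` unique fragments."""
    kept = []
    for region in regions:
        names = set()
        for read in bam.fetch(region.contig, region.start, region.end):
            if is_unique(read) and blocks_overlap(read, region.start, region.end):
                names.add(read.query_name)
        region.fragment_count = len(names)
        if region.fragment_count >= min_fragments:
            kept.append(region)
    return kept


@dataclass
class PutativeTerminalExon:
    """A skipped or composite terminal-exon hypothesis ending at the site."""

    kind: str  # "skipped" | "composite"
    contig: str
    start: int
    end: int
    strand: str
    site_pos: int
    region: CandidateRegion
    acceptor: int | None = None  # genomic first-base coordinate of the novel acceptor exon
    support: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def construct_putative_exons(
    region: CandidateRegion,
    bam: pysam.AlignmentFile,
    min_skipped_reads: int = DEFAULT_MIN_SKIPPED_READS,
    min_composite_reads: int = DEFAULT_MIN_COMPOSITE_READS,
) -> list[PutativeTerminalExon]:
    """Build 0-2 putative terminal exons (both kinds may coexist)."""
    out: list[PutativeTerminalExon] = []
    plus = region.strand == "+"
    site = region.site.pos

    # --- skipped: spliced reads whose acceptor lands in the region and
    # whose 3' aligned end stays in the region
    acceptor_votes: dict[int, int] = {}
    for read in bam.fetch(region.contig, region.start, region.end):
        if not is_unique(read):
            continue
        for gs, ge in _junctions(read):
            if plus:
                # acceptor = first exonic base after the gap
                if region.start < ge <= site and read.reference_end <= region.end:
                    acceptor_votes[ge] = acceptor_votes.get(ge, 0) + 1
            else:
                # acceptor exon is genomically left of the gap, ending at gs
                if site < gs < region.end and read.reference_start >= region.start:
                    acceptor_votes[gs] = acceptor_votes.get(gs, 0) + 1
    if acceptor_votes:
        # max support; ties broken toward the donor
        best = max(
            acceptor_votes.items(),
            key=(lambda kv: (kv[1], -kv[0])) if plus else (lambda kv: (kv[1], kv[0])),
        )
        acc, votes = best
        if votes >= min_skipped_reads:
            if plus:
                exon = PutativeTerminalExon(
                    "skipped", region.contig, acc, site + 1, "+", site, region,
                    acceptor=acc, support=votes,
                )
            else:
                exon = PutativeTerminalExon(
                    "skipped", region.contig, site, acc, "-", site, region,
                    acceptor=acc, support=votes,
                )
            out.append(exon)

    # --- composite: unspliced reads crossing the donor on both sides
    donor = region.donor
    n_cross = 0
    for read in bam.fetch(
        region.contig, max(0, donor - DONOR_CROSS_FLANK), donor + DONOR_CROSS_FLANK
    ):
        if not is_unique(read) or _junctions(read):
            continue
        if (
            read.reference_start <= donor - DONOR_CROSS_FLANK
            and read.reference_end >= donor + DONOR_CROSS_FLANK
        ):
            n_cross += 1
    if n_cross >= min_composite_reads:
        out.append(
            PutativeTerminalExon(
                "composite", region.contig, region.start, region.end,
                region.strand, site, region, support=n_cross,
            )
        )
    return out


@dataclass
class FeatureVector:
    """Named numeric features for one exon hypothesis; all finite."""

    kind: str
    values: dict[str, float] = field(default_factory=dict)

    def as_array(self, schema: list[str]) -> np.ndarray:
        return np.array([self.values[name] for name in schema], dtype=float)


def _coverage(bam: pysam.AlignmentFile, contig: str, start: int, end: int) -> np.ndarray:
    start = max(0, start)
    end = min(bam.get_reference_length(contig), end)
    if end <= start:
        return np.zeros(0)
    cov = bam.count_coverage(
        contig, start, end, quality_threshold=0, read_callback=is_unique
    )
    return np.asarray(cov).sum(axis=0).astype(float)


def extract_features(
    exon: PutativeTerminalExon,
    bam: pysam.AlignmentFile,
    library_size: int,
    donor: int | None = None,
) -> FeatureVector:
    """Compute the fixed feature schema for an exon hypothesis.

    ``donor`` defaults to the exon's candidate-region donor; for
    annotation-derived training exons the caller passes the upstream splice
    boundary of the transcript the exon came from, so the container
    (donor -> exon 3' end) has the same meaning at train and score time.
    """
    plus = exon.strand == "+"
    if donor is None:
        donor = exon.region.donor
    start, end, contig = exon.start, exon.end, exon.contig
    L = end - start
    container_len = (end - donor) if plus else (donor - start)
    if container_len <= 0:
        container_len = L

    cov = _coverage(bam, contig, start, end)
    total = cov.sum()
    if total <= 0:
        raise ValueError(f"zero coverage in exon {contig}:{start}-{end}")
    mean = cov.mean()
    cv = float(cov.std() / mean)
    p = cov[cov > 0] / total
    entropy_eff = float(-(p * np.log2(p)).sum() / np.log2(L)) if L > 1 else 1.0

    five_boundary = start if plus else end
    three_boundary = end if plus else start

    names = set()
    spliced_in = unspliced_cross = three_cross = down_spliced = 0
    for read in bam.fetch(contig, max(0, start - 200), end + 200):
        if not is_unique(read):
            continue
        juncs = _junctions(read)
        if juncs:
            for gs, ge in juncs:
                if plus:
                    if ge == start:
                        spliced_in += 1
                    if start < gs <= end and ge > end:
                        down_spliced += 1
                else:
                    if gs == end:
                        spliced_in += 1
                    if start <= ge < end and gs < start:
                        down_spliced += 1
        else:
            if (
                read.reference_start <= five_boundary - DONOR_CROSS_FLANK
                and read.reference_end >= five_boundary + DONOR_CROSS_FLANK
            ):
                unspliced_cross += 1
        # unspliced continuation past the 3' end by more than 10 nt
        if not any(gs <= three_boundary <= ge for gs, ge in juncs):
            if plus:
                if read.reference_start < end and read.reference_end > end + 10:
                    three_cross += 1
            else:
                if read.reference_end > start and read.reference_start < start - 10:
                    three_cross += 1
        names.add(read.query_name)

    frag_names = set()
    for read in bam.fetch(contig, start, end):
        if is_unique(read) and blocks_overlap(read, start, end):
            frag_names.add(read.query_name)
    norm_expr = len(frag_names) / (L / 1000.0) / (library_size / 1e6)

    w = 50
    if plus:
        inside = cov[-w:] if L >= w else cov
        outside = _coverage(bam, contig, end, end + w)
        five_inside = cov[:w] if L >= w else cov
        five_outside = _coverage(bam, contig, max(0, start - w), start)
    else:
        inside = cov[:w] if L >= w else cov
        outside = _coverage(bam, contig, max(0, start - w), start)
        five_inside = cov[-w:] if L >= w else cov
        five_outside = _coverage(bam, contig, end, end + w)
    eps = 1e-9
    dropoff = min(float(inside.mean() / max(outside.mean() if outside.size else 0.0, eps)), 100.0)
    donor_ratio = min(
        float(five_inside.mean() / max(five_outside.mean() if five_outside.size else 0.0, eps)),
        100.0,
    )

    rel = L / container_len
    values = {
        "relative_length": rel,
        "norm_expression": norm_expr,
        "coverage_cv": cv,
        "entropy_efficiency": entropy_eff,
        "five_prime_spliced_in": float(spliced_in),
        "five_prime_unspliced_cross": float(unspliced_cross),
        "three_prime_cross": float(three_cross),
        "three_prime_dropoff": dropoff,
        "downstream_spliced": float(down_spliced),
        "acceptor_support": float(exon.support if exon.kind == "skipped" else spliced_in),
        "acceptor_offset_fraction": 1.0 - rel,
        "donor_cross_count": float(unspliced_cross),
        "donor_coverage_ratio": donor_ratio,
    }
    for k, val in values.items():
        if not math.isfinite(val):
            raise ValueError(f"non-finite feature {k} for {contig}:{start}-{end}")
    return FeatureVector(exon.kind, values)


@dataclass
class LabeledRegion:
    label: str  # "terminal" | "internal" | "background"
    contig: str
    start: int
    end: int
    strand: str
    features: FeatureVector


def _splice_in_count(bam, contig: str, strand: str, start: int, end: int) -> int:
    n = 0
    for read in bam.fetch(contig, max(0, start - 1), end):
        if not is_unique(read):
            continue
        for gs, ge in _junctions(read):
            if (strand == "+" and ge == start) or (strand == "-" and gs == end):
                n += 1
    return n


def build_training_regions(
    genes: list[GeneModel],
    bam: pysam.AlignmentFile,
    library_size: int | None = None,
    min_splice_in: int = 5,
    min_per_class: int = 50,
) -> list[LabeledRegion]:
    """Label annotation-derived exons from the sample's own alignments.

    Unique last exons with >= ``min_splice_in`` splice-in reads become
    *terminal*, those below the bound *background*; unique internal exons
    with enough splice-in reads become *internal*. Zero-coverage regions are
    dropped before feature extraction. Aborts when terminal or internal
    regions are rarer than ``min_per_class`` (background may legitimately be
    scarce in well-covered samples).
    """
    if library_size is None:
        library_size = count_library_fragments(bam)
    out: list[LabeledRegion] = []
    for gene in genes:
        plus = gene.strand == "+"
        candidates: list[tuple[tuple[int, int], int, bool]] = []  # (exon, donor, is_last)
        seen: set[tuple[int, int]] = set()
        for t in gene.transcripts:
            if len(t.exons) < 2:
                continue
            last = gene.last_exon(t)
            if last not in seen:
                seen.add(last)
                donor = t.exons[-2][1] if plus else t.exons[1][0]
                candidates.append((last, donor, True))
        internal_set = set(gene.unique_internal_exons())
        for t in gene.transcripts:
            for i, exon in enumerate(t.exons[1:-1], start=1):
                if exon in internal_set:
                    internal_set.discard(exon)
                    donor = t.exons[i - 1][1] if plus else t.exons[i + 1][0]
                    candidates.append((exon, donor, False))
        for (s, e), donor, is_last in candidates:
            n_in = _splice_in_count(bam, gene.contig, gene.strand, s, e)
            if is_last:
                label = "terminal" if n_in >= min_splice_in else "background"
            else:
                if n_in < min_splice_in:
                    continue
                label = "internal"
            stub = PutativeTerminalExon(
                "training", gene.contig, s, e, gene.strand,
                e - 1 if plus else s, region=None, support=n_in,
            )
            try:
                fv = extract_features(stub, bam, library_size, donor=donor)
            except ValueError:
                continue  # degenerate (zero coverage)
            out.append(LabeledRegion(label, gene.contig, s, e, gene.strand, fv))
    counts = {lbl: sum(1 for r in out if r.label == lbl) for lbl in ("terminal", "internal", "background")}
    logger.info("training regions: %s", counts)
    for lbl in ("terminal", "internal"):
        if counts[lbl] < min_per_class:
            raise ValueError(
                f"only {counts[lbl]} {lbl} regions (< {min_per_class}); "
                "not enough annotation-derived training data"
            )
    return out


@dataclass
class TerminalExonClassifier:
    """Ensemble of random forests over one feature schema."""

    kind: str
    members: list[RandomForestClassifier]
    schema: list[str]
    threshold: float = 0.5
    metrics: dict = field(default_factory=dict)
    seed: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != len(self.schema):
            raise ValueError("feature schema mismatch")
        return np.mean([m.predict_proba(X)[:, 1] for m in self.members], axis=0)

    def score_features(self, fv: FeatureVector) -> float:
        return float(self.predict_proba(fv.as_array(self.schema)[None, :])[0])


def train_terminal_classifiers(
    labeled: list[LabeledRegion],
    seed: int = 0,
    n_members: int = 10,
    subsample: float = 0.8,
    test_fraction: float = 0.2,
    n_estimators: int = 100,
) -> dict[str, TerminalExonClassifier]:
    """Train the skipped and composite ensembles on labeled regions.

    Positive class = terminal exons; negatives = internal plus background.
    The labeled set is split 80:20 (stratified, seeded); each of the ten
    members is fit on a random 80% subsample (without replacement) of the
    training partition; held-out metrics are stored per classifier.
    """
    y_all = np.array([1 if r.label == "terminal" else 0 for r in labeled])
    if len(np.unique(y_all)) < 2:
        raise ValueError("training regions contain a single class")
    classifiers: dict[str, TerminalExonClassifier] = {}
    for kind_i, kind in enumerate(("skipped", "composite")):
        schema = KIND_FEATURES[kind]
        X_all = np.stack([r.features.as_array(schema) for r in labeled])
        X_tr, X_te, y_tr, y_te = train_test_split(
            X_all, y_all, test_size=test_fraction, random_state=seed, stratify=y_all
        )
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError("single-class partition after split")
        rng = np.random.default_rng(seed * 1000 + kind_i)
        members = []
        n_sub = max(2, int(round(subsample * len(y_tr))))
        for m in range(n_members):
            idx = rng.choice(len(y_tr), size=n_sub, replace=False)
            if len(np.unique(y_tr[idx])) < 2:  # degenerate subsample; resample once
                idx = rng.choice(len(y_tr), size=n_sub, replace=False)
            rf = RandomForestClassifier(
                n_estimators=n_estimators, random_state=int(seed * 1000 + kind_i * 100 + m)
            )
            rf.fit(X_tr[idx], y_tr[idx])
            members.append(rf)
        clf = TerminalExonClassifier(kind, members, schema, seed=seed)
        proba = clf.predict_proba(X_te)
        pred = (proba >= clf.threshold).astype(int)
        counts = ConfusionCounts(
            tp=int(((pred == 1) & (y_te == 1)).sum()),
            tn=int(((pred == 0) & (y_te == 0)).sum()),
            fp=int(((pred == 1) & (y_te == 0)).sum()),
            fn=int(((pred == 0) & (y_te == 1)).sum()),
        )
        clf.metrics = compute_metrics(counts)
        clf.metrics["AUROC"] = auroc(proba, y_te)
        classifiers[kind] = clf
    return classifiers


@dataclass
class IPAEvent:
    """An accepted intronic polyadenylation event."""

    kind: str
    contig: str
    site_pos: int
    strand: str
    exon_start: int
    exon_end: int
    gene_id: str
    probability: float
    acceptor: int | None = None
    support: int = 0


def classify(
    putative: list[tuple[PutativeTerminalExon, FeatureVector]],
    classifiers: dict[str, TerminalExonClassifier],
    threshold: float = 0.5,
) -> list[IPAEvent]:
    """Accept putative exons whose ensemble probability reaches threshold."""
    events = []
    for exon, fv in putative:
        clf = classifiers[exon.kind]
        p = clf.score_features(fv)
        if p >= threshold:
            events.append(
                IPAEvent(
                    exon.kind, exon.contig, exon.site_pos, exon.strand,
                    exon.start, exon.end,
                    exon.region.site.region.gene_id if exon.region else "",
                    p, exon.acceptor, exon.support,
                )
            )
    return events


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion counts")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("empty confusion table")


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """TNR, TPR, ACC, Precision, F1 and MCC from a confusion table."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "TNR": _safe_div(tn, tn + fp, "TNR"),
        "TPR": _safe_div(tp, tp + fn, "TPR"),
        "ACC": (tp + tn) / (tp + tn + fp + fn),
        "Precision": _safe_div(tp, tp + fp, "Precision"),
        "F1": _safe_div(2 * tp, 2 * tp + fp + fn, "F1"),
        "MCC": _safe_div(tp * tn - fp * fn, mcc_den, "MCC"),
    }
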