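"""Candidate regions, putative exons, features, classifiers and metrics."""

import math

import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from ipaforge import (
    ConfusionCounts,
    auroc,
    build_training_regions,
    classify,
    compute_metrics,
    construct_putative_exons,
    define_candidate_region,
    extract_features,
    filter_regions_by_count,
    train_terminal_classifiers,
)
from ipaforge.reference import IntronicRegion
from ipaforge.readmodel import PutativeTerminalExon, count_library_fragments
from ipaforge.seqmodel import CandidateSite

from conftest import write_test_bam


# ---------------------------------------------------------------- metrics


def test_metrics_perfect_classifier():
    m = compute_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
    assert all(v == 1.0 for v in m.values())


def test_metrics_worked_example():
    m = compute_metrics(ConfusionCounts(tp=8, fp=2, tn=7, fn=3))
    assert m["Precision"] == pytest.approx(0.8)
    assert m["F1"] == pytest.approx(16 / 21)
    assert m["MCC"] == pytest.approx(50 / math.sqrt(9900))
    assert m["TNR"] == pytest.approx(7 / 9)
    assert m["TPR"] == pytest.approx(8 / 11)
    assert m["ACC"] == pytest.approx(15 / 20)


def test_metrics_degenerate_denominator_warns():
    with pytest.warns(RuntimeWarning):
        m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
    assert math.isnan(m["Precision"])
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, tn=1, fp=1, fn=1)


@settings(max_examples=1000, deadline=None)
@given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
def test_metrics_against_direct_formulas(counts):
    """MCC bounded; F1 is the harmonic mean of precision and recall."""
    tp, tn, fp, fn = counts
    m = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    if not math.isnan(m["MCC"]):
        assert -1.0 <= m["MCC"] <= 1.0
    p, r = m["Precision"], m["TPR"]
    if not (math.isnan(p) or math.isnan(r)) and p + r > 0:
        assert m["F1"] == pytest.approx(2 * p * r / (p + r))


# ---------------------------------------------------------------- regions


def _site(pos, strand, region):
    return CandidateSite("chrT", pos, strand, 0.9, region)


def test_candidate_region_plus_strand():
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    cr = define_candidate_region(_site(1600, "+", region))
    assert (cr.start, cr.end) == (1000, 1601)
    assert cr.donor == 1000


def test_candidate_region_minus_strand():
    region = IntronicRegion("chrT", 1000, 2000, "-", "g1", 2000)
    cr = define_candidate_region(_site(1300, "-", region))
    assert (cr.start, cr.end) == (1300, 2000)
    assert cr.donor == 2000


def test_site_outside_intron_gives_none():
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    assert define_candidate_region(_site(2500, "+", region)) is None


def test_region_fragment_filter_counts_fragments_once(tmp_path):
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    cr = define_candidate_region(_site(1600, "+", region))
    reads = []
    for i in range(5):  # 5 proper pairs fully inside the region
        reads.append({"qname": f"p{i}", "blocks": [(1100, 1200)], "paired": True, "read1": True})
        reads.append({"qname": f"p{i}", "blocks": [(1250, 1350)], "paired": True, "read1": False})
    # a junction read spanning the region with a gap does not overlap it
    reads.append({"qname": "gap", "blocks": [(900, 990), (2100, 2110)]})
    bam_path = write_test_bam(tmp_path / "cov.bam", "chrT", 5000, reads)
    with pysam.AlignmentFile(bam_path) as bam:
        kept = filter_regions_by_count([cr], bam, min_fragments=5)
        assert kept and kept[0].fragment_count == 5
        assert filter_regions_by_count([cr], bam, min_fragments=6) == []
        empty = define_candidate_region(_site(4500, "+", IntronicRegion("chrT", 4000, 4800, "+", "g2", 4000)))
        assert filter_regions_by_count([empty], bam, min_fragments=1) == []


def _skipped_fixture_reads(n_junction, acceptor=1200):
    reads = []
    for i in range(n_junction):
        reads.append({"qname": f"j{i}", "blocks": [(950, 1000), (acceptor, acceptor + 60)]})
    return reads


def test_skipped_exon_default_bound_is_five(tmp_path):
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    cr = define_candidate_region(_site(1600, "+", region))
    bam4 = write_test_bam(tmp_path / "four.bam", "chrT", 5000, _skipped_fixture_reads(4))
    with pysam.AlignmentFile(bam4) as bam:
        assert construct_putative_exons(cr, bam) == []
    bam5 = write_test_bam(tmp_path / "five.bam", "chrT", 5000, _skipped_fixture_reads(5))
    with pysam.AlignmentFile(bam5) as bam:
        (exon,) = construct_putative_exons(cr, bam)
    assert exon.kind == "skipped"
    assert exon.acceptor == 1200
    assert (exon.start, exon.end) == (1200, 1601)
    assert exon.support == 5


def test_skipped_acceptor_majority_vote_with_donor_tiebreak(tmp_path):
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    cr = define_candidate_region(_site(1600, "+", region))
    reads = _skipped_fixture_reads(6, acceptor=1300) + _skipped_fixture_reads(3, acceptor=1150)
    bam = write_test_bam(tmp_path / "vote.bam", "chrT", 5000, reads)
    with pysam.AlignmentFile(bam) as fh:
        (exon,) = construct_putative_exons(cr, fh)
    assert exon.acceptor == 1300 and exon.support == 6


def test_composite_exon_default_bound_is_ten(tmp_path):
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    cr = define_candidate_region(_site(1600, "+", region))

    def crossing(n):
        return [{"qname": f"c{i}", "blocks": [(960, 1060)]} for i in range(n)]

    bam9 = write_test_bam(tmp_path / "nine.bam", "chrT", 5000, crossing(9))
    with pysam.AlignmentFile(bam9) as bam:
        assert construct_putative_exons(cr, bam) == []
    bam10 = write_test_bam(tmp_path / "ten.bam", "chrT", 5000, crossing(10))
    with pysam.AlignmentFile(bam10) as bam:
        (exon,) = construct_putative_exons(cr, bam)
    assert exon.kind == "composite"
    assert (exon.start, exon.end) == (1000, 1601)
    assert exon.support == 10


def test_non_unique_reads_are_ignored(tmp_path):
    region = IntronicRegion("chrT", 1000, 2000, "+", "g1", 1000)
    cr = define_candidate_region(_site(1600, "+", region))
    reads = [{"qname": f"c{i}", "blocks": [(960, 1060)], "mapq": 5} for i in range(20)]
    reads += [{"qname": f"d{i}", "blocks": [(960, 1060)], "nh": 3} for i in range(20)]
    bam = write_test_bam(tmp_path / "multi.bam", "chrT", 5000, reads)
    with pysam.AlignmentFile(bam) as fh:
        assert construct_putative_exons(cr, fh) == []
        assert count_library_fragments(fh) == 1  # floor value, nothing unique


# ---------------------------------------------------------------- features


def _stub_exon(start, end, strand="+", site=None):
    return PutativeTerminalExon(
        "training", "chrT", start, end, strand,
        site if site is not None else (end - 1 if strand == "+" else start),
        region=None,
    )


def test_uniform_coverage_entropy_and_cv(tmp_path):
    reads = [{"qname": f"u{i}", "blocks": [(100, 200)]} for i in range(3)]
    bam = write_test_bam(tmp_path / "uni.bam", "chrT", 1000, reads)
    with pysam.AlignmentFile(bam) as fh:
        fv = extract_features(_stub_exon(100, 200), fh, library_size=1000, donor=50)
    assert fv.values["entropy_efficiency"] == pytest.approx(1.0)
    assert fv.values["coverage_cv"] == pytest.approx(0.0)
    assert fv.values["three_prime_cross"] == 0.0
    assert fv.values["three_prime_dropoff"] == 100.0  # nothing downstream


def test_point_coverage_entropy_zero_cv_sqrt_l_minus_one(tmp_path):
    reads = [{"qname": "one", "blocks": [(150, 151)]}]
    bam = write_test_bam(tmp_path / "point.bam", "chrT", 1000, reads)
    with pysam.AlignmentFile(bam) as fh:
        fv = extract_features(_stub_exon(100, 200), fh, library_size=1000, donor=50)
    assert fv.values["entropy_efficiency"] == pytest.approx(0.0)
    assert fv.values["coverage_cv"] == pytest.approx(math.sqrt(99))


def test_zero_coverage_exon_raises(tmp_path):
    bam = write_test_bam(tmp_path / "empty.bam", "chrT", 1000,
                         [{"qname": "far", "blocks": [(900, 950)]}])
    with pysam.AlignmentFile(bam) as fh:
        with pytest.raises(ValueError):
            extract_features(_stub_exon(100, 200), fh, library_size=1000, donor=50)


def test_three_prime_cross_counts_readthrough(tmp_path):
    reads = [{"qname": f"u{i}", "blocks": [(150, 261)]} for i in range(4)]
    bam = write_test_bam(tmp_path / "rt.bam", "chrT", 1000, reads)
    with pysam.AlignmentFile(bam) as fh:
        fv = extract_features(_stub_exon(100, 250), fh, library_size=1000, donor=50)
    assert fv.values["three_prime_cross"] == 4.0


# ---------------------------------------------------------------- training


@pytest.fixture(scope="module")
def sim_training(classifier_training):
    return classifier_training


def test_training_region_labels(sim_training, classifier_sim):
    genes = classifier_sim["genes"]
    labels = {r.label for r in sim_training}
    assert "terminal" in labels and "internal" in labels
    by_label = {lbl: [r for r in sim_training if r.label == lbl] for lbl in labels}
    # terminal regions are annotated last exons
    last_exons = {
        (g.contig, *g.last_exon(t))
        for g in genes
        for t in g.transcripts
    }
    for r in by_label["terminal"]:
        assert (r.contig, r.start, r.end) in last_exons
    # background regions are last exons too, just poorly supported
    for r in by_label.get("background", []):
        assert (r.contig, r.start, r.end) in last_exons
    # internal regions are never last or first exons
    firsts = {(g.contig, *g.first_exon(t)) for g in genes for t in g.transcripts}
    for r in by_label.get("internal", []):
        key = (r.contig, r.start, r.end)
        assert key not in last_exons and key not in firsts


def test_training_region_splice_in_boundary(tmp_path, toy_genes):
    """Last exons need five splice-in reads to count as terminal."""
    import ipaforge.readmodel as rm

    gene = toy_genes[0]
    t = gene.transcripts[0]
    exon = gene.last_exon(t)
    reads = []
    for i in range(7):
        if gene.strand == "+":
            reads.append({"qname": f"s{i}", "blocks": [(exon[0] - 80, exon[0] - 30), (exon[0], exon[0] + 50)]})
        else:
            reads.append({"qname": f"s{i}", "blocks": [(exon[1] - 50, exon[1]), (exon[1] + 30, exon[1] + 80)]})
    bam = write_test_bam(tmp_path / "si.bam", gene.contig, 10**6, reads)
    with pysam.AlignmentFile(bam) as fh:
        assert rm._splice_in_count(fh, gene.contig, gene.strand, exon[0], exon[1]) == 7


def test_classifier_separates_and_is_reproducible(sim_training):
    clfs1 = train_terminal_classifiers(sim_training, seed=4)
    clfs2 = train_terminal_classifiers(sim_training, seed=4)
    for kind in ("skipped", "composite"):
        assert clfs1[kind].metrics["AUROC"] >= 0.95
        assert len(clfs1[kind].members) == 10
        X = np.stack([r.features.as_array(clfs1[kind].schema) for r in sim_training])
        assert np.array_equal(clfs1[kind].predict_proba(X), clfs2[kind].predict_proba(X))


def test_classifier_shuffled_labels_near_chance(sim_training):
    rng = np.random.default_rng(0)
    shuffled = list(sim_training)
    labels = [r.label for r in shuffled]
    permuted = rng.permutation(labels)
    relabeled = [
        type(r)(lbl, r.contig, r.start, r.end, r.strand, r.features)
        for r, lbl in zip(shuffled, permuted)
    ]
    clfs = train_terminal_classifiers(relabeled, seed=4)
    # near chance; the held-out partition is a few dozen regions, so the
    # rank statistic is coarse
    for kind in ("skipped", "composite"):
        assert abs(clfs[kind].metrics["AUROC"] - 0.5) <= 0.2


def test_classify_threshold_behavior(sim_training, toy_sim, toy_genes):
    clfs = train_terminal_classifiers(sim_training, seed=4)
    region = IntronicRegion("chrS", 1000, 2000, "+", "G000", 1000)
    cr = define_candidate_region(_site(1600, "+", region))
    exon = PutativeTerminalExon("skipped", "chrS", 1200, 1601, "+", 1600, cr,
                                acceptor=1200, support=9)
    fv = type(sim_training[0].features)("skipped",
                                        dict(sim_training[0].features.values))
    accepted = classify([(exon, fv)], clfs, threshold=0.0)
    assert len(accepted) == 1 and 0.0 <= accepted[0].probability <= 1.0
    assert classify([(exon, fv)], clfs, threshold=1.01) == []
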