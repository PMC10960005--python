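"""Isoform assembly, CDS annotation, augmented GTF and quantification."""

import numpy as np
import pandas as pd
import pysam
import pytest

from ipaforge import (
    GeneModel,
    TranscriptModel,
    annotate_cds,
    assemble_ipa_isoform,
    ipa_usage,
    load_annotation,
    load_genome,
    quantify,
    read_salmon_table,
    retained_cdr_fraction,
    write_augmented_gtf,
)
from ipaforge.isoform import IPAIsoform, spliced_sequence, STOP_CODONS
from ipaforge.readmodel import IPAEvent


def _gene_4exon():
    t = TranscriptModel(
        "t1",
        exons=[(100, 200), (300, 400), (500, 600), (700, 800)],
        cds=[(150, 200), (300, 400), (500, 550)],
    )
    return GeneModel("g1", "chrT", "+", [t])


def test_assemble_composite_extends_flanking_exon():
    gene = _gene_4exon()
    ev = IPAEvent("composite", "chrT", 450, "+", 400, 451, "g1", 0.9)
    iso = assemble_ipa_isoform(ev, [gene])
    assert iso.exons == [(100, 200), (300, 451)]
    assert iso.scaffold_id == "t1"
    assert iso.isoform_id == "g1|composite|450"


def test_assemble_skipped_terminal_exon_is_acceptor_to_site():
    gene = _gene_4exon()
    ev = IPAEvent("skipped", "chrT", 470, "+", 430, 471, "g1", 0.9, acceptor=430)
    iso = assemble_ipa_isoform(ev, [gene])
    assert iso.exons == [(100, 200), (300, 400), (430, 471)]


def test_assemble_minus_strand():
    t = TranscriptModel("t1", exons=[(100, 200), (300, 400), (500, 600)])
    gene = GeneModel("g1", "chrT", "-", [t])
    ev = IPAEvent("composite", "chrT", 250, "-", 250, 300, "g1", 0.9)
    iso = assemble_ipa_isoform(ev, [gene])
    assert iso.exons == [(250, 400), (500, 600)]
    ev2 = IPAEvent("skipped", "chrT", 210, "-", 210, 280, "g1", 0.9, acceptor=280)
    iso2 = assemble_ipa_isoform(ev2, [gene])
    assert iso2.exons == [(210, 280), (300, 400), (500, 600)]


def test_assemble_requires_host_intron():
    gene = _gene_4exon()
    ev = IPAEvent("composite", "chrT", 150, "+", 100, 151, "g1", 0.9)  # inside exon 1
    with pytest.raises(ValueError):
        assemble_ipa_isoform(ev, [gene])


def test_scaffold_prefers_longest_cds():
    short = TranscriptModel("a_short", exons=[(100, 200), (300, 400)], cds=[(150, 180)])
    long = TranscriptModel("b_long", exons=[(100, 200), (300, 400)],
                           cds=[(150, 200), (300, 380)])
    gene = GeneModel("g1", "chrT", "+", [short, long])
    ev = IPAEvent("composite", "chrT", 250, "+", 200, 251, "g1", 0.9)
    assert assemble_ipa_isoform(ev, [gene]).scaffold_id == "b_long"


def test_simdata_events_assemble_to_truth_structures(toy_sim, toy_genes):
    truth = toy_sim["truth"]
    for g in truth.ipa_genes():
        ipa = g.ipa
        if g.strand == "+":
            ev = IPAEvent(ipa.kind, g.contig, ipa.site, "+",
                          ipa.isoform_exons[-1][0], ipa.site + 1, g.gene_id, 1.0,
                          acceptor=ipa.acceptor)
        else:
            ev = IPAEvent(ipa.kind, g.contig, ipa.site, "-",
                          ipa.site, ipa.isoform_exons[0][1], g.gene_id, 1.0,
                          acceptor=None if ipa.acceptor is None else ipa.acceptor + 1)
        iso = assemble_ipa_isoform(ev, toy_genes)
        assert iso.exons == ipa.isoform_exons


# ---------------------------------------------------------------- CDS


def _independent_cds_scan(genome, iso, scaffold):
    """Oracle: locate the first in-frame stop by scanning the spliced sequence."""
    seq = spliced_sequence(genome, iso.contig, iso.strand, iso.exons)
    if not scaffold.cds:
        return None
    start_base = scaffold.cds[0][0] if iso.strand == "+" else scaffold.cds[-1][1] - 1
    off = 0
    found = None
    for s, e in (iso.exons if iso.strand == "+" else reversed(iso.exons)):
        if s <= start_base < e:
            found = off + (start_base - s if iso.strand == "+" else e - 1 - start_base)
        off += e - s
    if found is None:
        return None
    for o in range(found, len(seq) - 2, 3):
        if seq[o : o + 3] in STOP_CODONS:
            return (found, o + 3)
    return None


def test_cds_annotation_matches_independent_scan(toy_sim, toy_genes, toy_genome):
    truth = toy_sim["truth"]
    by_id = {g.gene_id: g for g in toy_genes}
    for g in truth.ipa_genes():
        iso = IPAIsoform(g.ipa_isoform_id, g.gene_id, g.transcript_id, g.ipa.kind,
                         g.contig, g.strand, list(g.ipa.isoform_exons), g.ipa.site)
        scaffold = by_id[g.gene_id].transcripts[0]
        annotate_cds(iso, toy_genome, scaffold)
        oracle = _independent_cds_scan(toy_genome, iso, scaffold)
        if oracle is None:
            assert iso.coding is False
        else:
            assert iso.coding
            assert iso.cds_length == oracle[1] - oracle[0]
            # always a whole number of codons ending in a stop triplet
            assert iso.cds_length % 3 == 0
            seq = spliced_sequence(toy_genome, iso.contig, iso.strand, iso.exons)
            assert seq[oracle[1] - 3 : oracle[1]] in STOP_CODONS


def test_noncoding_when_site_upstream_of_start(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">c\n" + "ACGT" * 300 + "\n")
    genome = load_genome(str(fa))
    t = TranscriptModel("t1", exons=[(100, 200), (500, 700)], cds=[(650, 680)])
    iso = IPAIsoform("i1", "g1", "t1", "composite", "c", "+", [(100, 250)], 249)
    annotate_cds(iso, genome, t)
    assert iso.coding is False
    # scaffold without CDS is always non-coding
    t2 = TranscriptModel("t2", exons=[(100, 200)])
    iso2 = IPAIsoform("i2", "g1", "t2", "composite", "c", "+", [(100, 150)], 149)
    assert annotate_cds(iso2, genome, t2).coding is False


def test_cds_identical_when_scaffold_stop_retained(toy_genome, toy_genes):
    """Site downstream of the annotated stop keeps the scaffold CDS."""
    gene = toy_genes[0]
    t = gene.transcripts[0]
    iso = IPAIsoform("x", gene.gene_id, t.transcript_id, "composite", gene.contig,
                     gene.strand, list(t.exons), 0)
    annotate_cds(iso, toy_genome, t)
    assert iso.coding and iso.cds == t.cds


def test_retained_cdr_fraction():
    gene = _gene_4exon()  # longest CDS = 200 nt
    iso = IPAIsoform("i", "g1", "t1", "composite", "chrT", "+", [(100, 200)], 199)
    iso.coding = False
    assert retained_cdr_fraction(iso, gene) == 0.0
    iso.coding = True
    iso.cds = [(150, 200)]
    assert retained_cdr_fraction(iso, gene) == pytest.approx(50 / 200)
    iso.cds = [(150, 200), (300, 400), (500, 550)]
    assert retained_cdr_fraction(iso, gene) == 1.0
    bare = GeneModel("g2", "chrT", "+", [TranscriptModel("t", exons=[(0, 10)])])
    assert retained_cdr_fraction(iso, bare) is None


# ---------------------------------------------------------------- GTF


def test_augmented_gtf_round_trip(toy_sim, toy_genes, toy_genome, tmp_path):
    truth = toy_sim["truth"]
    by_id = {g.gene_id: g for g in toy_genes}
    isoforms = []
    for g in truth.ipa_genes():
        iso = IPAIsoform(g.ipa_isoform_id, g.gene_id, g.transcript_id, g.ipa.kind,
                         g.contig, g.strand, list(g.ipa.isoform_exons), g.ipa.site)
        annotate_cds(iso, toy_genome, by_id[g.gene_id].transcripts[0])
        isoforms.append(iso)
    out = tmp_path / "augmented.gtf"
    write_augmented_gtf(toy_genes, isoforms, str(out))
    reloaded = load_annotation(str(out))
    by_tid = {t.transcript_id: t for g in reloaded for t in g.transcripts}
    for iso in isoforms:
        assert by_tid[iso.isoform_id].exons == iso.exons
        assert by_tid[iso.isoform_id].cds == iso.cds
    # reference structures preserved
    for g in toy_genes:
        for t in g.transcripts:
            assert by_tid[t.transcript_id].exons == t.exons


def test_augmented_gtf_without_isoforms_equals_reference(toy_genes, tmp_path):
    a, b = tmp_path / "a.gtf", tmp_path / "b.gtf"
    from ipaforge import write_gtf

    write_gtf(toy_genes, str(a))
    write_augmented_gtf(toy_genes, [], str(b))
    assert a.read_text() == b.read_text()


# ---------------------------------------------------------------- quantify


@pytest.fixture(scope="module")
def truth_isoform_quant(toy_sim, toy_genes, toy_genome):
    truth = toy_sim["truth"]
    isoforms = [
        IPAIsoform(g.ipa_isoform_id, g.gene_id, g.transcript_id, g.ipa.kind,
                   g.contig, g.strand, list(g.ipa.isoform_exons), g.ipa.site)
        for g in truth.ipa_genes()
    ]
    with pysam.AlignmentFile(toy_sim["bam"]) as bam:
        table = quantify(bam, toy_genes, isoforms, sample="s1")
    return table, isoforms


def test_tpm_normalization(truth_isoform_quant):
    table, _ = truth_isoform_quant
    assert table["TPM"].sum() == pytest.approx(1e6, abs=1e-3)
    assert (table["TPM"] >= 0).all()


def test_usage_recovers_planted_mixture(truth_isoform_quant, toy_sim):
    table, _ = truth_isoform_quant
    usage = ipa_usage(table)
    by_iso = dict(zip(usage["isoform_id"], usage["usage"]))
    errors = [
        abs(by_iso[g.ipa_isoform_id] - g.ipa.usage)
        for g in toy_sim["truth"].ipa_genes()
    ]
    assert np.median(errors) <= 0.10
    assert max(errors) <= 0.25


def test_usage_sums_to_one_per_gene(truth_isoform_quant):
    usage = ipa_usage(truth_isoform_quant[0])
    sums = usage.groupby(["sample", "gene_id"])["usage"].sum().dropna()
    assert np.allclose(sums, 1.0)


def test_exclusive_fragments_give_zero_to_unsupported_isoform(tmp_path, toy_genome):
    """All fragments on exon 1+2 junction of isoform A only -> TPM(B)=0."""
    from conftest import write_test_bam

    ta = TranscriptModel("A", exons=[(100, 300), (500, 700)])
    tb = TranscriptModel("B", exons=[(100, 300), (900, 1100)])
    gene = GeneModel("g", "chrT", "+", [ta, tb])
    reads = [
        {"qname": f"r{i}", "blocks": [(250, 300), (500, 550)]} for i in range(20)
    ]
    bam = write_test_bam(tmp_path / "ab.bam", "chrT", 2000, reads)
    table = quantify(bam, [gene], [], sample="x")
    tpm = dict(zip(table["isoform_id"], table["TPM"]))
    assert tpm["B"] == 0.0
    assert tpm["A"] == pytest.approx(1e6)


def test_usage_single_isoform_and_zero_gene():
    table = pd.DataFrame(
        {
            "sample": ["s", "s", "s"],
            "gene_id": ["g1", "g2", "g2"],
            "isoform_id": ["i1", "i2", "i3"],
            "TPM": [5.0, 0.0, 0.0],
        }
    )
    out = ipa_usage(table)
    assert out.loc[0, "usage"] == 1.0
    assert out.loc[1:, "usage"].isna().all()
    arithmetic = ipa_usage(pd.DataFrame(
        {"sample": ["s", "s"], "gene_id": ["g", "g"],
         "isoform_id": ["ipa", "fl"], "TPM": [30.0, 70.0]}))
    assert arithmetic.loc[0, "usage"] == pytest.approx(0.3)


def test_salmon_table_reader(tmp_path, toy_genes):
    path = tmp_path / "quant.sf"
    tid = toy_genes[0].transcripts[0].transcript_id
    path.write_text(
        "Name\tLength\tEffectiveLength\tTPM\tNumReads\n"
        f"{tid}\t1000\t800\t12.5\t42\n"
    )
    table = quantify(str(path), toy_genes, [], mode="external-table", sample="s")
    row = table[table["isoform_id"] == tid].iloc[0]
    assert row["TPM"] == 12.5 and row["num_reads"] == 42
    # absent transcripts get zero TPM
    assert (table[table["isoform_id"] != tid]["TPM"] == 0).all()
    bad = tmp_path / "bad.sf"
    bad.write_text("Name\tTPM\nx\t1\n")
    with pytest.raises(ValueError):
        read_salmon_table(str(bad))
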