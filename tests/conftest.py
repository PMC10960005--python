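"""Shared fixtures: synthetic references, alignments and trained models.

Everything is generated programmatically at test time; session scope keeps
the expensive artifacts (trained CNN, simulated replicates) shared across
test modules.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from ipaforge import (
    CnnConfig,
    load_annotation,
    load_genome,
    nonoverlapped_introns,
    one_hot_encode,
    build_sequence_training_set,
    train_polya_cnn,
)
from ipaforge.simdata import SimConfig, make_toy_reference, simulate_alignments


@pytest.fixture(scope="session")
def toy_sim(tmp_path_factory):
    """30-gene toy reference with IPA truth plus a 50X replicate (seed 1)."""
    outdir = tmp_path_factory.mktemp("toysim")
    cfg = SimConfig(n_genes=30, seed=1)
    fasta, gtf, truth = make_toy_reference(cfg, str(outdir))
    bam = str(outdir / "reads50.bam")
    simulate_alignments(truth, fasta, bam, seed=1)
    return {
        "dir": outdir,
        "config": cfg,
        "fasta": fasta,
        "gtf": gtf,
        "truth": truth,
        "bam": bam,
    }


@pytest.fixture(scope="session")
def toy_genome(toy_sim):
    return load_genome(toy_sim["fasta"])


@pytest.fixture(scope="session")
def toy_genes(toy_sim):
    return load_annotation(toy_sim["gtf"])


@pytest.fixture(scope="session")
def toy_introns(toy_genes):
    return nonoverlapped_introns(toy_genes)


@pytest.fixture(scope="session")
def classifier_sim(tmp_path_factory):
    """60-gene sample used for read-module classifier training checks."""
    outdir = tmp_path_factory.mktemp("clssim")
    cfg = SimConfig(n_genes=60, seed=11)
    fasta, gtf, truth = make_toy_reference(cfg, str(outdir))
    bam = str(outdir / "reads.bam")
    simulate_alignments(truth, fasta, bam, seed=11)
    return {"fasta": fasta, "gtf": gtf, "truth": truth, "bam": bam,
            "genes": load_annotation(gtf)}


@pytest.fixture(scope="session")
def classifier_training(classifier_sim):
    import pysam
    from ipaforge import build_training_regions

    with pysam.AlignmentFile(classifier_sim["bam"]) as bam:
        return build_training_regions(classifier_sim["genes"], bam, min_per_class=5)


@pytest.fixture(scope="session")
def trained_cnn(tmp_path_factory):
    """CNN trained on a larger toy reference's annotated polyA sites."""
    outdir = tmp_path_factory.mktemp("cnn_ref")
    cfg = SimConfig(n_genes=300, seed=42)
    fasta, gtf, _ = make_toy_reference(cfg, str(outdir))
    genome = load_genome(fasta)
    genes = load_annotation(gtf)
    windows = build_sequence_training_set(genes, genome, seed=3)
    return train_polya_cnn(windows, config=CnnConfig(max_epochs=50), seed=7)


def motif_window_set(n: int, seed: int, offset: int = 16):
    """Random 201-nt windows; the first half carry AATAAA upstream of center."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n):
        seq = rng.choice(list("ACGT"), 201)
        if i < n // 2:
            seq[100 - offset : 100 - offset + 6] = list("AATAAA")
            y.append(1)
        else:
            y.append(0)
        X.append(one_hot_encode("".join(seq)))
    return np.stack(X), np.array(y)


@pytest.fixture(scope="session")
def motif_cnn():
    """CNN trained to spot a planted hexamer; used by several sanity tests."""
    X, y = motif_window_set(500, seed=0)
    return train_polya_cnn(X, y, CnnConfig(max_epochs=40), seed=5)


def write_test_bam(path, contig, length, reads):
    """Write a tiny coordinate-sorted indexed BAM from block specs.

    ``reads`` is a list of dicts with keys: qname, blocks (list of genomic
    (start, end)), and optional mapq, nh, paired, read1, reverse, secondary.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": length}]}
    )
    recs = []
    for spec in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = spec["qname"]
        a.reference_id = 0
        blocks = spec["blocks"]
        a.reference_start = blocks[0][0]
        cig = []
        for i, (s, e) in enumerate(blocks):
            if i:
                cig.append((3, s - blocks[i - 1][1]))
            cig.append((0, e - s))
        a.cigartuples = cig
        rlen = sum(e - s for s, e in blocks)
        a.query_sequence = "A" * rlen
        a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
        a.mapping_quality = spec.get("mapq", 60)
        a.set_tag("NH", spec.get("nh", 1))
        if spec.get("paired"):
            a.is_paired = True
            a.is_proper_pair = True
            a.is_read1 = spec.get("read1", True)
            a.is_read2 = not spec.get("read1", True)
        a.is_reverse = spec.get("reverse", False)
        a.is_secondary = spec.get("secondary", False)
        recs.append(a)
    recs.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for r in recs:
            fh.write(r)
    pysam.index(str(path))
    return str(path)
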