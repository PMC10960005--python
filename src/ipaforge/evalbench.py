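"""Benchmarking utilities for polyA-site predictions.

Distance-based matching of predicted sites against a ground-truth set
(true positive within 50 nt by default), sensitivity/precision, relative
usage error (|dPAU|) summaries, polyA-signal hexamer frequencies and
enrichment in upstream windows, random intronic control sites, and
positional nucleotide profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .reference import GenomeBundle, IntronicRegion, fetch_window

logger = logging.getLogger(__name__)

Site = tuple[str, int, str]  # (contig, 0-based position, strand)

CANONICAL_SIGNALS = ("AATAAA", "ATTAAA")


@dataclass(frozen=True)
class SignalCatalog:
    """Ordered polyA-signal hexamers; order is the match priority."""

    signals: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.signals)) != len(self.signals):
            raise ValueError("duplicate signals in catalog")
        for s in self.signals:
            if len(s) != 6 or set(s) - set("ACGT"):
                raise ValueError(f"invalid hexamer {s!r}")

    @classmethod
    def default(cls) -> "SignalCatalog":
        text = resources.files("ipaforge.data").joinpath("polya_signals.txt").read_text()
        return cls.from_lines(text.splitlines())

    @classmethod
    def from_lines(cls, lines) -> "SignalCatalog":
        signals = [ln.strip().upper() for ln in lines if ln.strip() and not ln.startswith("#")]
        # the two canonical signals always lead the priority order
        ordered = [s for s in CANONICAL_SIGNALS if s in signals]
        ordered += [s for s in signals if s not in CANONICAL_SIGNALS]
        return cls(tuple(ordered))

    @classmethod
    def load(cls, path: str) -> "SignalCatalog":
        with open(path) as fh:
            return cls.from_lines(fh)


@dataclass(frozen=True)
class SiteMatch:
    predicted: Site
    nearest_truth: Site | None
    distance: int | None  # signed, transcription orientation (predicted - truth)
    label: str  # "TP" | "FP"


def match_sites(
    predicted: list[Site], truth: list[Site], max_dist: int = 50
) -> list[SiteMatch]:
    """Assign each predicted site to its nearest same-strand truth site.

    A prediction within ``max_dist`` nt of its nearest truth site is a TP,
    otherwise an FP. Distances are signed in transcription orientation.
    """
    if not truth:
        raise ValueError("empty truth set")
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for contig, pos, strand in truth:
        by_key.setdefault((contig, strand), []).append(pos)
    by_key = {k: np.array(sorted(v)) for k, v in by_key.items()}
    out = []
    for site in predicted:
        contig, pos, strand = site
        arr = by_key.get((contig, strand))
        if arr is None:
            out.append(SiteMatch(site, None, None, "FP"))
            continue
        i = int(np.searchsorted(arr, pos))
        best = min(
            (int(arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)),
            key=lambda t: (abs(pos - t), t),
        )
        signed = (pos - best) if strand == "+" else (best - pos)
        label = "TP" if abs(signed) <= max_dist else "FP"
        out.append(SiteMatch(site, (contig, best, strand), signed, label))
    return out


def sensitivity_precision(
    matches: list[SiteMatch], n_truth: int
) -> tuple[float, float]:
    """Sensitivity = truth sites hit / truth sites; Precision = TP / (TP+FP).

    A truth site hit by several predictions counts once toward sensitivity.
    With no predictions, sensitivity is 0 and precision undefined (NaN).
    """
    if n_truth <= 0:
        raise ValueError("n_truth must be positive")
    if not matches:
        logger.warning("no predictions; precision undefined")
        return 0.0, float("nan")
    tp_matches = [m for m in matches if m.label == "TP"]
    hit_truth = {m.nearest_truth for m in tp_matches}
    sensitivity = min(len(hit_truth), n_truth) / n_truth
    precision = len(tp_matches) / len(matches)
    return sensitivity, precision


def delta_pau(
    estimated_usage: dict[Site, float],
    truth_usage: dict[Site, float],
    cdf_points: tuple[float, ...] = (0.05, 0.10, 0.20),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Absolute usage error per matched site plus an empirical CDF summary."""
    rows = []
    for site, est in estimated_usage.items():
        if site not in truth_usage:
            raise KeyError(f"site {site} not present in truth usage")
        rows.append({"site": site, "estimated": est, "truth": truth_usage[site],
                     "abs_error": abs(est - truth_usage[site])})
    table = pd.DataFrame(rows)
    errors = table["abs_error"].to_numpy() if len(table) else np.array([])
    summary = {f"cdf_{p:g}": float(np.mean(errors <= p)) if errors.size else float("nan")
               for p in cdf_points}
    summary["median"] = float(np.median(errors)) if errors.size else float("nan")
    return table, summary


def sample_random_intronic_sites(
    introns: list[IntronicRegion], n: int | None = None, seed: int = 0,
    size_match: int | None = None,
) -> list[Site]:
    """Uniform sample of intronic bases (without replacement), seeded."""
    if not introns:
        raise ValueError("empty intron set")
    if n is None:
        if size_match is None:
            raise ValueError("either n or size_match is required")
        n = size_match
    lengths = np.array([r.end - r.start for r in introns])
    total = int(lengths.sum())
    if n > total:
        raise ValueError(f"requested {n} sites from {total} intronic bases")
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.choice(total, size=n, replace=False))
    bounds = np.cumsum(lengths)
    sites = []
    for off in offsets:
        i = int(np.searchsorted(bounds, off, side="right"))
        r = introns[i]
        base = int(off - (bounds[i - 1] if i else 0))
        sites.append((r.contig, r.start + base, r.strand))
    return sites


def polya_signal_scan(
    sites: list[Site],
    genome: GenomeBundle,
    catalog: SignalCatalog | None = None,
    upstream: int = 60,
    control: list[Site] | None = None,
) -> pd.DataFrame:
    """Highest-priority signal hexamer per upstream window, with frequencies.

    Each site contributes the first catalog hexamer found in its
    strand-aware ``upstream``-nt window (or "none"); frequencies over the
    catalog plus "none" sum to 1. With a control site set, per-signal
    enrichment is tested one-sided by the hypergeometric distribution.
    """
    catalog = catalog or SignalCatalog.default()

    def best_signal(window: str) -> str:
        for sig in catalog.signals:
            if sig in window:
                return sig
        return "none"

    def windows(site_list):
        hits = []
        for contig, pos, strand in site_list:
            lo = pos - upstream if strand == "+" else pos + 1
            hi = pos if strand == "+" else pos + 1 + upstream
            if lo < 0 or hi > genome.contig_lengths[contig]:
                logger.warning("upstream window off contig at %s:%d; skipped", contig, pos)
                continue
            seq = genome.fetch(contig, lo, hi)
            if strand == "-":
                from .reference import reverse_complement

                seq = reverse_complement(seq)
            hits.append(best_signal(seq))
        return hits

    fg = windows(sites)
    labels = list(catalog.signals) + ["none"]
    rows = []
    ctrl = windows(control) if control else None
    for sig in labels:
        n_fg = fg.count(sig)
        row = {"signal": sig, "count": n_fg, "frequency": n_fg / len(fg) if fg else np.nan}
        if ctrl is not None and sig != "none":
            n_ctrl = ctrl.count(sig)
            M = len(fg) + len(ctrl)
            K = n_fg + n_ctrl
            row["control_frequency"] = n_ctrl / len(ctrl) if ctrl else np.nan
            row["p_enrichment"] = float(hypergeom.sf(n_fg - 1, M, K, len(fg)))
        rows.append(row)
    return pd.DataFrame(rows)


def nucleotide_profile(
    sites: list[Site], genome: GenomeBundle, flank: int = 100
) -> pd.DataFrame:
    """Per-position base fractions over strand-aware windows around sites.

    Rows are positions -flank..flank (0 = the site); N bases are excluded
    from the per-position denominator, so A+C+G+T fractions sum to 1.
    """
    if not sites:
        raise ValueError("empty site set")
    L = 2 * flank + 1
    counts = np.zeros((L, 4), dtype=float)
    bases = "ACGT"
    idx = {b: i for i, b in enumerate(bases)}
    used = 0
    for contig, pos, strand in sites:
        if pos - flank < 0 or pos + flank + 1 > genome.contig_lengths[contig]:
            logger.warning("profile window off contig at %s:%d; skipped", contig, pos)
            continue
        seq = fetch_window(genome, contig, pos, flank, strand)
        for i, ch in enumerate(seq):
            if ch in idx:
                counts[i, idx[ch]] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable windows")
    denom = counts.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    frac = counts / denom
    out = pd.DataFrame(frac, columns=list(bases))
    out.insert(0, "offset", np.arange(-flank, flank + 1))
    return out
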