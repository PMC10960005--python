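"""Sequence module: a convolutional polyA-site classifier and intron scanner.

A small CNN (two convolution+ReLU+max-pool pairs, one fully connected hidden
layer, dropout, sigmoid output) is trained to separate 201-nt windows
centered on annotated polyA sites from windows drawn at random from
intergenic space, then slid across non-overlapped intronic regions to
propose candidate intronic polyadenylation sites.

The network is implemented directly in NumPy (im2col convolutions, manual
backpropagation, Adam), which keeps training bit-reproducible under a fixed
seed and dependency-light. Inputs are one-hot encoded with row order
(A, T, G, C); ambiguous bases (N) are encoded as uniform 0.25 so every
column still sums to one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import roc_auc_score

from .reference import GenomeBundle, GeneModel, IntronicRegion, fetch_window, reverse_complement
from ._intervals import merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

_ROW = {"A": 0, "T": 1, "G": 2, "C": 3}


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a 4 x L matrix, rows ordered (A, T, G, C).

    N becomes a uniform 0.25 column; any other character raises.
    """
    seq = seq.upper()
    mat = np.zeros((4, len(seq)), dtype=np.float32)
    for i, ch in enumerate(seq):
        if ch == "N":
            mat[:, i] = 0.25
        else:
            try:
                mat[_ROW[ch], i] = 1.0
            except KeyError:
                raise ValueError(f"invalid base {ch!r} at position {i}") from None
    return mat


@dataclass
class WindowSet:
    """A batch of encoded windows with labels and genomic origins.

    ``X`` has shape (n, 4, L); ``y`` holds 1 (positive), 0 (negative) or -1
    (unlabeled); ``origins`` are (contig, center, strand) triples.
    """

    X: np.ndarray
    y: np.ndarray
    origins: list[tuple[str, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class CnnConfig:
    filters1: int = 64
    kernel1: int = 10
    filters2: int = 128
    kernel2: int = 8
    pool: int = 4
    hidden: int = 64
    dropout: float = 0.5
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    val_fraction: float = 0.2


#: hyperparameter random-search space (filters/kernels shared by both conv layers)
SEARCH_SPACE = {
    "filters": [32, 64, 128],
    "kernel": [6, 8, 10, 12],
    "dropout": [0.2, 0.5],
    "lr": [1e-2, 1e-3, 1e-4],
}


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class PolyACnn:
    """The trained sequence classifier.

    Forward pass follows the conv -> ReLU -> max-pool -> conv -> ReLU ->
    max-pool -> dense -> ReLU -> dropout -> dense -> sigmoid stack; scores
    are probabilities in [0, 1].
    """

    def __init__(self, window_length: int, config: CnnConfig, seed: int = 0):
        self.L = int(window_length)
        self.config = config
        self.seed = int(seed)
        self.history: list[dict] = []
        rng = np.random.default_rng(seed)
        c = config
        p1 = self.L - c.kernel1 + 1
        q1 = p1 // c.pool
        p2 = q1 - c.kernel2 + 1
        q2 = p2 // c.pool
        if q2 < 1:
            raise ValueError("window too short for architecture")
        self._dims = (p1, q1, p2, q2)
        flat = q2 * c.filters2

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float64)

        self.params = {
            "W1": he((4 * c.kernel1, c.filters1), 4 * c.kernel1),
            "b1": np.zeros(c.filters1),
            "W2": he((c.filters1 * c.kernel2, c.filters2), c.filters1 * c.kernel2),
            "b2": np.zeros(c.filters2),
            "W3": he((flat, c.hidden), flat),
            "b3": np.zeros(c.hidden),
            "W4": he((c.hidden, 1), c.hidden),
            "b4": np.zeros(1),
        }

    # ---- forward / backward -------------------------------------------------

    def _conv_patches(self, x: np.ndarray, kernel: int) -> np.ndarray:
        # x: (B, C, P) -> (B, P-k+1, C*k)
        win = sliding_window_view(x, kernel, axis=2)  # (B, C, P-k+1, k)
        win = np.transpose(win, (0, 2, 1, 3))
        return win.reshape(win.shape[0], win.shape[1], -1)

    def _forward(self, X: np.ndarray, train: bool = False, rng=None):
        c, p = self.config, self.params
        B = X.shape[0]
        cache = {}
        pat1 = self._conv_patches(X, c.kernel1)  # (B, p1, 4k1)
        z1 = pat1 @ p["W1"] + p["b1"]
        a1 = _relu(z1)  # (B, p1, F1)
        q1 = self._dims[1]
        a1t = a1[:, : q1 * c.pool].reshape(B, q1, c.pool, c.filters1)
        m1 = a1t.max(axis=2)  # (B, q1, F1)
        pat2 = self._conv_patches(np.transpose(m1, (0, 2, 1)), c.kernel2)
        z2 = pat2 @ p["W2"] + p["b2"]
        a2 = _relu(z2)
        q2 = self._dims[3]
        a2t = a2[:, : q2 * c.pool].reshape(B, q2, c.pool, c.filters2)
        m2 = a2t.max(axis=2)
        flat = m2.reshape(B, -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = _relu(z3)
        if train and c.dropout > 0:
            mask = (rng.random(a3.shape) >= c.dropout) / (1.0 - c.dropout)
            a3d = a3 * mask
            cache["mask"] = mask
        else:
            a3d = a3
        z4 = a3d @ p["W4"] + p["b4"]
        out = _sigmoid(z4[:, 0])
        cache.update(
            X=X, pat1=pat1, z1=z1, a1t=a1t, m1=m1, pat2=pat2, z2=z2, a2t=a2t,
            flat=flat, z3=z3, a3d=a3d, out=out,
        )
        return out, cache

    def _backward(self, cache, y: np.ndarray):
        c, p = self.config, self.params
        B = y.shape[0]
        grads = {}
        dz4 = (cache["out"] - y)[:, None] / B  # BCE + sigmoid
        grads["W4"] = cache["a3d"].T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["W4"].T
        if "mask" in cache:
            da3 = da3 * cache["mask"]
        dz3 = da3 * (cache["z3"] > 0)
        grads["W3"] = cache["flat"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T
        q2 = self._dims[3]
        dm2 = dflat.reshape(B, q2, c.filters2)
        # route through max-pool 2
        a2t = cache["a2t"]
        amax2 = a2t.argmax(axis=2)
        da2t = np.zeros_like(a2t)
        np.put_along_axis(da2t, amax2[:, :, None, :], dm2[:, :, None, :], axis=2)
        da2 = np.zeros(cache["z2"].shape)
        da2[:, : q2 * c.pool] = da2t.reshape(B, q2 * c.pool, c.filters2)
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"] = np.einsum("bpk,bpf->kf", cache["pat2"], dz2)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dpat2 = dz2 @ p["W2"].T  # (B, p2, F1*k2)
        # scatter conv2 patches back onto m1
        q1 = self._dims[1]
        dm1 = np.zeros(cache["m1"].shape)  # (B, q1, F1)
        dpat2 = dpat2.reshape(B, -1, c.filters1, c.kernel2)
        for off in range(c.kernel2):
            dm1[:, off : off + dpat2.shape[1]] += dpat2[:, :, :, off]
        a1t = cache["a1t"]
        amax1 = a1t.argmax(axis=2)
        da1t = np.zeros_like(a1t)
        np.put_along_axis(da1t, amax1[:, :, None, :], dm1[:, :, None, :], axis=2)
        da1 = np.zeros(cache["z1"].shape)
        da1[:, : q1 * c.pool] = da1t.reshape(B, q1 * c.pool, c.filters1)
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"] = np.einsum("bpk,bpf->kf", cache["pat1"], dz1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    # ---- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int | None = None) -> "PolyACnn":
        """Train with Adam + early stopping on validation AUROC."""
        c = self.config
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are single-class")
        n = X.shape[0]
        # stratified train/validation split
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        rng.shuffle(idx_pos)
        rng.shuffle(idx_neg)
        n_vp = max(1, int(round(len(idx_pos) * c.val_fraction)))
        n_vn = max(1, int(round(len(idx_neg) * c.val_fraction)))
        val_idx = np.concatenate([idx_pos[:n_vp], idx_neg[:n_vn]])
        tr_idx = np.concatenate([idx_pos[n_vp:], idx_neg[n_vn:]])
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        t = 0
        best_auc, best_params, patience_left = -np.inf, None, c.patience
        for epoch in range(c.max_epochs):
            order = rng.permutation(len(tr_idx))
            losses = []
            for start in range(0, len(order), c.batch_size):
                batch = order[start : start + c.batch_size]
                out, cache = self._forward(Xtr[batch], train=True, rng=rng)
                eps = 1e-12
                losses.append(
                    -np.mean(
                        ytr[batch] * np.log(out + eps)
                        + (1 - ytr[batch]) * np.log(1 - out + eps)
                    )
                )
                grads = self._backward(cache, ytr[batch])
                if not np.isfinite(losses[-1]):
                    raise FloatingPointError("non-finite training loss")
                t += 1
                for k in self.params:
                    m[k] = 0.9 * m[k] + 0.1 * grads[k]
                    v[k] = 0.999 * v[k] + 0.001 * grads[k] ** 2
                    mhat = m[k] / (1 - 0.9**t)
                    vhat = v[k] / (1 - 0.999**t)
                    self.params[k] -= c.lr * mhat / (np.sqrt(vhat) + 1e-8)
            val_auc = auroc(self.score(Xval), yval)
            self.history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "val_auroc": float(val_auc)}
            )
            if val_auc > best_auc + 1e-6:
                best_auc = val_auc
                best_params = {k: p.copy() for k, p in self.params.items()}
                patience_left = c.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_params is not None:
            self.params = best_params
        self.val_auroc_ = float(best_auc)
        return self

    def score(self, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Vectorized, order-preserving forward pass; scores in [0, 1]."""
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != 4 or X.shape[2] != self.L:
            raise ValueError(f"expected windows of shape (n, 4, {self.L})")
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], chunk):
            out[start : start + chunk] = self._forward(
                np.asarray(X[start : start + chunk], dtype=np.float64)
            )[0]
        return out

    def save(self, path: str) -> None:
        meta = {"window_length": self.L, "seed": self.seed, "config": asdict(self.config),
                "history": self.history}
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path: str) -> "PolyACnn":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as data:
            meta = json.loads(str(data["__meta__"]))
            model = cls(meta["window_length"], CnnConfig(**meta["config"]), meta["seed"])
            model.history = meta.get("history", [])
            for k in model.params:
                model.params[k] = data[k]
        return model


def build_sequence_training_set(
    genes: list[GeneModel],
    genome: GenomeBundle,
    flank: int = 100,
    n_negatives: int | None = None,
    seed: int = 0,
) -> WindowSet:
    """Labeled windows: annotated transcript-end polyA sites vs intergenic.

    Positives are deduplicated by (contig, position, strand); negatives are
    sampled uniformly from intergenic space such that no negative window
    overlaps any gene span. Deterministic under ``seed``.
    """
    L = 2 * flank + 1
    rng = np.random.default_rng(seed)
    pos_origins: list[tuple[str, int, str]] = []
    seen = set()
    for gene in genes:
        for site in gene.polya_sites():
            key = (gene.contig, site, gene.strand)
            if key in seen:
                continue
            seen.add(key)
            if site - flank < 0 or site + flank + 1 > genome.contig_lengths[gene.contig]:
                logger.warning("polyA site %s:%d window out of bounds; skipped", *key[:2])
                continue
            pos_origins.append(key)
    if not pos_origins:
        raise ValueError("no annotated polyA sites found")

    span_by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contig_names}
    for gene in genes:
        span_by_contig.setdefault(gene.contig, []).append(gene.span)
    allowed: list[tuple[str, int, int]] = []
    for contig, clen in genome.contig_lengths.items():
        blocked = merge_intervals(
            [(max(0, s - flank), min(clen, e + flank)) for s, e in span_by_contig.get(contig, [])]
        )
        for s, e in subtract_intervals([(flank, clen - flank)], blocked):
            if e > s:
                allowed.append((contig, s, e))
    n_neg = len(pos_origins) if n_negatives is None else int(n_negatives)
    total = sum(e - s for _, s, e in allowed)
    if total < n_neg:
        raise ValueError(f"intergenic space ({total} bases) smaller than {n_neg} negatives")
    offsets = rng.choice(total, size=n_neg, replace=False)
    offsets.sort()
    neg_origins: list[tuple[str, int, str]] = []
    bounds = np.cumsum([e - s for _, s, e in allowed])
    for off in offsets:
        i = int(np.searchsorted(bounds, off, side="right"))
        contig, s, _ = allowed[i]
        base = off - (bounds[i - 1] if i else 0)
        neg_origins.append((contig, int(s + base), "+" if rng.random() < 0.5 else "-"))

    origins = pos_origins + neg_origins
    X = np.stack(
        [one_hot_encode(fetch_window(genome, c, p, flank, s)) for c, p, s in origins]
    )
    y = np.concatenate([np.ones(len(pos_origins)), np.zeros(len(neg_origins))])
    assert X.shape[1:] == (4, L)
    return WindowSet(X, y, origins)


def train_polya_cnn(
    windows: WindowSet | np.ndarray,
    labels: np.ndarray | None = None,
    config: CnnConfig | None = None,
    seed: int = 0,
) -> PolyACnn:
    """Fit the CNN on labeled windows with the given (or default) config."""
    if isinstance(windows, WindowSet):
        X, y = windows.X, windows.y if labels is None else labels
    else:
        X, y = windows, labels
    config = config or CnnConfig()
    model = PolyACnn(X.shape[2], config, seed=seed)
    return model.fit(np.asarray(X, dtype=np.float64), y, seed=seed)


def search_hyperparameters(
    windows: WindowSet,
    seed: int = 0,
    n_draws: int = 10,
    base: CnnConfig | None = None,
) -> tuple[PolyACnn, CnnConfig]:
    """Random hyperparameter search; returns the best model by validation AUROC."""
    rng = np.random.default_rng(seed)
    best: tuple[float, PolyACnn, CnnConfig] | None = None
    for draw in range(n_draws):
        cfg = CnnConfig(**asdict(base or CnnConfig()))
        cfg.filters1 = int(rng.choice(SEARCH_SPACE["filters"]))
        cfg.filters2 = int(rng.choice(SEARCH_SPACE["filters"]))
        cfg.kernel1 = int(rng.choice(SEARCH_SPACE["kernel"]))
        cfg.kernel2 = int(rng.choice(SEARCH_SPACE["kernel"]))
        cfg.dropout = float(rng.choice(SEARCH_SPACE["dropout"]))
        cfg.lr = float(rng.choice(SEARCH_SPACE["lr"]))
        model = train_polya_cnn(windows, config=cfg, seed=seed + draw)
        if best is None or model.val_auroc_ > best[0]:
            best = (model.val_auroc_, model, cfg)
    assert best is not None
    return best[1], best[2]


def score_windows(model: PolyACnn, windows: WindowSet | np.ndarray) -> np.ndarray:
    X = windows.X if isinstance(windows, WindowSet) else windows
    return model.score(np.asarray(X, dtype=np.float64))


@dataclass(frozen=True)
class CandidateSite:
    """A putative intronic polyA site proposed by the scanner."""

    contig: str
    pos: int
    strand: str
    score: float
    region: IntronicRegion


def scan_intronic_regions(
    model: PolyACnn,
    genome: GenomeBundle,
    introns: list[IntronicRegion],
    threshold: float = 0.5,
    stride: int = 1,
    merge_radius: int = 50,
    max_n_fraction: float = 0.1,
) -> list[CandidateSite]:
    """Score every intronic position and reduce to merged local maxima.

    Positions scoring >= ``threshold`` are reduced by non-maximum
    suppression with radius ``merge_radius`` (highest score wins; ties break
    toward the lower coordinate); each kept peak is then localized to the
    score-weighted centroid of its above-threshold neighborhood
    (half the merge radius), which centers the call on the scanner's
    response plateau rather than its noisy arg-max. Windows leaving the
    contig or containing more than ``max_n_fraction`` N are skipped.
    """
    if not introns:
        raise ValueError("empty intron set")
    flank = model.L // 2
    raw: list[tuple[str, str, int, float, IntronicRegion]] = []
    region_scores: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # id(region) -> (pos, score)
    for region in introns:
        clen = genome.contig_lengths[region.contig]
        lo = max(region.start, flank)
        hi = min(region.end, clen - flank)
        if lo != region.start or hi != region.end:
            logger.warning(
                "region %s:%d-%d clipped to keep scan windows on the contig",
                region.contig, region.start, region.end,
            )
        if hi <= lo:
            continue
        ext = genome.fetch(region.contig, lo - flank, hi + flank)
        if region.strand == "-":
            ext = reverse_complement(ext)
        enc = one_hot_encode(ext)
        wins = sliding_window_view(enc, model.L, axis=1)  # (4, n, L)
        wins = np.transpose(wins, (1, 0, 2))[::stride]
        n_frac = np.array(
            [ext[i : i + model.L].count("N") / model.L for i in range(0, wins.shape[0] * stride, stride)]
        )
        keep = n_frac <= max_n_fraction
        if not keep.all():
            logger.warning("skipping %d N-heavy windows in %s", int((~keep).sum()), region.gene_id)
        scores = np.full(wins.shape[0], -1.0)
        if keep.any():
            scores[keep] = model.score(wins[keep])
        offs = np.arange(wins.shape[0]) * stride
        positions = (lo + offs) if region.strand == "+" else (hi - 1 - offs)
        region_scores[id(region)] = (positions, scores)
        for pos, sc in zip(positions, scores):
            if sc >= threshold:
                raw.append((region.contig, region.strand, int(pos), float(sc), region))
    # non-maximum suppression per contig+strand
    sites: list[CandidateSite] = []
    bykey: dict[tuple[str, str], list] = {}
    for item in raw:
        bykey.setdefault((item[0], item[1]), []).append(item)
    for (contig, strand), items in sorted(bykey.items()):
        items.sort(key=lambda x: (-x[3], x[2]))
        kept: list[tuple[int, float, IntronicRegion]] = []
        for _, _, pos, sc, region in items:
            if all(abs(pos - kp) > merge_radius for kp, _, _ in kept):
                kept.append((pos, sc, region))
        refined = []
        for pos, sc, region in kept:
            rpos, rsc = region_scores[id(region)]
            near = (np.abs(rpos - pos) <= merge_radius // 2) & (rsc >= threshold)
            if near.any():
                pos = int(round(float(np.sum(rpos[near] * rsc[near]) / np.sum(rsc[near]))))
            refined.append((pos, sc, region))
        # refinement can draw neighboring peaks together; suppress again
        refined.sort(key=lambda x: (-x[1], x[0]))
        final: list[tuple[int, float, IntronicRegion]] = []
        for pos, sc, region in refined:
            if all(abs(pos - kp) > merge_radius for kp, _, _ in final):
                final.append((pos, sc, region))
        for pos, sc, region in sorted(final):
            sites.append(CandidateSite(contig, pos, strand, sc, region))
    sites.sort(key=lambda s: (s.contig, s.pos))
    return sites


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney rank formulation, midranks)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores)))


def write_candidate_bed(sites: list[CandidateSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.region.gene_id}|{s.score:.4f}\t"
                f"{s.score:.4f}\t{s.strand}\n"
            )
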