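"""From converged discriminative modes to a bag-of-words dictionary.

The pipeline mirrors the mean-shift clustering recipe: seed kernels
with a uniform subsample of the training fixations (1/20 by default),
shift every kernel to an extremum of the class-density-difference
surface, then run k-means on the shifted kernels to obtain K word
centroids. Fixations are assigned to the nearest centroid, and each
subject-image fixation sequence becomes an L1-normalized K-bin
histogram (its bag-of-words feature).

The module also computes per-word diagnostics: purity (normalized class
imbalance of a word's members), coverage (member count), and their
product, the word quality |n_pos - n_neg|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .density import FixationDataset, KernelConfig, _sqdist, quality_signed
from .modeseek import SeekConfig, seek_all

__all__ = [
    "Dictionary",
    "ClusterPartition",
    "BowFeature",
    "WordQuality",
    "learn_dictionary",
    "assign",
    "encode_bow",
    "encode_dataset",
    "word_quality_table",
    "purity_profile",
    "quality_heatmap",
]


@dataclass
class Dictionary:
    """K word centroids in pixel coordinates plus provenance."""

    centroids: np.ndarray  # (K, 2)
    method_tag: str
    h: float | None = None
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.K >= 2:
            d2 = _sqdist(self.centroids, self.centroids)
            np.fill_diagonal(d2, np.inf)
            if d2.min() <= 0.0:
                raise ValueError("centroids must be pairwise distinct")

    @property
    def K(self) -> int:
        return len(self.centroids)


@dataclass
class ClusterPartition:
    """Per-fixation word index in 0..K-1, induced by nearest centroid."""

    assignment: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.size and (
            self.assignment.min() < 0 or self.assignment.max() >= self.K
        ):
            raise ValueError("assignment index out of range")


@dataclass
class BowFeature:
    """L1-normalized word histogram for one subject-image sequence."""

    histogram: np.ndarray
    n_fixations: int
    subject_id: str
    image_id: str
    label: int | None = None

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=float)
        if self.n_fixations < 1:
            raise ValueError("a bag-of-words feature needs at least one fixation")
        if not math.isclose(float(self.histogram.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("histogram must sum to 1")


@dataclass
class WordQuality:
    """Purity/coverage/quality diagnostics for one dictionary word."""

    word: int
    n_pos: int
    n_neg: int
    coverage: int
    purity_pos: float
    purity_neg: float
    purity_abs: float
    quality: float
    defined: bool  # False for words that cover no fixation


def _kmeans_centroids(points: np.ndarray, K: int, seed: int) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    n_distinct = len(np.unique(points, axis=0))
    if K > n_distinct:
        raise ValueError(
            f"K={K} exceeds the {n_distinct} distinct positions available; choose a smaller K"
        )
    km = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31), algorithm="lloyd")
    km.fit(points)
    return km.cluster_centers_


def _order_by_quality(centroids: np.ndarray, train: FixationDataset) -> np.ndarray:
    """Deterministic column order: quality descending, ties by x then y."""
    part = _nearest(train.points, centroids)
    qual = np.zeros(len(centroids))
    for k in range(len(centroids)):
        m = part == k
        qual[k] = abs(int(np.sum(train.labels[m] == 1)) - int(np.sum(train.labels[m] == -1)))
    order = sorted(range(len(centroids)), key=lambda k: (-qual[k], centroids[k, 0], centroids[k, 1]))
    return centroids[order]


def _nearest(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # argmin returns the lowest index on exact ties, matching the tie rule
    out = np.empty(len(points), dtype=int)
    chunk = 4096
    for lo in range(0, len(points), chunk):
        out[lo : lo + chunk] = np.argmin(_sqdist(points[lo : lo + chunk], centroids), axis=1)
    return out


def learn_dictionary(
    train: FixationDataset,
    cfg: KernelConfig,
    seek: SeekConfig | None = None,
    K: int = 40,
    subsample_rate: float = 0.05,
    seed: int = 0,
    mode: str = "dual",
    method_tag: str = "proposed",
) -> Dictionary:
    """Learn a K-word discriminative dictionary from training fixations.

    1. Draw a seeded uniform subsample (without replacement) of the
       training coordinates as initial kernels.
    2. Shift every kernel to a class-density-difference extremum by
       dual mode seeking.
    3. Cluster the shifted kernels with k-means (10 restarts) into K
       centroids, returned in quality-descending order.

    ``mode`` is exposed so baseline learners can reuse the identical
    pipeline with classic or ratio seeking.
    """
    seek = seek or SeekConfig()
    if not (0.0 < subsample_rate <= 1.0):
        raise ValueError("subsample_rate must lie in (0, 1]")
    n_init = math.ceil(train.n * subsample_rate)
    if n_init < K:
        raise ValueError(
            f"subsample of {n_init} kernels cannot support K={K} words; "
            "increase subsample_rate or reduce K"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(train.n, size=n_init, replace=False)
    inits = train.points[idx]
    trajectories = seek_all(inits, train, cfg, seek, mode=mode)
    finals = np.array([t.final for t in trajectories if not t.failed])
    centroids = _kmeans_centroids(finals, K, seed)
    centroids = _order_by_quality(centroids, train)
    return Dictionary(
        centroids=centroids,
        method_tag=method_tag,
        h=cfg.h,
        seed=seed,
        provenance={
            "mode": mode,
            "subsample_rate": subsample_rate,
            "n_init_kernels": int(n_init),
            "n_failed_kernels": int(sum(t.failed for t in trajectories)),
            "seed": int(seed),
        },
    )


def assign(points, dictionary: Dictionary) -> ClusterPartition:
    """Assign each fixation to its nearest word (ties -> lowest index)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    return ClusterPartition(_nearest(points, dictionary.centroids), dictionary.K)


def encode_bow(
    points,
    dictionary: Dictionary,
    subject_id: str = "",
    image_id: str = "",
    label: int | None = None,
) -> BowFeature:
    """Encode one subject-image fixation sequence as a normalized histogram."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise ValueError(f"no fixations for subject-image ({subject_id!r}, {image_id!r})")
    part = assign(points, dictionary)
    counts = np.bincount(part.assignment, minlength=dictionary.K)
    return BowFeature(
        histogram=counts / len(points),
        n_fixations=len(points),
        subject_id=str(subject_id),
        image_id=str(image_id),
        label=label,
    )


def encode_dataset(data: FixationDataset, dictionary: Dictionary) -> list[BowFeature]:
    """Encode every subject-image sequence in the dataset, in sorted key order."""
    keys = sorted(set(zip(map(str, data.subject_ids), map(str, data.image_ids))))
    sid = data.subject_ids.astype(str)
    iid = data.image_ids.astype(str)
    feats = []
    for s, im in keys:
        m = (sid == s) & (iid == im)
        feats.append(
            encode_bow(data.points[m], dictionary, subject_id=s, image_id=im,
                       label=int(data.labels[m][0]))
        )
    return feats


def word_quality_table(train: FixationDataset, dictionary: Dictionary) -> list[WordQuality]:
    """Per-word class counts, purities, coverage and quality on ``train``."""
    part = assign(train.points, dictionary)
    rows = []
    for k in range(dictionary.K):
        m = part.assignment == k
        n_pos = int(np.sum(train.labels[m] == 1))
        n_neg = int(np.sum(train.labels[m] == -1))
        cov = n_pos + n_neg
        if cov > 0:
            pp = n_pos / cov
            pn = n_neg / cov
            pa = abs(n_pos - n_neg) / cov
            defined = True
        else:
            pp = pn = pa = float("nan")
            defined = False
        rows.append(
            WordQuality(
                word=k,
                n_pos=n_pos,
                n_neg=n_neg,
                coverage=cov,
                purity_pos=pp,
                purity_neg=pn,
                purity_abs=pa,
                quality=float(abs(n_pos - n_neg)),
                defined=defined,
            )
        )
    return rows


def purity_profile(qualities: list[WordQuality], cls: str = "pos") -> np.ndarray:
    """Class purities sorted high to low (words covering nothing count 0)."""
    if not qualities:
        raise ValueError("empty word-quality table")
    if cls == "pos":
        vals = [w.purity_pos if w.defined else 0.0 for w in qualities]
    elif cls == "neg":
        vals = [w.purity_neg if w.defined else 0.0 for w in qualities]
    elif cls == "abs":
        vals = [w.purity_abs if w.defined else 0.0 for w in qualities]
    else:
        raise ValueError("cls must be 'pos', 'neg' or 'abs'")
    return np.sort(np.asarray(vals))[::-1]


def quality_heatmap(
    data: FixationDataset,
    cfg: KernelConfig,
    extent: tuple[float, float] = (700.0, 500.0),
    step: float = 2.0,
):
    """Evaluate the signed and absolute quality surfaces on a pixel grid.

    Returns ``(q_signed, q_abs, xs, ys)`` with array shape (len(ys),
    len(xs)) — row index is y (screen convention, origin top-left).
    """
    xs = np.arange(0.0, extent[0] + step / 2, step)
    ys = np.arange(0.0, extent[1] + step / 2, step)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    qs = np.empty(len(grid))
    chunk = 8192
    for lo in range(0, len(grid), chunk):
        sub, _ = quality_signed(grid[lo : lo + chunk], data, cfg)
        qs[lo : lo + chunk] = sub
    qs = qs.reshape(gy.shape)
    return qs, np.abs(qs), xs, ys
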