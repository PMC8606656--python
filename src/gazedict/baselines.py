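"""Baseline dictionary learners for comparison with dual mode seeking.

Five learners share the assignment/encoding/evaluation machinery:

* ``kmeans`` — k-means on all fixations pooled (class-blind);
* ``class_kmeans`` — k-means per class with the K words split
  ceil(K/2) / floor(K/2), centroids pooled;
* ``meanshift`` — classic mean shift on pooled fixations, then k-means
  on the shifted kernels;
* ``class_meanshift`` — classic mean shift per class, k-means per
  class, centroids pooled;
* ``ratio`` — mode seeking on the guarded density ratio
  p(x|X+)/(p(x|X-)+eps), then k-means (the density-ratio formulation
  of discriminative mode seeking).

Every learner is deterministic given (inputs, seed) and emits a
:class:`~gazedict.dictionary.Dictionary` with a distinguishing
``method_tag``.
"""

from __future__ import annotations

import math

import numpy as np

def _class_seed(seed: int, class_index: int) -> int:
    """Distinct deterministic sub-seed per class for class-wise learners."""
    ss = np.random.SeedSequence([int(seed), int(class_index)])
    return int(ss.generate_state(1)[0] % (2**31))

from .density import FixationDataset, KernelConfig
from .dictionary import Dictionary, _kmeans_centroids, _order_by_quality, learn_dictionary
from .modeseek import SeekConfig, seek_all

__all__ = [
    "kmeans_dictionary",
    "class_kmeans_dictionary",
    "meanshift_dictionary",
    "class_meanshift_dictionary",
    "ratio_modeseek_dictionary",
    "LEARNERS",
    "make_learner",
]


def _split_K(K: int) -> tuple[int, int]:
    """Split K words across the two classes as evenly as possible."""
    return math.ceil(K / 2), math.floor(K / 2)


def kmeans_dictionary(train: FixationDataset, K: int, seed: int = 0) -> Dictionary:
    """Plain k-means on all fixation coordinates, both classes pooled."""
    centroids = _kmeans_centroids(train.points, K, seed)
    centroids = _order_by_quality(centroids, train)
    return Dictionary(centroids, method_tag="kmeans", seed=seed,
                      provenance={"seed": int(seed)})


def class_kmeans_dictionary(train: FixationDataset, K: int, seed: int = 0) -> Dictionary:
    """K-means run separately on each class, centroids pooled."""
    if K < 2:
        raise ValueError("class-wise k-means needs K >= 2")
    k_pos, k_neg = _split_K(K)
    for pts, share, name in ((train.points_pos, k_pos, "positive"),
                             (train.points_neg, k_neg, "negative")):
        if len(pts) < share:
            raise ValueError(f"{name} class has too few points for its {share} clusters")
    c_pos = _kmeans_centroids(train.points_pos, k_pos, _class_seed(seed, 0))
    c_neg = _kmeans_centroids(train.points_neg, k_neg, _class_seed(seed, 1))
    centroids = _order_by_quality(np.vstack([c_pos, c_neg]), train)
    return Dictionary(centroids, method_tag="class_kmeans", seed=seed,
                      provenance={"seed": int(seed), "split": (k_pos, k_neg)})


def meanshift_dictionary(
    train: FixationDataset,
    cfg: KernelConfig,
    seek: SeekConfig | None = None,
    K: int = 40,
    subsample_rate: float = 0.05,
    seed: int = 0,
) -> Dictionary:
    """Classic mean shift on pooled fixations, followed by k-means."""
    return learn_dictionary(
        train, cfg, seek, K=K, subsample_rate=subsample_rate, seed=seed,
        mode="classic", method_tag="meanshift",
    )


def class_meanshift_dictionary(
    train: FixationDataset,
    cfg: KernelConfig,
    seek: SeekConfig | None = None,
    K: int = 40,
    subsample_rate: float = 0.05,
    seed: int = 0,
) -> Dictionary:
    """Classic mean shift per class, k-means per class, centroids pooled."""
    seek = seek or SeekConfig()
    if K < 2:
        raise ValueError("class-wise mean shift needs K >= 2")
    k_pos, k_neg = _split_K(K)
    cents = []
    for ci, (pts, share, name) in enumerate(
        ((train.points_pos, k_pos, "positive"), (train.points_neg, k_neg, "negative"))
    ):
        n_init = math.ceil(len(pts) * subsample_rate)
        if n_init < share:
            raise ValueError(
                f"{name} class subsample ({n_init}) cannot support {share} clusters"
            )
        cseed = _class_seed(seed, ci)
        rng = np.random.default_rng(cseed)
        idx = rng.choice(len(pts), size=n_init, replace=False)
        trajs = seek_all(pts[idx], pts, cfg, seek, mode="classic")
        finals = np.array([t.final for t in trajs if not t.failed])
        cents.append(_kmeans_centroids(finals, share, cseed))
    centroids = _order_by_quality(np.vstack(cents), train)
    return Dictionary(centroids, method_tag="class_meanshift", h=cfg.h, seed=seed,
                      provenance={"seed": int(seed), "split": (k_pos, k_neg),
                                  "subsample_rate": subsample_rate})


def ratio_modeseek_dictionary(
    train: FixationDataset,
    cfg: KernelConfig,
    seek: SeekConfig | None = None,
    K: int = 40,
    subsample_rate: float = 0.05,
    seed: int = 0,
) -> Dictionary:
    """Discriminative mode seeking on the guarded density ratio, then k-means."""
    return learn_dictionary(
        train, cfg, seek, K=K, subsample_rate=subsample_rate, seed=seed,
        mode="ratio", method_tag="ratio",
    )


def make_learner(method: str):
    """Return ``learner(train, cfg, seek, K, subsample_rate, seed) -> Dictionary``.

    All six learners (the proposed one plus five baselines) are exposed
    behind a uniform signature; learners that do not use the kernel or
    seeking configuration simply ignore those arguments.
    """
    if method == "proposed":
        return lambda train, cfg, seek, K, rate, seed: learn_dictionary(
            train, cfg, seek, K=K, subsample_rate=rate, seed=seed)
    if method == "kmeans":
        return lambda train, cfg, seek, K, rate, seed: kmeans_dictionary(train, K, seed)
    if method == "class_kmeans":
        return lambda train, cfg, seek, K, rate, seed: class_kmeans_dictionary(train, K, seed)
    if method == "meanshift":
        return lambda train, cfg, seek, K, rate, seed: meanshift_dictionary(
            train, cfg, seek, K=K, subsample_rate=rate, seed=seed)
    if method == "class_meanshift":
        return lambda train, cfg, seek, K, rate, seed: class_meanshift_dictionary(
            train, cfg, seek, K=K, subsample_rate=rate, seed=seed)
    if method == "ratio":
        return lambda train, cfg, seek, K, rate, seed: ratio_modeseek_dictionary(
            train, cfg, seek, K=K, subsample_rate=rate, seed=seed)
    raise ValueError(f"unknown dictionary method {method!r}")


LEARNERS = ("proposed", "kmeans", "class_kmeans", "meanshift", "class_meanshift", "ratio")
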