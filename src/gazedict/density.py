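"""Kernel density machinery over 2D eye-fixation coordinates.

This module provides the numerical core of the package: Gaussian kernel
density estimation (KDE) over fixation clouds, the *signed class density
difference* — the continuous surrogate of dictionary-word quality — its
analytic gradient, and the label-weighted (supervised) mean-shift vector
whose fixed points are the extrema of the absolute density difference.

All quantities live in raw pixel coordinates on the stimulus canvas; the
bandwidth ``h`` is therefore expressed in pixels and is directly
interpretable against the 700x500 face stimuli the method was designed
for. Coordinates are never standardized.

Conventions
-----------
* The per-class KDE divides by the *total* training-set size ``N`` (not
  the class subset size), so that the signed difference
  ``q(x) = p(x | X+) - p(x | X-)`` is proportional to the signed kernel
  sum ``sum_i y_i k(x, x_i)`` with a single shared constant.
* The KDE of an empty point set is 0, which makes every supervised
  operation reduce exactly to its classic unsupervised counterpart when
  one class is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelConfig",
    "FixationDataset",
    "QualityValue",
    "IsolatedQueryError",
    "BalancedDensityError",
    "kde",
    "quality_signed",
    "weighted_mean",
    "grad_quality_signed",
    "supervised_shift_vector",
    "signed_kernel_stats",
]

# exp() underflows to 0 below roughly exp(-745); we flag a query as
# isolated when the total kernel mass cannot be represented (< 1e-300).
_LOG_WEIGHT_FLOOR = math.log(1e-300)


class IsolatedQueryError(ValueError):
    """Query point has no kernel support: total kernel weight underflows.

    Callers performing mode seeking should freeze such a kernel at its
    current position instead of propagating NaNs.
    """


class BalancedDensityError(ValueError):
    """Signed kernel-weight sum is below the numerical floor.

    Raised where positive and negative class densities cancel almost
    exactly; the supervised mean-shift vector is undefined there and the
    caller should fall back to a normalized gradient step.
    """


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian kernel configuration.

    Parameters
    ----------
    h : float
        Bandwidth in pixels; controls kernel smoothness.
    d : int
        Data dimension. Fixations are 2D screen coordinates, so ``d=2``.
    c_d : float, optional
        Kernel normalization constant. Defaults to the standard Gaussian
        constant ``(2*pi)**(-d/2)``. It cancels in the supervised
        mean-shift vector and only sets the absolute density scale.
    """

    h: float
    d: int = 2
    c_d: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.isfinite(self.h) or self.h <= 0:
            raise ValueError(f"bandwidth h must be positive and finite, got {self.h}")
        if self.d < 1:
            raise ValueError("dimension d must be >= 1")
        if self.c_d is None:
            object.__setattr__(self, "c_d", (2.0 * math.pi) ** (-self.d / 2.0))
        elif self.c_d <= 0:
            raise ValueError("normalization constant c_d must be positive")

    @property
    def norm(self) -> float:
        """Per-point density prefactor ``c_d / h**d`` (before dividing by N)."""
        return self.c_d / self.h**self.d


@dataclass
class FixationDataset:
    """Labeled 2D fixation records for a training cohort.

    ``points[i]`` is the i-th fixation (x, y) in pixels; ``labels[i]`` is
    the diagnosis label of the subject it came from (+1 positive class,
    -1 negative class); ``subject_ids``/``image_ids`` key the record to
    the subject and the viewed stimulus.
    """

    points: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.image_ids = np.asarray(self.image_ids)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (N, 2)")
        n = len(self.points)
        for name in ("labels", "subject_ids", "image_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match points ({n})")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("fixation coordinates must be finite")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        self.labels = self.labels.astype(int)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == -1))

    @property
    def points_pos(self) -> np.ndarray:
        return self.points[self.labels == 1]

    @property
    def points_neg(self) -> np.ndarray:
        return self.points[self.labels == -1]

    def subset(self, mask: np.ndarray) -> "FixationDataset":
        mask = np.asarray(mask)
        return FixationDataset(
            self.points[mask],
            self.labels[mask],
            self.subject_ids[mask],
            self.image_ids[mask],
        )

    def subject_label_map(self) -> dict:
        """Per-subject diagnosis label (labels are constant within subject)."""
        out: dict = {}
        for sid, lab in zip(self.subject_ids, self.labels):
            prev = out.setdefault(sid, int(lab))
            if prev != lab:
                raise ValueError(f"subject {sid!r} has inconsistent labels")
        return out


@dataclass(frozen=True)
class QualityValue:
    """Signed density difference and its absolute value at one location."""

    q_signed: float
    q_abs: float


def _as_queries(x) -> tuple[np.ndarray, bool]:
    """Coerce ``x`` to a (M, 2) query array; report whether it was scalar."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
        scalar = True
    else:
        scalar = False
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("query points must be 2D coordinates")
    if not np.all(np.isfinite(arr)):
        raise ValueError("query point must be finite")
    return arr, scalar


def _sqdist(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, (M, 2) x (N, 2) -> (M, N)."""
    d2 = q @ p.T
    d2 *= -2.0
    d2 += np.einsum("ij,ij->i", q, q)[:, None]
    d2 += np.einsum("ij,ij->i", p, p)[None, :]
    np.maximum(d2, 0.0, out=d2)
    return d2


def kde(x, points, cfg: KernelConfig, n_total: int | None = None):
    """Gaussian kernel density estimate at ``x`` from a point cloud.

    ``n_total`` is the divisor of the estimator. When estimating a
    *class-conditional* density inside the quality objective it must be
    the full training-set size N (both classes), so that the two class
    densities share one constant; it defaults to ``len(points)`` for
    plain single-set usage.

    Returns a scalar for a single query, an array for a batch of queries.
    """
    q, scalar = _as_queries(x)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        out = np.zeros(len(q))
        return float(out[0]) if scalar else out
    if n_total is None:
        n_total = len(points)
    d2 = _sqdist(q, points)
    vals = np.exp(-d2 / (2.0 * cfg.h**2)).sum(axis=1) * (cfg.norm / n_total)
    return float(vals[0]) if scalar else vals


def quality_signed(x, data: FixationDataset, cfg: KernelConfig):
    """Signed word-quality surface ``q(x) = p(x|X+) - p(x|X-)``.

    Both class densities divide by the full N so the difference is the
    normalized signed kernel sum. Returns a :class:`QualityValue` for a
    single query, a pair of arrays ``(q_signed, q_abs)`` for a batch.
    """
    q, scalar = _as_queries(x)
    p_pos = kde(q, data.points_pos, cfg, n_total=data.n)
    p_neg = kde(q, data.points_neg, cfg, n_total=data.n)
    qs = np.asarray(p_pos) - np.asarray(p_neg)
    if scalar:
        v = float(qs[0])
        return QualityValue(q_signed=v, q_abs=abs(v))
    return qs, np.abs(qs)


def _shifted_weights(d2: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Row-stabilized kernel weights.

    Returns ``(w, log_shift)`` where the true kernel weight of entry
    (m, i) is ``w[m, i] * exp(log_shift[m])`` and ``max_i w[m, i] = 1``.
    """
    m = d2.min(axis=1)
    w = d2  # reuse the buffer; callers treat d2 as consumed
    w -= m[:, None]
    w /= -2.0 * h * h
    np.exp(w, out=w)
    return w, -m / (2.0 * h * h)


def weighted_mean(x, points, cfg: KernelConfig):
    """Kernel-weighted mean of ``points`` around query ``x``.

    This is the fixed-point map of classic mean shift. Raises
    :class:`IsolatedQueryError` when the total kernel weight underflows
    (query far outside the cloud's kernel support).
    """
    q, scalar = _as_queries(x)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) == 0:
        raise IsolatedQueryError("weighted mean of an empty point set")
    d2 = _sqdist(q, points)
    w, log_shift = _shifted_weights(d2, cfg.h)
    tot = w.sum(axis=1)
    log_total = log_shift + np.log(tot)
    if np.any(log_total < _LOG_WEIGHT_FLOOR):
        raise IsolatedQueryError(
            "total kernel weight underflows; query is isolated from the point set"
        )
    means = (w @ points) / tot[:, None]
    return means[0] if scalar else means


def grad_quality_signed(x, data: FixationDataset, cfg: KernelConfig) -> np.ndarray:
    """Analytic gradient of the signed quality surface.

    grad q(x) = (1/h^2) [ p(x|X+) (xm+ - x) - p(x|X-) (xm- - x) ]

    where xm+/- are the kernel-weighted class means. A class whose
    density underflows at ``x`` (or is empty) contributes zero.
    """
    q, scalar = _as_queries(x)
    out = np.zeros_like(q)
    for sign, pts in ((1.0, data.points_pos), (-1.0, data.points_neg)):
        if len(pts) == 0:
            continue
        dens = np.atleast_1d(kde(q, pts, cfg, n_total=data.n))
        try:
            xm = np.atleast_2d(weighted_mean(q, pts, cfg))
        except IsolatedQueryError:
            continue  # density underflows too: zero contribution
        out += sign * dens[:, None] * (xm - q) / cfg.h**2
    return out[0] if scalar else out


def signed_kernel_stats(x, data_points: np.ndarray, labels: np.ndarray, cfg: KernelConfig):
    """Batch label-weighted kernel sums used by supervised mean shift.

    For each query row ``x_m`` computes, with ``k_i = exp(-||x - x_i||^2 / 2h^2)``:

    * ``s``        — the signed sum ``sum_i y_i k_i`` (true scale);
    * ``mean``     — ``sum_i y_i k_i x_i / sum_i y_i k_i`` (NaN where balanced);
    * ``s_rel``    — the signed sum relative to the max single kernel
      weight (scale-free balance diagnostic, in [-N, N]);
    * ``isolated`` — mask of queries whose total kernel mass underflows.

    Returns a dict of arrays keyed by the names above.
    """
    q, _ = _as_queries(x)
    pts = np.asarray(data_points, dtype=float).reshape(-1, 2)
    y = np.asarray(labels, dtype=float)
    d2 = _sqdist(q, pts)
    w, log_shift = _shifted_weights(d2, cfg.h)
    abs_tot = w.sum(axis=1)
    # one fused matmul: columns are (y, y*x, y*y) -> (signed sum, signed moments)
    basis = np.column_stack([y, y[:, None] * pts])
    sums = w @ basis
    s_rel = sums[:, 0]  # relative to max kernel weight (=1 after shift)
    num = sums[:, 1:]
    isolated = (log_shift + np.log(abs_tot)) < _LOG_WEIGHT_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = num / s_rel[:, None]
    s = s_rel * np.exp(log_shift)
    return {"s": s, "s_rel": s_rel, "mean": mean, "isolated": isolated}


def supervised_shift_vector(
    x,
    data: FixationDataset,
    cfg: KernelConfig,
    eps_den: float = 1e-12,
):
    """Supervised mean-shift vector and signed kernel-weight sum at ``x``.

    m(x) = sum_i y_i k(x, x_i) x_i / sum_i y_i k(x, x_i)  -  x
    s(x) = sum_i y_i k(x, x_i)

    The sign of ``s`` equals the sign of the signed density difference,
    so iterating ``x <- x + m(x)`` ascends the density difference where
    the positive class dominates and descends it where the negative
    class dominates — i.e. it ascends the absolute difference on both
    sides without any explicit sign flip.

    ``eps_den`` is the balance floor expressed relative to the largest
    single kernel weight at ``x``; below it the vector is numerically
    undefined and :class:`BalancedDensityError` is raised.
    """
    q, scalar = _as_queries(x)
    stats = signed_kernel_stats(q, data.points, data.labels, cfg)
    if np.any(stats["isolated"]):
        raise IsolatedQueryError("query isolated from all training fixations")
    if np.any(np.abs(stats["s_rel"]) < eps_den):
        raise BalancedDensityError(
            "signed kernel sum below balance floor; class densities cancel here"
        )
    m = stats["mean"] - q
    if scalar:
        return m[0], float(stats["s"][0])
    return m, stats["s"]
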