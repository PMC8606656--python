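"""Dual mode seeking on the class-density-difference surface.

The central routine iterates the supervised mean-shift map

    x  <-  x + m(x),      m(x) = sum_i y_i k(x, x_i) x_i / sum_i y_i k(x, x_i) - x

which ascends the signed density difference q(x) where the positive
class dominates (q > 0) and descends it where the negative class
dominates (q < 0) — in both cases increasing the absolute difference
|q(x)|, the continuous word-quality objective. Because the signed
kernel sum contains negative terms, the plain iteration does not
guarantee monotone progress; two safeguards restore it:

* backtracking line search — whenever a proposed step does not improve
  |q|, the step is repeatedly halved until it does (or a cap is hit and
  the kernel is frozen where it stands);
* adaptive step normalization — where the class densities nearly
  cancel, the denominator of m(x) is numerically meaningless and the
  iteration instead takes a short normalized step along the analytic
  gradient of |q|.

A batched engine drives many kernels simultaneously (the dictionary
pipeline seeds hundreds of kernels); the scalar entry points are thin
wrappers over batches of size one, so single-kernel and batched runs
follow bit-identical arithmetic. Classic (unsupervised) mean shift and
the guarded density-ratio ascent used by baselines run through the same
engine with a different objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import (
    FixationDataset,
    KernelConfig,
    _as_queries,
    _shifted_weights,
    _sqdist,
    grad_quality_signed,
    kde,
    signed_kernel_stats,
)

__all__ = ["SeekConfig", "ShiftTrajectory", "dual_mode_seek", "classic_mean_shift", "seek_all"]


@dataclass(frozen=True)
class SeekConfig:
    """Iteration controls for mode seeking.

    ``max_rounds`` caps accepted shift rounds (30 matches the reference
    protocol); ``tol`` is the displacement convergence threshold in
    pixels (defaults to ``1e-3 * h`` when left None); ``step_shrink`` is
    the backtracking multiplier; ``max_backtracks`` caps halvings per
    round, after which the kernel is frozen and treated as converged.
    """

    max_rounds: int = 30
    tol: float | None = None
    step_shrink: float = 0.5
    max_backtracks: int = 20
    eps_den: float = 1e-12

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0.0 < self.step_shrink < 1.0):
            raise ValueError("step_shrink must lie in (0, 1)")
        if self.max_backtracks < 0:
            raise ValueError("max_backtracks must be >= 0")

    def resolved_tol(self, cfg: KernelConfig) -> float:
        return self.tol if self.tol is not None else 1e-3 * cfg.h


@dataclass
class ShiftTrajectory:
    """One kernel's path through mode seeking.

    ``positions`` holds the initial position followed by every accepted
    position; ``q_values`` the objective value at each of them (|q| for
    dual seeking, plain density for classic mean shift, the guarded
    ratio for ratio mode). ``q_values`` is non-decreasing by
    construction of the line search.
    """

    positions: np.ndarray
    q_values: np.ndarray
    converged: bool
    initial_sign: int
    failed: bool = False

    @property
    def final(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


# ---------------------------------------------------------------------------
# batched objective/step evaluators


class _DualObjective:
    """|q(x)| with the supervised mean-shift step (gradient fallback)."""

    def __init__(self, data: FixationDataset, cfg: KernelConfig, seek: SeekConfig):
        self.data = data
        self.cfg = cfg
        self.seek = seek
        self.scale = cfg.norm / max(data.n, 1)

    def __call__(self, X: np.ndarray):
        st = signed_kernel_stats(X, self.data.points, self.data.labels, self.cfg)
        obj = np.abs(st["s"]) * self.scale
        sign = np.sign(st["s_rel"]).astype(int)
        step = st["mean"] - X
        frozen = st["isolated"].copy()
        balanced = (np.abs(st["s_rel"]) < self.seek.eps_den) & ~frozen
        if np.any(balanced):
            tol = self.seek.resolved_tol(self.cfg)
            g = np.atleast_2d(grad_quality_signed(X[balanced], self.data, self.cfg))
            gn = np.linalg.norm(g, axis=1)
            dirsign = np.where(sign[balanced] == 0, 1, sign[balanced])
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = g / gn[:, None]
            fb = tol * dirsign[:, None] * unit
            dead = gn == 0.0
            fb[dead] = 0.0
            step[balanced] = fb
            frozen[balanced] |= dead
        bad = ~np.all(np.isfinite(step), axis=1)
        step[bad] = 0.0
        return obj, step, frozen, sign, bad


class _ClassicObjective:
    """Pooled kernel density with the classic mean-shift step."""

    def __init__(self, points: np.ndarray, cfg: KernelConfig):
        self.points = np.asarray(points, dtype=float).reshape(-1, 2)
        if len(self.points) == 0:
            raise ValueError("classic mean shift needs a non-empty point set")
        self.labels = np.ones(len(self.points))
        self.cfg = cfg
        self.scale = cfg.norm / len(self.points)

    def __call__(self, X: np.ndarray):
        st = signed_kernel_stats(X, self.points, self.labels, self.cfg)
        obj = st["s"] * self.scale
        step = st["mean"] - X
        frozen = st["isolated"].copy()
        sign = np.ones(len(X), dtype=int)
        bad = ~np.all(np.isfinite(step), axis=1)
        step[bad] = 0.0
        return obj, step, frozen, sign, bad


class _RatioObjective:
    """Guarded density ratio p(x|X+) / (p(x|X-) + eps) with log-gradient step.

    The step h^2 * grad log[(p+ + t)/(p- + eps)] is a bounded
    combination of the two class mean-shift vectors; backtracking on the
    ratio value keeps the ascent monotone. The small absolute guards
    deliberately stop at preventing division blow-ups — the ratio
    objective's known pathologies (unbounded values over sparse negative
    regions, no coverage weighting) are part of what this baseline
    represents.
    """

    def __init__(self, data: FixationDataset, cfg: KernelConfig, seek: SeekConfig):
        self.data = data
        self.cfg = cfg
        neg = data.points_neg
        if len(neg) > 0:
            # eps = 1e-8 x the largest negative-class density over training points
            dens = _chunked_kde(data.points, neg, cfg, data.n)
            self.eps_ratio = 1e-8 * float(dens.max())
        else:
            self.eps_ratio = 1e-8 * cfg.norm / max(data.n, 1)
        self.tiny = 1e-12 * cfg.norm / max(data.n, 1)

    def _class_stats(self, X: np.ndarray, pts: np.ndarray):
        if len(pts) == 0:
            z = np.zeros(len(X))
            return z, np.zeros_like(X)
        d2 = _sqdist(X, pts)
        w, log_shift = _shifted_weights(d2, self.cfg.h)
        tot = w.sum(axis=1)
        dens = tot * np.exp(log_shift) * self.cfg.norm / self.data.n
        mean = (w @ pts) / tot[:, None]
        return dens, mean

    def __call__(self, X: np.ndarray):
        p_pos, m_pos = self._class_stats(X, self.data.points_pos)
        p_neg, m_neg = self._class_stats(X, self.data.points_neg)
        obj = p_pos / (p_neg + self.eps_ratio)
        alpha = p_pos / (p_pos + self.tiny)
        beta = p_neg / (p_neg + self.eps_ratio)
        step = alpha[:, None] * (m_pos - X) - beta[:, None] * (m_neg - X)
        frozen = (p_pos + p_neg) == 0.0
        step[frozen] = 0.0
        sign = np.sign(p_pos - p_neg).astype(int)
        bad = ~np.all(np.isfinite(step), axis=1)
        step[bad] = 0.0
        return obj, step, frozen, sign, bad


def _chunked_kde(queries, points, cfg, n_total, chunk=2000):
    out = np.empty(len(queries))
    for lo in range(0, len(queries), chunk):
        out[lo : lo + chunk] = kde(queries[lo : lo + chunk], points, cfg, n_total=n_total)
    return out


# ---------------------------------------------------------------------------
# batched seeking engine


def _seek_batch(inits: np.ndarray, objective, cfg: KernelConfig, seek: SeekConfig):
    X = np.array(inits, dtype=float)
    M = len(X)
    tol = seek.resolved_tol(cfg)

    obj, step, frozen, sign0, bad = objective(X)
    q = obj.copy()
    done = frozen | bad
    failed = bad.copy()

    hist_pos = [X.copy()]
    hist_q = [q.copy()]
    stop_round = np.where(done, 0, -1)

    for rnd in range(1, seek.max_rounds + 1):
        act = np.where(~done)[0]
        if len(act) == 0:
            break
        base = X[act]
        st = step[act]
        scale = np.ones(len(act))
        new_pos = base.copy()
        new_q = q[act].copy()
        new_step = st.copy()
        moved = np.zeros(len(act), dtype=bool)
        froze = np.zeros(len(act), dtype=bool)
        pending = np.arange(len(act))
        n_bt = 0
        while len(pending) > 0:
            prop = base[pending] + scale[pending, None] * st[pending]
            p_obj, p_step, p_frozen, _, p_bad = objective(prop)
            ok = (p_obj >= q[act][pending]) & ~p_frozen & ~p_bad & np.all(
                np.isfinite(prop), axis=1
            )
            acc = pending[ok]
            new_pos[acc] = prop[ok]
            new_q[acc] = p_obj[ok]
            new_step[acc] = p_step[ok]
            moved[acc] = True
            rej = pending[~ok]
            if n_bt >= seek.max_backtracks:
                froze[rej] = True
                pending = np.empty(0, dtype=int)
            else:
                scale[rej] *= seek.step_shrink
                pending = rej
                n_bt += 1

        disp = np.linalg.norm(new_pos - base, axis=1)
        X[act] = new_pos
        q[act] = new_q
        step[act] = new_step
        newly_done = froze | (moved & (disp < tol)) | failed[act]
        done[act[newly_done]] = True
        stop_round[act[newly_done]] = rnd
        hist_pos.append(X.copy())
        hist_q.append(q.copy())

    n_rounds = len(hist_pos) - 1
    stop_round[stop_round < 0] = n_rounds
    pos_arr = np.stack(hist_pos)  # (rounds+1, M, 2)
    q_arr = np.stack(hist_q)
    trajectories = []
    for i in range(M):
        r = stop_round[i]
        trajectories.append(
            ShiftTrajectory(
                positions=pos_arr[: r + 1, i].copy(),
                q_values=q_arr[: r + 1, i].copy(),
                converged=bool(done[i]) and not bool(failed[i]),
                initial_sign=int(sign0[i]),
                failed=bool(failed[i]),
            )
        )
    return trajectories


# ---------------------------------------------------------------------------
# public entry points


def dual_mode_seek(
    x0, data: FixationDataset, cfg: KernelConfig, seek: SeekConfig | None = None
) -> ShiftTrajectory:
    """Seek the nearest extremum of |q(x)| by supervised mean shift.

    Ascends the signed density difference from ``x0`` when the positive
    class dominates there, descends it when the negative class
    dominates; accepted steps never decrease |q|.
    """
    seek = seek or SeekConfig()
    x0_arr, _ = _as_queries(x0)
    traj = _seek_batch(x0_arr, _DualObjective(data, cfg, seek), cfg, seek)[0]
    if traj.failed:
        raise RuntimeError(
            f"dual mode seeking produced a non-finite position; trajectory so far: {traj.positions}"
        )
    return traj


def classic_mean_shift(
    x0, points, cfg: KernelConfig, seek: SeekConfig | None = None
) -> ShiftTrajectory:
    """Conventional (unsupervised) mean shift toward the nearest density mode."""
    seek = seek or SeekConfig()
    x0_arr, _ = _as_queries(x0)
    traj = _seek_batch(x0_arr, _ClassicObjective(points, cfg), cfg, seek)[0]
    if traj.failed:
        raise RuntimeError(
            f"mean shift produced a non-finite position; trajectory so far: {traj.positions}"
        )
    return traj


def seek_all(
    inits,
    data,
    cfg: KernelConfig,
    seek: SeekConfig | None = None,
    mode: str = "dual",
) -> list[ShiftTrajectory]:
    """Run mode seeking independently from every initial kernel.

    ``mode`` selects the objective: ``dual`` (supervised mean shift on
    |q|), ``classic`` (plain density ascent on the pooled points), or
    ``ratio`` (guarded positive/negative density-ratio ascent). ``data``
    is a :class:`FixationDataset`; for classic mode a bare point array
    is also accepted. Kernels that fail numerically are returned flagged
    rather than aborting the batch. Deterministic: no randomness inside.
    """
    seek = seek or SeekConfig()
    inits = np.asarray(inits, dtype=float).reshape(-1, 2)
    if len(inits) == 0:
        raise ValueError("need at least one initial kernel")
    if mode == "dual":
        objective = _DualObjective(data, cfg, seek)
    elif mode == "classic":
        pts = data.points if isinstance(data, FixationDataset) else data
        objective = _ClassicObjective(pts, cfg)
    elif mode == "ratio":
        objective = _RatioObjective(data, cfg, seek)
    else:
        raise ValueError(f"unknown seeking mode {mode!r}")
    return _seek_batch(inits, objective, cfg, seek)
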