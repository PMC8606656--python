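"""Synthetic gaze cohorts with class-dependent attention structure.

The generator emulates the statistical structure the dictionary method
assumes: each stimulus carries a small set of attention regions
(isotropic 2D Gaussian components — eyes, nose, mouth, off-face
background on a 700x500 face canvas), both diagnostic classes share the
component locations, and the classes differ only in how much fixation
mass they place on designated *discriminative* components. The
positive (ASD-like) class moves a weight gap ``delta`` of its mass away
from the eye regions toward nose/background, mirroring the reduced
eye-contact pattern the method is designed to detect; ``delta`` is
exactly the total-variation distance between the class weight vectors.

Inter-subject variability is modeled by drawing each subject's mixture
weights from a Dirichlet centered on their class weights; fixations
are i.i.d. draws from the subject's mixture, clipped to the canvas.
Without that jitter every subject would be exchangeable and
leave-one-subject-out evaluation would be trivially easy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter

from .density import FixationDataset

__all__ = ["AttentionModel", "CohortSpec", "default_face_model", "generate_cohort", "oracle_modes"]

logger = logging.getLogger(__name__)

CANVAS = (700.0, 500.0)


@dataclass(frozen=True)
class AttentionModel:
    """Class-conditional Gaussian-mixture attention map."""

    means: np.ndarray  # (J, 2) component centers, pixels
    sds: np.ndarray  # (J,) isotropic component sd, pixels
    base_weights: np.ndarray  # (J,) shared mixing proportions
    pos_weights: np.ndarray  # (J,) positive-class proportions
    neg_weights: np.ndarray  # (J,) negative-class proportions
    canvas: tuple = CANVAS
    component_names: tuple = ()

    def __post_init__(self) -> None:
        for name in ("means", "sds", "base_weights", "pos_weights", "neg_weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        j = len(self.means)
        if not (len(self.sds) == len(self.base_weights) == len(self.pos_weights)
                == len(self.neg_weights) == j):
            raise ValueError("component arrays must have equal length")
        for w in (self.base_weights, self.pos_weights, self.neg_weights):
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("class weights must be non-negative and sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")
        w, hgt = self.canvas
        if np.any(self.means[:, 0] < 0) or np.any(self.means[:, 0] > w) or np.any(
            self.means[:, 1] < 0
        ) or np.any(self.means[:, 1] > hgt):
            raise ValueError("component means must lie inside the canvas")

    def class_weights(self, label: int) -> np.ndarray:
        return self.pos_weights if label == 1 else self.neg_weights


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: subject counts, images per subject, fixations per image.

    ``subject_concentration`` is the Dirichlet concentration of the
    per-subject weight jitter (larger = subjects closer to their class
    mean; ``None`` disables jitter entirely).
    """

    n_pos: int = 30
    n_neg: int = 30
    n_images: int = 6
    fixations_per_image: int = 40
    subject_concentration: float | None = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_images", "fixations_per_image"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.subject_concentration is not None and self.subject_concentration <= 0:
            raise ValueError("subject_concentration must be positive")


def default_face_model(delta: float, sd: float = 30.0) -> AttentionModel:
    """Five-region face attention model with weight gap ``delta``.

    Regions: left eye, right eye, nose, mouth, off-face background on a
    700x500 canvas. The positive class sheds ``delta/2`` from each eye
    and gains ``delta/2`` on nose and background; the total-variation
    distance between the class weight vectors is exactly ``delta``.
    """
    if not (0.0 <= delta <= 0.4):
        raise ValueError("delta must lie in [0, 0.4]")
    means = np.array([
        [245.0, 180.0],  # left eye
        [455.0, 180.0],  # right eye
        [350.0, 270.0],  # nose
        [350.0, 360.0],  # mouth
        [120.0, 440.0],  # off-face background
    ])
    base = np.array([0.25, 0.25, 0.20, 0.20, 0.10])
    neg = base.copy()
    pos = base.copy()
    pos[0] -= delta / 2.0
    pos[1] -= delta / 2.0
    pos[2] += delta / 2.0
    pos[4] += delta / 2.0
    return AttentionModel(
        means=means,
        sds=np.full(5, float(sd)),
        base_weights=base,
        pos_weights=pos,
        neg_weights=neg,
        component_names=("left_eye", "right_eye", "nose", "mouth", "background"),
    )


def generate_cohort(model: AttentionModel, spec: CohortSpec) -> FixationDataset:
    """Draw a labeled fixation cohort, fully reproducible from the seed.

    Subject ids are ``pos###`` / ``neg###``; labels are +1 / -1. Each
    subject gets jittered mixture weights, each image an i.i.d. fixation
    sample from them, clipped to the canvas (clip fraction logged).
    """
    rng = np.random.default_rng(spec.seed)
    pts, labs, sids, iids = [], [], [], []
    n_clipped = 0
    n_total = 0
    for label, count, prefix in ((1, spec.n_pos, "pos"), (-1, spec.n_neg, "neg")):
        class_w = model.class_weights(label)
        for s in range(count):
            sid = f"{prefix}{s:03d}"
            if spec.subject_concentration is None:
                w = class_w
            else:
                alpha = np.maximum(class_w * spec.subject_concentration, 1e-6)
                w = rng.dirichlet(alpha)
            for im in range(spec.n_images):
                comps = rng.choice(len(w), size=spec.fixations_per_image, p=w)
                xy = model.means[comps] + rng.normal(
                    size=(spec.fixations_per_image, 2)
                ) * model.sds[comps, None]
                clipped = np.clip(xy, [0.0, 0.0], list(model.canvas))
                n_clipped += int(np.sum(np.any(clipped != xy, axis=1)))
                n_total += spec.fixations_per_image
                pts.append(clipped)
                labs.append(np.full(spec.fixations_per_image, label))
                sids.append(np.full(spec.fixations_per_image, sid, dtype=object))
                iids.append(np.full(spec.fixations_per_image, f"img{im:02d}", dtype=object))
    if n_clipped:
        logger.info("clipped %d / %d fixations to the canvas", n_clipped, n_total)
    return FixationDataset(
        points=np.vstack(pts),
        labels=np.concatenate(labs),
        subject_ids=np.concatenate(sids),
        image_ids=np.concatenate(iids),
    )


def expected_quality_surface(model: AttentionModel, h: float, xs, ys) -> np.ndarray:
    """Population signed density difference smoothed by the analysis kernel.

    A mixture component with sd ``s`` convolved with a Gaussian kernel of
    bandwidth ``h`` is Gaussian with variance ``s^2 + h^2``, so the
    expected signed quality surface is available in closed form (up to
    the balanced class-proportion factor, irrelevant for extrema).
    """
    gx, gy = np.meshgrid(np.asarray(xs, dtype=float), np.asarray(ys, dtype=float))
    out = np.zeros_like(gx)
    dw = model.pos_weights - model.neg_weights
    for j in range(len(model.means)):
        if dw[j] == 0.0:
            continue
        var = model.sds[j] ** 2 + h**2
        d2 = (gx - model.means[j, 0]) ** 2 + (gy - model.means[j, 1]) ** 2
        out += dw[j] * np.exp(-d2 / (2.0 * var)) / (2.0 * np.pi * var)
    return out


def oracle_modes(
    model: AttentionModel,
    h: float,
    grid_step: float = 0.5,
    rel_threshold: float = 0.1,
) -> list[dict]:
    """Grid-search extrema of the expected quality surface.

    Evaluates the analytic smoothed class-density difference on a
    ``grid_step``-pixel grid over the canvas and returns local extrema
    of its absolute value exceeding ``rel_threshold`` of the global
    maximum, as dicts with keys ``x``, ``y``, ``sign``, ``q``.
    """
    xs = np.arange(0.0, model.canvas[0] + grid_step / 2, grid_step)
    ys = np.arange(0.0, model.canvas[1] + grid_step / 2, grid_step)
    surf = expected_quality_surface(model, h, xs, ys)
    absq = np.abs(surf)
    peak = absq.max()
    if peak <= 0.0:
        return []
    local_max = (absq == maximum_filter(absq, size=3)) & (absq >= rel_threshold * peak)
    iy, ix = np.nonzero(local_max)
    modes = [
        {"x": float(xs[cx]), "y": float(ys[cy]), "sign": int(np.sign(surf[cy, cx])),
         "q": float(surf[cy, cx])}
        for cy, cx in zip(iy, ix)
    ]
    modes.sort(key=lambda m: -abs(m["q"]))
    return modes
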