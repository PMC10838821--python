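"""Bone-surface detection on 2D B-mode ultrasound frames.

The bone interface appears as a bright, roughly horizontal band with an
acoustic shadow beneath it: the soft-tissue/bone impedance step reflects
nearly all energy, so little signal returns from deeper tissue.  The
default, deterministic *classical* backend scores each pixel by combining
three cues — local brightness, a positive axial-gradient ridge response,
and darkness of everything deeper in the same scanline — and then keeps the
deepest strong local maximum per column (soft-tissue interfaces above the
bone can also be bright, but nothing bright should survive *below* it).

An optional trainable encoder–decoder backend (see :mod:`usbonereg._nn`)
exposes the same ``predict`` contract and is trained with a binary
cross-entropy + Dice loss, mirroring a standard medical-segmentation
recipe at desk scale.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "FrameMask",
    "SegmentationMetrics",
    "TrainConfig",
    "bone_probability_map",
    "extract_surface",
    "largest_component",
    "dice",
    "coverage_and_distance",
    "segment_frame",
    "segment_sweep",
    "train_segmenter",
]


@dataclasses.dataclass(frozen=True)
class FrameMask:
    """Binary per-frame segmentation, optionally with the score map behind it."""

    mask: np.ndarray
    score_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if self.score_map is not None:
            s = np.asarray(self.score_map, dtype=float)
            if s.shape != m.shape:
                raise ValueError("score map shape differs from mask shape")
            object.__setattr__(self, "score_map", s)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass(frozen=True)
class SegmentationMetrics:
    dice: float
    coverage_pct: float
    mean_surface_distance_mm: float


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training recipe for the learned backend.

    Defaults: batch size 4, Adam at 1e-4, BCE+Dice loss, Gaussian-blur
    (sigma 1.1) and left-right-flip augmentation each on an independent
    random quarter of the training split, 80:20 train/test split.
    """

    batch_size: int = 4
    learning_rate: float = 1e-4
    loss: str = "bce_dice"
    augment_fraction: float = 0.25
    blur_sigma: float = 1.1
    epochs: int = 20
    split_ratio: float = 0.8
    seed: int = 0
    base_filters: int = 8
    depth: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.augment_fraction <= 1.0):
            raise ValueError("augment_fraction must be in [0, 1]")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


# ---------------------------------------------------------------------------
# Classical backend
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def bone_probability_map(
    frame: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Per-pixel bone-surface score in [0, 1] for one B-mode frame.

    Product of three per-frame min-max-normalised factors:

    1. Gaussian-smoothed intensity (sigma 1 px) — the band is bright;
    2. an axial ridge response (negative second axial derivative of the
       smoothed image, clipped at zero) — a bright band has a rising upper
       edge and falling lower edge, so the curvature response peaks at the
       band centre instead of its leading edge;
    3. shadow factor ``1 - mean(deeper intensities)`` per scanline — the
       bone casts an acoustic shadow, soft-tissue echoes do not.

    Per-frame (not global) normalisation is used because B-mode gain varies
    frame to frame.  A constant frame yields an all-zero map.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2D image")
    smooth = ndimage.gaussian_filter(img, sigma=1.0)
    intensity = _minmax(smooth)

    band = ndimage.gaussian_filter1d(smooth, sigma=1.5, axis=0, order=2)
    ridge = _minmax(np.clip(-band, 0.0, None))

    norm = _minmax(img)
    # mean of strictly deeper pixels per column; last row has no deeper pixels
    rev_csum = np.cumsum(norm[::-1], axis=0)[::-1]
    n_deeper = np.arange(img.shape[0] - 1, -1, -1)[:, None].astype(float)
    deeper_mean = np.zeros_like(norm)
    valid = n_deeper[:, 0] > 0
    deeper_sum = rev_csum - norm
    deeper_mean[valid] = deeper_sum[valid] / n_deeper[valid]
    shadow = _minmax(1.0 - deeper_mean)

    return _minmax(intensity * ridge * shadow)


def extract_surface(
    score_map: np.ndarray, threshold: float = 0.3, min_score: float = 0.1
) -> FrameMask:
    """Pick one surface pixel per column: the deepest local maximum.

    Bone occludes deeper echoes, so among the candidate ridge responses of a
    scanline the deepest strong one is the bone interface.  Columns whose
    best score falls below ``min_score`` stay empty (no bone visible there).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    s = np.asarray(score_map, dtype=float)
    rows, cols = s.shape
    mask = np.zeros_like(s, dtype=bool)
    up = np.vstack([s[:1], s[:-1]])
    down = np.vstack([s[1:], s[-1:]])
    local_max = (s >= up) & (s >= down) & (s >= threshold)
    col_best = s.max(axis=0)
    for c in range(cols):
        if col_best[c] < min_score:
            continue
        candidates = np.nonzero(local_max[:, c])[0]
        if candidates.size:
            mask[candidates[-1], c] = True
    return FrameMask(mask=mask, score_map=s)


def largest_component(fm: FrameMask) -> FrameMask:
    """Keep only the largest 8-connected component of the mask.

    Ties on pixel count are broken toward the component with the smallest
    mean depth (row index) — the shallower structure.  An empty mask passes
    through unchanged.
    """
    mask = fm.mask
    if not mask.any():
        return fm
    labels = measure.label(mask, connectivity=2)
    best_label, best_key = None, None
    for lab in range(1, labels.max() + 1):
        where = labels == lab
        count = int(where.sum())
        mean_depth = float(np.nonzero(where)[0].mean())
        key = (-count, mean_depth)
        if best_key is None or key < best_key:
            best_key, best_label = key, lab
    return FrameMask(mask=labels == best_label, score_map=fm.score_map)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _as_mask(x) -> np.ndarray:
    if isinstance(x, FrameMask):
        return x.mask
    return np.asarray(x, dtype=bool)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1.0 if both empty."""
    ma, mb = _as_mask(a), _as_mask(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")
    total = int(ma.sum()) + int(mb.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / total


def coverage_and_distance(
    pred, truth, spacing: tuple[float, float]
) -> tuple[float, float]:
    """Column-wise coverage (%) and mean axial surface distance (mm).

    Coverage counts the truth columns for which the prediction has any
    detection; the distance averages, over those covered columns, the axial
    offset between the (deepest) predicted and truth pixels, scaled by the
    axial spacing.  Raises on an empty truth mask (coverage undefined).
    """
    mp, mt = _as_mask(pred), _as_mask(truth)
    if mp.shape != mt.shape:
        raise ValueError(f"mask shapes differ: {mp.shape} vs {mt.shape}")
    spacing_axial = float(spacing[0])
    truth_cols = np.nonzero(mt.any(axis=0))[0]
    if truth_cols.size == 0:
        raise ValueError("truth mask is empty; coverage is undefined")
    covered = []
    dists = []
    for c in truth_cols:
        pr = np.nonzero(mp[:, c])[0]
        if pr.size == 0:
            continue
        tr = np.nonzero(mt[:, c])[0]
        covered.append(c)
        dists.append(abs(float(pr[-1]) - float(tr[-1])) * spacing_axial)
    coverage_pct = 100.0 * len(covered) / truth_cols.size
    msd = float(np.mean(dists)) if dists else float("nan")
    return coverage_pct, msd


def evaluate_segmentation(
    pred, truth, spacing: tuple[float, float]
) -> SegmentationMetrics:
    """Dice, column coverage and mean axial surface distance in one call."""
    cov, msd = coverage_and_distance(pred, truth, spacing)
    return SegmentationMetrics(
        dice=dice(pred, truth), coverage_pct=cov,
        mean_surface_distance_mm=msd,
    )


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------

def segment_frame(
    frame: np.ndarray,
    spacing: tuple[float, float] = (1.0, 1.0),
    threshold: float = 0.3,
    min_score: float = 0.1,
    backend=None,
) -> FrameMask:
    """Score -> surface extraction -> largest-component cleanup for one frame."""
    if backend is None:
        score = bone_probability_map(frame, spacing)
    else:
        score = backend.predict(frame, spacing)
    return largest_component(extract_surface(score, threshold, min_score))


def segment_sweep(frames: Sequence[np.ndarray], spacing=(1.0, 1.0),
                  threshold: float = 0.3, min_score: float = 0.1,
                  backend=None) -> list[FrameMask]:
    return [
        segment_frame(f, spacing, threshold, min_score, backend)
        for f in frames
    ]


def train_segmenter(dataset, cfg: TrainConfig | None = None):
    """Train the compact encoder–decoder backend on labelled frames.

    ``dataset`` is a sequence of ``(frame, mask)`` pairs.  Returns a backend
    object with the same ``predict(frame, spacing) -> score_map`` contract
    as :func:`bone_probability_map`.  Deterministic given ``cfg.seed``.
    """
    from . import _nn

    return _nn.train_unet(dataset, cfg or TrainConfig())
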