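"""Two-stage rigid registration of the preoperative bone model to the
intraoperative ultrasound surface, and its accuracy evaluation.

Stage one is a coarse paired-landmark registration that initialises stage
two, a trimmed iterative-closest-point refinement between the CT surface
and the partial ultrasound cloud.  Because the sweep only sees one side of
the bone, correspondences run from the cloud into the (subsampled) CT
model — every cloud point has a genuine counterpart there — and are
robustified twice: pairs farther than a correspondence gate are discarded
and the largest-residual fraction is trimmed before each closed-form
rigid solve.

Accuracy is reported as the target registration error (TRE): the Euclidean
distance at each surgical target between its positions under the
gold-standard and the ultrasound-derived transforms.  A registration
counts as successful when the mean TRE is strictly below the clinical
threshold (default 5 mm, from the surgical-margin requirement).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .reconstruction import SurfaceModel
from .rigid_geometry import (
    PointSet,
    RigidTransform,
    compose,
    paired_point_register,
)

__all__ = [
    "ICPConfig",
    "RegistrationResult",
    "RegistrationFailureError",
    "coarse_register",
    "icp_register",
    "compute_tre",
    "classify_success",
    "save_result_json",
]

DEFAULT_SUCCESS_THRESHOLD_MM = 5.0


class RegistrationFailureError(RuntimeError):
    """No usable correspondences; the surfaces cannot be registered."""


@dataclasses.dataclass(frozen=True)
class ICPConfig:
    """Trimmed-ICP settings.

    ``trim_fraction`` drops that fraction of the largest-residual pairs each
    iteration (the ultrasound cloud covers only part of the CT surface, so
    some trimming is essential); ``max_corr_dist_mm`` gates correspondences
    outright.  ``subsample`` caps the number of source points (uniform,
    seeded) to bound the nearest-neighbour cost.
    """

    max_iterations: int = 100
    convergence_tol_mm: float = 1e-4
    trim_fraction: float = 0.2
    max_corr_dist_mm: float | None = 10.0
    subsample: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol_mm <= 0:
            raise ValueError("convergence tolerance must be positive")
        if not (0.0 <= self.trim_fraction <= 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5]")


@dataclasses.dataclass
class RegistrationResult:
    transform_ct_to_ref: RigidTransform
    coarse_rms_mm: float
    icp_rms_mm: float
    icp_iterations: int
    tre_per_target_mm: list[float] = dataclasses.field(default_factory=list)
    tre_mean_mm: float = float("nan")
    tre_sd_mm: float = float("nan")
    success: bool = False

    def to_dict(self) -> dict:
        return {
            "transform_ct_to_ref": self.transform_ct_to_ref.matrix.tolist(),
            "coarse_rms_mm": self.coarse_rms_mm,
            "icp_rms_mm": self.icp_rms_mm,
            "icp_iterations": self.icp_iterations,
            "tre_per_target_mm": list(self.tre_per_target_mm),
            "tre_mean_mm": self.tre_mean_mm,
            "tre_sd_mm": self.tre_sd_mm,
            "success": self.success,
        }


def coarse_register(
    ct_landmarks: PointSet, us_landmarks: PointSet
) -> tuple[RigidTransform, float]:
    """Paired-landmark initialisation of the surface registration."""
    return paired_point_register(ct_landmarks, us_landmarks)


def icp_register(
    source: SurfaceModel,
    target: SurfaceModel,
    init: RigidTransform,
    cfg: ICPConfig | None = None,
    history: list | None = None,
) -> tuple[RigidTransform, float, int]:
    """Trimmed ICP refining ``init`` so that ``source`` matches ``target``.

    Returns ``(transform, trimmed_rms_mm, iterations)``.  The loop keeps
    the best (lowest trimmed-rms) transform seen and stops as soon as an
    iteration fails to improve it by ``convergence_tol_mm``, so the
    accepted rms sequence is non-increasing by construction.  Pass a list
    as ``history`` to record the accepted rms per iteration.
    """
    cfg = cfg or ICPConfig()
    src_all = source.points
    tgt_all = target.points
    if src_all.shape[0] == 0 or tgt_all.shape[0] == 0:
        raise RegistrationFailureError("empty source or target surface")
    rng = np.random.default_rng(cfg.seed)
    if src_all.shape[0] > cfg.subsample:
        keep = rng.choice(src_all.shape[0], size=cfg.subsample, replace=False)
        src = src_all[keep]
    else:
        src = src_all
    if tgt_all.shape[0] > cfg.subsample:
        keep = rng.choice(tgt_all.shape[0], size=cfg.subsample, replace=False)
        tgt = tgt_all[keep]
    else:
        tgt = tgt_all

    # correspondences run from the partial ultrasound cloud into the dense
    # CT model: every cloud point has a true counterpart on the CT surface,
    # whereas the reverse direction manufactures spurious pairs for the CT
    # points the sweep never saw and drags the solution toward them
    T = RigidTransform(init.rotation, init.translation,
                       source.frame, target.frame)
    best_T, best_rms = T, np.inf
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        moved = T.apply(src)
        dists, nn = cKDTree(moved).query(tgt)
        keep = np.ones(len(tgt), dtype=bool)
        if cfg.max_corr_dist_mm is not None:
            keep &= dists <= cfg.max_corr_dist_mm
        if cfg.trim_fraction > 0:
            n_keep = int(np.ceil((1.0 - cfg.trim_fraction) * keep.sum()))
            if n_keep >= 3:
                kept_idx = np.nonzero(keep)[0]
                order = np.argsort(dists[kept_idx])
                keep = np.zeros(len(tgt), dtype=bool)
                keep[kept_idx[order[:n_keep]]] = True
        if keep.sum() < 3:
            raise RegistrationFailureError(
                "fewer than 3 correspondences survive gating/trimming"
            )
        rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
        improvement = best_rms - rms
        if rms < best_rms:
            best_T, best_rms = T, rms
            if history is not None:
                history.append(best_rms)
        if improvement < cfg.convergence_tol_mm:
            break
        T, _ = paired_point_register(
            PointSet(src[nn[keep]], frame=source.frame),
            PointSet(tgt[keep], frame=target.frame),
        )
    return best_T, best_rms, iterations


def compute_tre(
    targets_ct: PointSet,
    gold: RigidTransform,
    estimated: RigidTransform,
) -> tuple[np.ndarray, float, float]:
    """Per-target Euclidean error between gold and estimated registrations.

    Returns ``(per_target_mm, mean_mm, sd_mm)`` with the sample standard
    deviation (n-1 denominator; 0.0 for a single target).
    """
    p = targets_ct.points
    per_target = np.linalg.norm(gold.apply(p) - estimated.apply(p), axis=1)
    mean = float(per_target.mean())
    sd = float(per_target.std(ddof=1)) if per_target.size > 1 else 0.0
    return per_target, mean, sd


def classify_success(
    tre_mean_mm: float, threshold_mm: float = DEFAULT_SUCCESS_THRESHOLD_MM
) -> bool:
    """Strict comparison: successful iff mean TRE is below the threshold."""
    if tre_mean_mm < 0:
        raise ValueError("TRE cannot be negative")
    return tre_mean_mm < threshold_mm


def save_result_json(path: str | Path, result: RegistrationResult) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))
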