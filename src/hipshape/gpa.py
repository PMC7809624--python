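"""Generalized Procrustes analysis for 2D landmark configurations.

A configuration is reduced to a *pre-shape* by removing translation (centroid
to the origin) and size (centroid size scaled to 1).  Rotation is removed by
the closed-form 2D ordinary Procrustes solution

    theta = atan2(sum(x_i * y'_i - y_i * x'_i), sum(x_i * x'_i + y_i * y'_i)),

which is the proper rotation (no reflection) minimising
``||R(theta) @ shape - target||^2``.

The generalized fit iterates: rotate every pre-shape onto the current mean
estimate, rescale each aligned pre-shape onto the tangent plane of the mean
(division by its inner product with the mean), and re-estimate the mean as
the re-normalised coordinate-wise average.  The tangent rescaling makes the
converged mean equal to the plain average of the aligned configurations —
residuals then average to zero exactly, which is what downstream mode scores
rely on for their mean-0 standardisation.  A ``tangent_scale=False`` switch
reproduces the plain rotation-only variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmark_io import LandmarkSet

__all__ = [
    "PreShape",
    "GpaResult",
    "to_preshape",
    "optimal_rotation",
    "rotate",
    "align_to",
    "generalized_procrustes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreShape:
    """A centred, unit-centroid-size landmark configuration."""

    subject_id: str
    points: np.ndarray  # (n, 2); centroid 0, Frobenius norm 1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if np.abs(pts.mean(axis=0)).max() > 1e-10:
            raise ValueError("pre-shape centroid not at origin")
        if abs(np.sqrt((pts**2).sum()) - 1.0) > 1e-10:
            raise ValueError("pre-shape centroid size not 1")
        object.__setattr__(self, "points", pts)

    @property
    def vector(self) -> np.ndarray:
        """Interleaved (x1, y1, ..., xn, yn) view."""
        return self.points.ravel()


def to_preshape(shape: LandmarkSet, mirror: bool = False) -> PreShape:
    """Remove translation and size from a landmark configuration.

    ``mirror=True`` reflects the configuration about the y axis first (for
    datasets mixing left and right sides).  Idempotent on configurations that
    are already centred with unit centroid size.
    """
    pts = shape.points.astype(float).copy()
    if mirror:
        pts[:, 0] = -pts[:, 0]
    pts -= pts.mean(axis=0)
    size = np.sqrt((pts**2).sum())
    if size <= 0.0:
        raise ValueError(f"subject {shape.subject_id!r}: zero centroid size")
    return PreShape(shape.subject_id, pts / size)


def optimal_rotation(shape: PreShape | np.ndarray, target: PreShape | np.ndarray) -> float:
    """Proper rotation angle (radians) minimising ``||R(theta) shape - target||``."""
    p = shape.points if isinstance(shape, PreShape) else np.asarray(shape, float)
    t = target.points if isinstance(target, PreShape) else np.asarray(target, float)
    a = float(p[:, 0] @ t[:, 1] - p[:, 1] @ t[:, 0])
    b = float(p[:, 0] @ t[:, 0] + p[:, 1] @ t[:, 1])
    return float(np.arctan2(a, b))


def rotate(points: np.ndarray, theta: float) -> np.ndarray:
    """Rotate an (n, 2) configuration by ``theta`` radians about the origin."""
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T


def align_to(pre: PreShape | np.ndarray, target: np.ndarray,
             tangent_scale: bool = True) -> np.ndarray:
    """Rotate ``pre`` onto ``target``; optionally rescale onto its tangent plane.

    With ``tangent_scale`` the rotated configuration is divided by its inner
    product with ``target`` so the result satisfies ``<q, target> = ||target||^2``
    (Kendall tangent rescaling).  Raises if the configuration is nearly
    orthogonal to the target, where the rescale is unstable.
    """
    pts = pre.points if isinstance(pre, PreShape) else np.asarray(pre, float)
    aligned = rotate(pts, optimal_rotation(pts, target))
    if tangent_scale:
        dot = float((aligned * target).sum()) / float((target * target).sum())
        if dot <= 1e-8:
            raise ValueError("configuration nearly orthogonal to the alignment target")
        aligned = aligned / dot
    return aligned


def _align_stack(pres: np.ndarray, mean: np.ndarray,
                 tangent_scale: bool) -> np.ndarray:
    """Vectorised :func:`align_to` over a (N, n, 2) stack of pre-shapes."""
    a = pres[:, :, 0] @ mean[:, 1] - pres[:, :, 1] @ mean[:, 0]
    b = pres[:, :, 0] @ mean[:, 0] + pres[:, :, 1] @ mean[:, 1]
    theta = np.arctan2(a, b)
    c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
    x, y = pres[:, :, 0], pres[:, :, 1]
    aligned = np.stack([c * x - s * y, s * x + c * y], axis=-1)
    if tangent_scale:
        dots = (aligned * mean).sum(axis=(1, 2)) / float((mean * mean).sum())
        if (dots <= 1e-8).any():
            raise ValueError(
                "configuration nearly orthogonal to the alignment target")
        aligned = aligned / dots[:, None, None]
    return aligned


@dataclass
class GpaResult:
    """Output of :func:`generalized_procrustes`."""

    mean_shape: np.ndarray  # (n, 2), unit centroid size
    aligned: np.ndarray  # (n_subjects, n, 2)
    subject_ids: list[str]
    n_iterations: int
    converged: bool
    residual_norms: np.ndarray  # per-subject ||aligned - mean||
    ss_history: list[float]  # total Procrustes sum of squares per iteration
    tangent_scale: bool = True

    @property
    def n_shapes(self) -> int:
        return int(self.aligned.shape[0])


def canonical_rotation_angle(points: np.ndarray) -> float:
    """Angle that rotates a centred configuration into canonical orientation.

    The superimposition leaves one global rotation undetermined (it follows
    whatever shape initialised the mean), so results would depend on the
    arbitrary orientation of the input files.  Canonical orientation puts the
    configuration's major inertia axis along +y, with the 180-degree
    ambiguity resolved by requiring positive third moment along that axis.
    """
    pts = np.asarray(points, float)
    pts = pts - pts.mean(axis=0)
    sxx = float(pts[:, 0] @ pts[:, 0])
    syy = float(pts[:, 1] @ pts[:, 1])
    sxy = float(pts[:, 0] @ pts[:, 1])
    alpha = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)  # major-axis angle
    delta = np.pi / 2.0 - alpha
    y_rot = rotate(pts, delta)[:, 1]
    if (y_rot**3).sum() < 0.0:
        delta += np.pi
    return float(np.arctan2(np.sin(delta), np.cos(delta)))


def _mean_normalise(stack: np.ndarray) -> np.ndarray:
    m = stack.mean(axis=0)
    m -= m.mean(axis=0)
    return m / np.sqrt((m**2).sum())


def generalized_procrustes(
    shapes: Sequence[LandmarkSet],
    tol: float = 1e-10,
    max_iter: int = 100,
    tangent_scale: bool = True,
    mirror: Sequence[bool] | None = None,
) -> GpaResult:
    """Iteratively superimpose a set of landmark configurations.

    The mean is initialised as the first shape's pre-shape; each iteration
    rotates (and tangent-rescales) every pre-shape onto the current mean and
    re-estimates the mean as the re-normalised average.  Convergence is the
    Euclidean norm of the mean-shape change falling below ``tol``.
    """
    if len(shapes) < 2:
        raise ValueError("generalized Procrustes needs at least 2 shapes")
    counts = {s.n_points for s in shapes}
    if len(counts) > 1:
        raise ValueError(f"shapes disagree on point count: {sorted(counts)}")
    if mirror is None:
        mirror = [False] * len(shapes)
    pres = np.stack(
        [to_preshape(s, m).points for s, m in zip(shapes, mirror)]
    )
    ids = [s.subject_id for s in shapes]

    mean = pres[0].copy()
    aligned = pres.copy()
    ss_history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = _align_stack(pres, mean, tangent_scale)
        ss_history.append(float(((aligned - mean) ** 2).sum()))
        new_mean = _mean_normalise(aligned)
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        log.warning(
            "GPA did not converge in %d iterations (last mean shift above %g)",
            max_iter, tol,
        )
    # gauge-fix the arbitrary global orientation, then re-align everything
    # onto the canonical mean
    mean = rotate(mean, canonical_rotation_angle(mean))
    aligned = _align_stack(pres, mean, tangent_scale)
    resid = np.sqrt(((aligned - mean) ** 2).sum(axis=(1, 2)))
    return GpaResult(
        mean_shape=mean,
        aligned=aligned,
        subject_ids=ids,
        n_iterations=n_iter,
        converged=converged,
        residual_norms=resid,
        ss_history=ss_history,
        tangent_scale=tangent_scale,
    )


def procrustes_distance(a: LandmarkSet | PreShape, b: LandmarkSet | PreShape) -> float:
    """Partial Procrustes distance between two configurations after optimal
    translation/scale/rotation removal."""
    pa = a if isinstance(a, PreShape) else to_preshape(a)
    pb = b if isinstance(b, PreShape) else to_preshape(b)
    aligned = rotate(pa.points, optimal_rotation(pa, pb))
    return float(np.sqrt(((aligned - pb.points) ** 2).sum()))
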