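"""Point-distribution shape models: PCA mode extraction, projection of new
cohorts onto a reference model, and mode-score summaries.

A :class:`ShapeModel` holds the reference mean configuration (unit centroid
size), an orthonormal basis of deformation modes, and the per-mode standard
deviations of the raw training scores.  Projecting a configuration yields
scores standardised by the *reference* SDs, so scores for a new cohort are
expressed as deviations from the reference mean in reference-SD units and
need not have zero mean or unit SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gpa import (GpaResult, _align_stack, align_to, generalized_procrustes,
                  optimal_rotation, rotate, to_preshape)
from .landmark_io import LandmarkSet

__all__ = [
    "ShapeModel",
    "ModeScores",
    "build_model",
    "apply_reference_model",
    "align_to_model",
    "variance_explained",
    "mode_independence",
    "cross_timepoint_correlation",
    "save_model",
    "load_model",
    "read_scores",
    "write_scores",
]

SCHEMA_VERSION = 1


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude coefficient of each mode is
    positive, so serialized models are reproducible across runs."""
    out = modes.copy()
    for k in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[k])))
        if out[k, j] < 0:
            out[k] = -out[k]
    return out


@dataclass
class ShapeModel:
    """Reference statistical shape model.

    Attributes
    ----------
    mean_shape:
        (n_points, 2) reference mean, centred with unit centroid size.
    modes:
        (K, 2 * n_points) orthonormal deformation modes over interleaved
        (x1, y1, ..., xn, yn) coordinates.
    mode_sds:
        Per-mode SD of the raw training scores (denominator n - 1); the
        squares equal ``eigenvalues`` for models built from data.
    eigenvalues:
        Descending PCA eigenvalues of the retained modes.
    total_variance:
        Trace of the training residual covariance (across all ranks), the
        denominator of :func:`variance_explained`.
    """

    n_points: int
    mean_shape: np.ndarray
    modes: np.ndarray
    mode_sds: np.ndarray
    eigenvalues: np.ndarray
    total_variance: float
    training_n: int
    dim: int = 2
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, float)
        self.modes = np.asarray(self.modes, float)
        self.mode_sds = np.asarray(self.mode_sds, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if self.mean_shape.shape != (self.n_points, 2):
            raise ValueError("mean_shape must have shape (n_points, 2)")
        if self.modes.shape != (self.n_modes, 2 * self.n_points):
            raise ValueError("modes must have shape (K, 2 * n_points)")
        gram = self.modes @ self.modes.T
        if np.abs(gram - np.eye(self.n_modes)).max() > 1e-8:
            raise ValueError("mode vectors are not orthonormal")
        if (self.mode_sds <= 0).any():
            raise ValueError("mode SDs must be positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    @property
    def mean_vector(self) -> np.ndarray:
        return self.mean_shape.ravel()


@dataclass
class ModeScores:
    """Per-subject mode scores in reference-SD units."""

    subject_ids: list[str]
    values: np.ndarray  # (n_subjects, K)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.subject_ids):
            raise ValueError("scores must be (n_subjects, K) with matching ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite mode score")

    @property
    def n_modes(self) -> int:
        return int(self.values.shape[1])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"hsm{k}" for k in range(1, self.n_modes + 1)]
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="id"),
                            columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModeScores":
        return cls([str(i) for i in df.index], df.to_numpy(float))

    def mode(self, k: int) -> pd.Series:
        """1-based single-mode score series indexed by subject id."""
        if not 1 <= k <= self.n_modes:
            raise IndexError(f"mode index {k} out of range 1..{self.n_modes}")
        return pd.Series(self.values[:, k - 1],
                         index=pd.Index(self.subject_ids, name="id"),
                         name=f"hsm{k}")


def write_scores(scores: ModeScores, path: str | Path) -> None:
    scores.to_frame().to_csv(path, sep="\t")


def read_scores(path: str | Path) -> ModeScores:
    df = pd.read_csv(path, sep="\t", dtype={"id": str},
                     float_precision="round_trip").set_index("id")
    return ModeScores.from_frame(df)


def _polish_mean(gpa: GpaResult, tol: float = 1e-14, max_iter: int = 200):
    """Refine the GPA mean until the aligned shapes average to it exactly
    (to machine precision), so training residuals have zero mean."""
    mean = gpa.mean_shape
    pres = gpa.aligned  # already centred, tangent-rescaled; re-normalise each
    norms = np.sqrt((pres**2).sum(axis=(1, 2)))[:, None, None]
    pres = pres / norms
    aligned = pres
    for _ in range(max_iter):
        aligned = _align_stack(pres, mean, gpa.tangent_scale)
        new_mean = aligned.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        shift = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        mean = new_mean
        if shift < tol:
            break
    aligned = _align_stack(pres, mean, gpa.tangent_scale)
    return mean, aligned


def build_model(gpa: GpaResult, K: int = 10, metadata: dict | None = None) -> ShapeModel:
    """PCA of aligned-shape residuals about the (polished) Procrustes mean.

    The top-``K`` eigenvectors are retained with the fixed sign convention;
    ``mode_sds`` are the training-score SDs (denominator n - 1), whose squares
    equal the eigenvalues.
    """
    n = gpa.n_shapes
    if n < K + 1:
        raise ValueError(f"need at least K + 1 = {K + 1} shapes, got {n}")
    mean, aligned = _polish_mean(gpa)
    resid = (aligned - mean).reshape(n, -1)
    # SVD of the residual matrix; eigenvalues of cov = s^2 / (n - 1)
    _, svals, vt = np.linalg.svd(resid, full_matrices=False)
    eigvals = svals**2 / (n - 1)
    rank = int((svals > svals[0] * 1e-10).sum()) if svals.size else 0
    if K > rank:
        raise ValueError(
            f"requested K={K} modes but the training residuals have rank {rank}"
        )
    modes = _fix_mode_signs(vt[:K])
    return ShapeModel(
        n_points=mean.shape[0],
        mean_shape=mean,
        modes=modes,
        mode_sds=np.sqrt(eigvals[:K]),
        eigenvalues=eigvals[:K],
        total_variance=float(eigvals.sum()),
        training_n=n,
        metadata=metadata or {},
    )


def align_to_model(model: ShapeModel, shape: LandmarkSet,
                   mirror: bool = False) -> np.ndarray:
    """Pre-shape a configuration and superimpose it on the model mean
    (optimal rotation + tangent rescale).  Returns the aligned (n, 2) array."""
    if shape.n_points != model.n_points:
        raise ValueError(
            f"subject {shape.subject_id!r}: {shape.n_points} points but the "
            f"model expects {model.n_points}"
        )
    pre = to_preshape(shape, mirror=mirror)
    return align_to(pre, model.mean_shape, tangent_scale=True)


def apply_reference_model(
    model: ShapeModel,
    shapes: Sequence[LandmarkSet],
    cohort_pregpa: bool = False,
    mirror: bool = False,
) -> ModeScores:
    """Project configurations onto a reference model.

    Each shape is reduced to a pre-shape, rotated onto the reference mean and
    tangent-rescaled; the residual from the reference mean is projected on
    the mode basis and divided by the reference mode SDs.  Scores are
    therefore deviations from the reference mean shape in reference-SD units.

    ``cohort_pregpa=True`` implements the alternative reading in which the
    cohort is first superimposed internally by GPA and a single common
    similarity transform maps the cohort mean onto the reference mean.  The
    per-shape residuals are then taken from the commonly-transformed
    configurations; with individually optimal alignment (the default) scores
    are independent of cohort composition.
    """
    if cohort_pregpa:
        gpa = generalized_procrustes(list(shapes), mirror=[mirror] * len(shapes))
        theta = optimal_rotation(gpa.mean_shape, model.mean_shape)
        aligned = [rotate(q, theta) for q in gpa.aligned]
        ids = gpa.subject_ids
    else:
        aligned = [align_to_model(model, s, mirror=mirror) for s in shapes]
        ids = [s.subject_id for s in shapes]
    resid = np.stack(aligned).reshape(len(aligned), -1) - model.mean_vector
    raw = resid @ model.modes.T
    return ModeScores(ids, raw / model.mode_sds)


def variance_explained(model: ShapeModel, modes: Iterable[int]) -> float:
    """Fraction of total training variance carried by the given 1-based modes."""
    idx = sorted(set(int(m) for m in modes))
    if not idx:
        return 0.0
    if idx[0] < 1 or idx[-1] > model.n_modes:
        raise IndexError(f"mode indices must lie in 1..{model.n_modes}")
    sel = model.eigenvalues[[i - 1 for i in idx]]
    return float(sel.sum() / model.total_variance)


def mode_independence(scores: ModeScores) -> pd.DataFrame:
    """Pearson correlation matrix between mode columns.

    Constant columns have undefined correlations, reported as NaN.
    """
    if len(scores.subject_ids) < 3:
        raise ValueError("mode independence needs at least 3 subjects")
    df = scores.to_frame()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = df.corr()
    constant = df.std(ddof=1) == 0.0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr


def cross_timepoint_correlation(scores_t1: ModeScores,
                                scores_t2: ModeScores) -> pd.DataFrame:
    """Per-mode Pearson r between two timepoints for overlapping subjects.

    Returns a frame with columns ``mode``, ``r`` and ``n`` (overlap size).
    """
    f1, f2 = scores_t1.to_frame(), scores_t2.to_frame()
    common = f1.index.intersection(f2.index)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} overlapping subjects; need at least 3"
        )
    if scores_t1.n_modes != scores_t2.n_modes:
        raise ValueError("timepoints disagree on the number of modes")
    rows = []
    for k, col in enumerate(f1.columns, start=1):
        a = f1.loc[common, col].to_numpy()
        b = f2.loc[common, col].to_numpy()
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"mode": k, "r": r, "n": len(common)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: ShapeModel, path: str | Path) -> None:
    """Write the model as schema-versioned JSON with full-precision floats."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "n_points": model.n_points,
        "dim": model.dim,
        "training_n": model.training_n,
        "total_variance": model.total_variance,
        "mean_shape": model.mean_vector.tolist(),
        "modes": model.modes.tolist(),
        "mode_sds": model.mode_sds.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> ShapeModel:
    """Load a model saved by :func:`save_model`.

    Fails hard on a schema-version mismatch or if the stored mode vectors are
    no longer orthonormal (tampering / corruption check).
    """
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    n_points = int(payload["n_points"])
    return ShapeModel(
        n_points=n_points,
        mean_shape=np.asarray(payload["mean_shape"], float).reshape(n_points, 2),
        modes=np.asarray(payload["modes"], float),
        mode_sds=np.asarray(payload["mode_sds"], float),
        eigenvalues=np.asarray(payload["eigenvalues"], float),
        total_variance=float(payload["total_variance"]),
        training_n=int(payload["training_n"]),
        dim=int(payload.get("dim", 2)),
        metadata=payload.get("metadata", {}),
    )
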