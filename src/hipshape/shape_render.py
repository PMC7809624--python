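"""Reconstruct landmark outlines from mode scores and export them.

``reconstruct`` inverts model projection: ``mean + sum_k score_k * sd_k *
mode_k``.  Single-mode outline pairs visualise one mode at +/- c reference
SDs (solid above, dashed below, by convention).  Composite outlines sum
per-allele regression betas across several modes, multiplied by an
illustrative scale factor (default 20) that is always recorded in the output
so exaggerated displacements are not mistaken for physical effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ssm import ShapeModel

__all__ = [
    "Outline",
    "CompositeEffectSpec",
    "reconstruct",
    "mode_outline_pair",
    "composite_effect",
    "export_outline",
    "read_outline_tsv",
]

DEFAULT_COMPOSITE_SCALE = 20.0


@dataclass(frozen=True)
class Outline:
    """A reconstructed outline in the model coordinate frame."""

    points: np.ndarray  # (n_points, 2)
    label: str = ""
    style: str = "solid"  # solid | dashed

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("outline points must be (n, 2)")
        if self.style not in ("solid", "dashed"):
            raise ValueError(f"unknown outline style {self.style!r}")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class CompositeEffectSpec:
    """Per-mode betas (SD units per allele) plus an illustrative scale."""

    effects: tuple[tuple[int, float], ...]
    scale: float = DEFAULT_COMPOSITE_SCALE

    def __post_init__(self) -> None:
        modes = [m for m, _ in self.effects]
        if len(set(modes)) != len(modes):
            raise ValueError("duplicate mode indices in composite effect spec")
        if self.scale <= 0:
            raise ValueError("illustrative scale must be positive")
        object.__setattr__(self, "effects", tuple((int(m), float(b))
                                                  for m, b in self.effects))


def reconstruct(model: ShapeModel, scores: Sequence[float],
                label: str = "", style: str = "solid") -> Outline:
    """Outline at the given score vector (length K, reference-SD units)."""
    s = np.asarray(scores, float)
    if s.shape != (model.n_modes,):
        raise ValueError(
            f"score vector must have length {model.n_modes}, got {s.shape}"
        )
    vec = model.mean_vector + (s * model.mode_sds) @ model.modes
    return Outline(vec.reshape(model.n_points, 2), label=label, style=style)


def mode_outline_pair(model: ShapeModel, hsm: int, c: float = 2.0
                      ) -> tuple[Outline, Outline]:
    """Outlines at +c and -c reference SDs on a single mode (others zero)."""
    if not 1 <= hsm <= model.n_modes:
        raise IndexError(f"mode index {hsm} out of range 1..{model.n_modes}")
    scores = np.zeros(model.n_modes)
    scores[hsm - 1] = c
    plus = reconstruct(model, scores, label=f"hsm{hsm}+{c:g}sd", style="solid")
    scores[hsm - 1] = -c
    minus = reconstruct(model, scores, label=f"hsm{hsm}-{c:g}sd", style="dashed")
    return plus, minus


def composite_effect(model: ShapeModel, spec: CompositeEffectSpec) -> Outline:
    """Outline displaced by ``scale * beta_k`` SDs on each listed mode."""
    scores = np.zeros(model.n_modes)
    for mode, beta in spec.effects:
        if not 1 <= mode <= model.n_modes:
            raise IndexError(f"mode index {mode} out of range 1..{model.n_modes}")
        scores[mode - 1] = spec.scale * beta
    label = "composite(" + ",".join(
        f"{m}:{b:g}" for m, b in spec.effects) + f")x{spec.scale:g}"
    return reconstruct(model, scores, label=label, style="dashed")


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_outline(outlines: Sequence[Outline], path: str | Path,
                   metadata: dict | None = None) -> tuple[Path, Path]:
    """Write outlines as an SVG (one polyline per outline, solid/dashed
    styles preserved) and a lossless TSV of coordinates.

    ``path`` is a prefix; ``<path>.svg`` and ``<path>.tsv`` are written and
    their paths returned.  ``metadata`` key/values are embedded as SVG
    comments (e.g. the illustrative scale of a composite outline).
    """
    if not outlines:
        raise ValueError("no outlines to export")
    path = Path(path)
    svg_path = path.with_suffix(".svg")
    tsv_path = path.with_suffix(".tsv")

    recs = []
    for out in outlines:
        for i, (x, y) in enumerate(out.points, start=1):
            recs.append((out.label, out.style, i, x, y))
    pd.DataFrame(
        recs, columns=["label", "style", "point_index", "x", "y"]
    ).to_csv(tsv_path, sep="\t", index=False)

    all_pts = np.vstack([o.points for o in outlines])
    lo = all_pts.min(axis=0)
    hi = all_pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    pad = 0.05 * float(span.max())
    width = float(span[0] + 2 * pad)
    height = float(span[1] + 2 * pad)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="0 0 {width:.6g} {height:.6g}">'
    ]
    for key, value in (metadata or {}).items():
        parts.append(f"<!-- {key}: {value} -->")
    dash = {"solid": "none", "dashed": "6,4"}
    stroke_w = 0.004 * max(width, height)
    for out in outlines:
        # SVG y grows downward; flip so the outline appears upright
        pts = " ".join(
            f"{x - lo[0] + pad:.6g},{hi[1] - y + pad:.6g}" for x, y in out.points
        )
        parts.append(
            f'<polyline fill="none" stroke="black" '
            f'stroke-width="{stroke_w:.6g}" '
            f'stroke-dasharray="{dash[out.style]}" '
            f'data-label="{out.label}" points="{pts}"/>'
        )
    parts.append("</svg>")
    svg_path.write_text("\n".join(parts) + "\n")
    return svg_path, tsv_path


def read_outline_tsv(path: str | Path) -> list[Outline]:
    """Read back outlines written by :func:`export_outline` (TSV part)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for (label, style), grp in df.groupby(["label", "style"], sort=False):
        grp = grp.sort_values("point_index")
        out.append(Outline(grp[["x", "y"]].to_numpy(float),
                           label=str(label), style=str(style)))
    return out
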