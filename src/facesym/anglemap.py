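"""Angle-map rendering.

An angle map draws one line segment per landmark pair, from the left to
the right landmark of the aligned face, colour-coded by the magnitude of
the pair angle: blue at 0 degrees, red at or above the clip value
(default 5 degrees), linearly interpolated in RGB in between. Rendered on
a blank background the map carries no photographic content, making it a
privacy-preserving full-face picture of asymmetry.

Single maps are emitted as deterministic SVG text (byte-identical for
identical inputs); grids and photo overlays go through matplotlib (Agg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .landmarks import LandmarkSet, PairRegistry

__all__ = ["MapStyle", "angle_color", "render_map", "render_grid", "percentile_rows"]


@dataclass(frozen=True)
class MapStyle:
    """Rendering style; defaults follow the blue(0)->red(>=5 deg) convention."""

    clip_deg: float = 5.0
    line_width: float = 2.0
    background: str = "blank"  # or "photo"
    show_score: bool = True
    canvas: tuple[int, int] | None = None  # (width, height); default image size
    blue: tuple[int, int, int] = (0, 0, 255)
    red: tuple[int, int, int] = (255, 0, 0)

    def __post_init__(self) -> None:
        if self.clip_deg <= 0:
            raise ValueError("clip_deg must be > 0")


def angle_color(theta_deg: float | np.ndarray, style: MapStyle | None = None) -> np.ndarray:
    """RGB colour (0..255 ints) for |theta|, linear blue->red, clipped.

    Monotone in |theta| up to the clip; every |theta| >= clip_deg maps to
    the identical red endpoint.
    """
    style = style or MapStyle()
    frac = np.clip(np.abs(np.asarray(theta_deg, dtype=float)) / style.clip_deg, 0.0, 1.0)
    blue = np.asarray(style.blue, dtype=float)
    red = np.asarray(style.red, dtype=float)
    rgb = blue + np.multiply.outer(frac, red - blue)
    return np.round(rgb).astype(int)


def _hex(rgb: Sequence[int]) -> str:
    r, g, b = (int(v) for v in rgb)
    return f"#{r:02x}{g:02x}{b:02x}"


def render_map(
    aligned: LandmarkSet,
    theta: np.ndarray,
    registry: PairRegistry,
    subset: str | Sequence[int] | None = None,
    style: MapStyle | None = None,
    path: str | Path | None = None,
    score_deg: float | None = None,
) -> str:
    """Render one angle map as SVG text (optionally written to ``path``).

    Output bytes are a pure function of the inputs. Segments reaching
    outside the canvas are clipped by the SVG viewport.
    """
    style = style or MapStyle()
    ordinals = registry.subset_ordinals(subset)
    if ordinals.size == 0:
        raise ValueError("render_map requires a non-empty subset")
    theta = np.asarray(theta, dtype=float)
    w, h = style.canvas or (aligned.image_width, aligned.image_height)
    pairs = np.asarray(registry.pairs, dtype=int)[ordinals]
    colors = angle_color(theta[ordinals], style)
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f'<rect width="{w}" height="{h}" fill="white"/>',
    ]
    for (li, ri), rgb in zip(pairs, colors):
        x1, y1 = aligned.xy[li]
        x2, y2 = aligned.xy[ri]
        lines.append(
            f'<line x1="{x1:.3f}" y1="{y1:.3f}" x2="{x2:.3f}" y2="{y2:.3f}" '
            f'stroke="{_hex(rgb)}" stroke-width="{style.line_width:g}" '
            f'stroke-linecap="round"/>'
        )
    if style.show_score:
        if score_deg is None:
            score_deg = float(np.mean(np.abs(theta[ordinals])))
        lines.append(
            f'<text x="{w / 2:.1f}" y="{0.06 * h:.1f}" text-anchor="middle" '
            f'font-family="sans-serif" font-size="{0.04 * h:.1f}">'
            f"Score = {score_deg:.2f}&#176;</text>"
        )
    lines.append("</svg>")
    svg = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(svg)
    return svg


def render_grid(
    cells: Mapping[tuple[int, int], tuple[LandmarkSet, np.ndarray]],
    registry: PairRegistry,
    subset: str | Sequence[int] | None = None,
    style: MapStyle | None = None,
    row_labels: Sequence[str] | None = None,
    row_scores: Sequence[float] | None = None,
    path: str | Path | None = None,
):
    """Composite grid of angle maps: rows = sessions (chronological) or
    percentile groups, columns = expressions 1..9.

    ``cells`` maps (row_index, expression_id) to (aligned set, theta
    vector); missing cells render as labelled empty slots. Returns the
    matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    style = style or MapStyle()
    ordinals = registry.subset_ordinals(subset)
    pairs = np.asarray(registry.pairs, dtype=int)[ordinals]
    n_rows = (max(r for r, _ in cells) + 1) if cells else 1
    n_cols = 9
    fig, axes = plt.subplots(
        n_rows, n_cols, figsize=(1.6 * n_cols, 1.9 * n_rows), squeeze=False
    )
    for r in range(n_rows):
        for c in range(n_cols):
            ax = axes[r][c]
            ax.set_xticks([])
            ax.set_yticks([])
            key = (r, c + 1)
            if key not in cells:
                ax.text(0.5, 0.5, "missing", ha="center", va="center",
                        transform=ax.transAxes, fontsize=7, color="0.5")
                continue
            ls, theta = cells[key]
            segs = np.stack([ls.xy[pairs[:, 0]], ls.xy[pairs[:, 1]]], axis=1)
            cols = angle_color(np.asarray(theta)[ordinals], style) / 255.0
            ax.add_collection(LineCollection(segs, colors=cols, linewidths=1.0))
            ax.set_xlim(0, ls.image_width)
            ax.set_ylim(ls.image_height, 0)  # raster y-down
            ax.set_aspect("equal")
            if r == 0:
                ax.set_title(str(c + 1), fontsize=8)
    for r in range(n_rows):
        label = row_labels[r] if row_labels else ""
        if row_scores is not None:
            label = f"{label}  Score = {row_scores[r]:.2f}\N{DEGREE SIGN}".strip()
        if label:
            axes[r][0].set_ylabel(label, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig


def percentile_rows(score_by_dataset: Mapping[str, float]) -> list[tuple[str, str]]:
    """Pick (label, dataset_id) rows at max / 75th / median / 25th / min
    of the per-dataset "all" score, for cross-sectional grids."""
    items = sorted(score_by_dataset.items(), key=lambda kv: kv[1])
    if not items:
        return []
    n = len(items)

    def at(q: float) -> str:
        return items[min(n - 1, int(round(q * (n - 1))))][0]

    return [
        ("max", items[-1][0]),
        ("p75", at(0.75)),
        ("median", at(0.5)),
        ("p25", at(0.25)),
        ("min", items[0][0]),
    ]
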