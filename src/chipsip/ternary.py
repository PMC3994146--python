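"""Barycentric (ternary) representation of the three-concentration response.

Each enriched taxon's HCE triplet (H, M, L) is normalized to its sum, giving
barycentric coordinates (w_H, w_M, w_L) that sum to one and place the taxon
inside an equilateral triangle: corners are the pure responses, the centroid
is an equal response at all three concentrations. Copiotroph-like taxa pull
toward the H corner; saturated taxa sit near the centroid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError

#: Vertex placement: H apex, M bottom-left, L bottom-right (configurable in
#: :func:`ternary_xy`); fixed so rendered layouts are deterministic.
DEFAULT_VERTICES = {
    "H": (0.5, math.sqrt(3.0) / 2.0),
    "M": (0.0, 0.0),
    "L": (1.0, 0.0),
}


@dataclass
class TernaryPoint:
    taxon_id: str
    w_H: float
    w_M: float
    w_L: float
    guild: Optional[str] = None

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.w_H, self.w_M, self.w_L)


def normalize_hce(triplet: Sequence[float], taxon_id: str = "",
                  guild: Optional[str] = None) -> Optional[TernaryPoint]:
    """Normalize an (HCE_H, HCE_M, HCE_L) triplet to barycentric coordinates.

    Negative components (possible from regression noise) are floored to
    zero before normalizing, since barycentric coordinates must be
    nonnegative. Returns ``None`` (with a warning) when no component is
    positive — such taxa are not plotted.
    """
    arr = np.asarray(triplet, dtype=float)
    if arr.shape != (3,):
        raise ParameterError(f"expected an (H, M, L) triplet, got shape {arr.shape}")
    floored = np.clip(arr, 0.0, None)
    total = floored.sum()
    if total <= 0.0:
        warnings.warn(
            f"taxon {taxon_id!r}: no positive HCE component; excluded from ternary plot",
            stacklevel=2,
        )
        return None
    w = floored / total
    return TernaryPoint(taxon_id=taxon_id, w_H=float(w[0]), w_M=float(w[1]),
                        w_L=float(w[2]), guild=guild)


def ternary_xy(point: TernaryPoint, vertices: Optional[dict] = None
               ) -> tuple[float, float]:
    """Cartesian position of a barycentric point: sum of w_i * vertex_i."""
    v = vertices or DEFAULT_VERTICES
    x = point.w_H * v["H"][0] + point.w_M * v["M"][0] + point.w_L * v["L"][0]
    y = point.w_H * v["H"][1] + point.w_M * v["M"][1] + point.w_L * v["L"][1]
    return (x, y)


GUILD_COLORS = {
    "NULL_HML": "#4477aa",
    "INTERMEDIATE": "#ccbb44",
    "COPIOTROPH": "#ee6677",
    "OTHER": "#888888",
    None: "#888888",
}


def render_ternary(points: Sequence[TernaryPoint], path: str,
                   vertices: Optional[dict] = None, title: str = "") -> bool:
    """Render the ternary diagram to a vector/raster file (by extension).

    Points are colored by guild; layout is deterministic for fixed input.
    Returns False (no file written, warning emitted) on empty input.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not points:
        warnings.warn("no ternary points to render; skipping plot", stacklevel=2)
        return False
    v = vertices or DEFAULT_VERTICES
    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri_x = [v["M"][0], v["L"][0], v["H"][0], v["M"][0]]
    tri_y = [v["M"][1], v["L"][1], v["H"][1], v["M"][1]]
    ax.plot(tri_x, tri_y, color="black", lw=1)
    for label, (vx, vy) in v.items():
        offset = 0.04 if vy > 0 else -0.06
        ax.text(vx, vy + offset, label, ha="center",
                va="bottom" if vy > 0 else "top", fontsize=12)
    seen_guilds: list = []
    for pt in points:
        x, y = ternary_xy(pt, v)
        guild = pt.guild
        lbl = guild if guild not in seen_guilds else None
        if lbl is not None:
            seen_guilds.append(guild)
        ax.scatter([x], [y], s=28, color=GUILD_COLORS.get(guild, "#888888"),
                   edgecolors="black", linewidths=0.3, label=lbl, zorder=3)
    if seen_guilds:
        ax.legend(frameon=False, fontsize=9, loc="upper left")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return True
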