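"""Topographic maps of dV and EF on the nested recording spheres.

Each depth level is drawn as an orthographic disc (anterior, posterior
or superior view) with the recording sites as coloured markers and a
smooth inverse-distance-weighted shading over the disc.  Warm colours
mean higher values.  Back-facing electrodes are drawn hollow and are
excluded from the interpolation.

Handedness convention: the anterior view shows the head as a viewer
facing it would — the left hemisphere (x < 0) appears on the viewer's
right.  The posterior and superior views keep the left hemisphere on
the viewer's left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .geometry import DepthLevel, MontageLayout, RecordingPoint, recording_grid

__all__ = ["ViewSpec", "project_view", "render_map", "CMAP"]

#: Warm-high colormap used for all maps.
CMAP = "RdYlBu_r"

VIEWS = ("anterior", "posterior", "superior")
QUANTITIES = {"dv": ("delta_v_mV", "ΔV (mV)"), "ef": ("ef_mV_per_mm", "EF (mV/mm)")}


@dataclass(frozen=True)
class ViewSpec:
    """What to draw: quantity, depth (or the four-depth panel), view and
    colour-scale policy (``"global"`` shares bounds across depths,
    ``"per-depth"`` rescales each panel, or an explicit (low, high))."""

    quantity: str = "ef"
    depth: DepthLevel | str = "all"
    view: str = "superior"
    scale: str | tuple[float, float] = "global"

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {sorted(QUANTITIES)}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if isinstance(self.scale, tuple):
            lo, hi = self.scale
            if not lo < hi:
                raise ValueError(f"explicit scale bounds must satisfy low < high")
        if not (self.depth == "all" or isinstance(DepthLevel.parse(self.depth), DepthLevel)):
            raise ValueError(f"bad depth {self.depth!r}")

    @property
    def depths(self) -> list[DepthLevel]:
        if self.depth == "all":
            return list(DepthLevel)
        return [DepthLevel.parse(self.depth)]


def project_view(
    points: Sequence[RecordingPoint],
    view: str,
    center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Orthographic 2-D coordinates of recording points for one view.

    Projection axes (sphere-centred frame): anterior along -y with
    u = -x (facing-the-head handedness), posterior along +y with u = x,
    superior along -z with u = x, v = y.  ``hidden`` marks back-facing
    points (on the far hemisphere of their own depth sphere).
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    c = np.asarray(center, dtype=float)
    rows = []
    for p in points:
        x, y, z = p.world_array - c
        if view == "anterior":
            u, v, depth_axis = -x, z, y
        elif view == "posterior":
            u, v, depth_axis = x, z, -y
        else:  # superior
            u, v, depth_axis = x, y, z
        rows.append({
            "electrode": p.electrode, "depth": p.depth.name,
            "u": u, "v": v, "hidden": depth_axis < 0.0,
        })
    return pd.DataFrame(rows)


def _idw(u: np.ndarray, v: np.ndarray, vals: np.ndarray,
         gu: np.ndarray, gv: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation on the projected plane."""
    d2 = (gu[..., None] - u) ** 2 + (gv[..., None] - v) ** 2
    d2 = np.maximum(d2, 1e-12)
    w = d2 ** (-power / 2.0)
    return (w * vals).sum(axis=-1) / w.sum(axis=-1)


def render_map(
    table: pd.DataFrame,
    spec: ViewSpec,
    out: str | Path,
    diameter_mm: float | None = None,
    reference: str | None = None,
    projection: str | None = None,
    grid_n: int = 160,
    dpi: int = 120,
) -> Path:
    """Render a field table to a PNG map; returns the written path.

    ``diameter_mm``/``reference``/``projection`` default to the table's
    metadata (set by ``build_field_table``); they are needed to recover
    the sphere-frame positions from the exported reference-frame table.
    """
    diameter_mm = diameter_mm or table.attrs.get("diameter_mm")
    reference = reference or table.attrs.get("reference")
    projection = projection or table.attrs.get("projection", "mirror")
    if diameter_mm is None or reference is None:
        raise ValueError("diameter_mm and reference are required (not found "
                         "in the table's metadata)")
    layout = MontageLayout.standard(float(diameter_mm))
    points = recording_grid(layout, reference, projection=projection)
    proj = project_view(points, spec.view, layout.sphere.center_array)
    col, cbar_label = QUANTITIES[spec.quantity]

    merged = proj.merge(table[["electrode", "depth", col]],
                        on=["electrode", "depth"], validate="one_to_one")
    radius = layout.sphere.radius

    depths = spec.depths
    if isinstance(spec.scale, tuple):
        bounds = {d: spec.scale for d in depths}
    elif spec.scale == "per-depth":
        bounds = {}
        for d in depths:
            vals = merged.loc[merged["depth"] == d.name, col].dropna()
            bounds[d] = (float(vals.min()), float(vals.max()))
    else:  # global
        vals = merged.loc[merged["depth"].isin([d.name for d in depths]), col].dropna()
        bounds = {d: (float(vals.min()), float(vals.max())) for d in depths}

    n_panels = len(depths)
    ncols = 2 if n_panels == 4 else n_panels
    nrows = 2 if n_panels == 4 else 1
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(4.2 * ncols, 4.0 * nrows), squeeze=False)
    panel_tags = "ABCD"
    for i, depth in enumerate(depths):
        ax = axes[i // ncols][i % ncols]
        sub = merged[merged["depth"] == depth.name]
        r_sphere = radius * depth.radius_fraction
        lo, hi = bounds[depth]
        if hi <= lo:  # constant panel
            lo, hi = lo - 0.5, hi + 0.5
        norm = plt.Normalize(lo, hi)

        vis = sub[~sub["hidden"] & sub[col].notna()]
        gu, gv = np.meshgrid(np.linspace(-r_sphere, r_sphere, grid_n),
                             np.linspace(-r_sphere, r_sphere, grid_n))
        disc = gu ** 2 + gv ** 2 <= r_sphere ** 2
        if len(vis):
            shade = _idw(vis["u"].to_numpy(), vis["v"].to_numpy(),
                         vis[col].to_numpy(dtype=float), gu, gv)
            shade = np.where(disc, shade, np.nan)
            im = ax.pcolormesh(gu, gv, shade, cmap=CMAP, norm=norm,
                               shading="auto", rasterized=True)
            ax.scatter(vis["u"], vis["v"], c=vis[col], cmap=CMAP, norm=norm,
                       edgecolors="black", s=60, zorder=3)
        else:
            im = ax.pcolormesh(gu, gv, np.where(disc, lo, np.nan),
                               cmap=CMAP, norm=norm, shading="auto")
        hid = sub[sub["hidden"]]
        ax.scatter(hid["u"], hid["v"], facecolors="none", edgecolors="grey",
                   s=45, zorder=3)
        for _, row in sub.iterrows():
            ax.annotate(row["electrode"], (row["u"], row["v"]),
                        textcoords="offset points", xytext=(0, 6),
                        ha="center", fontsize=6,
                        color="grey" if row["hidden"] else "black")
        circ = plt.Circle((0, 0), r_sphere, fill=False, color="black", lw=0.8)
        ax.add_patch(circ)
        ax.set_xlim(-radius * 1.08, radius * 1.08)
        ax.set_ylim(-radius * 1.08, radius * 1.08)
        ax.set_aspect("equal")
        ax.set_axis_off()
        tag = f"({panel_tags[i]}) " if n_panels == 4 else ""
        ax.set_title(f"{tag}{depth.name} — {spec.view}", fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.75, label=cbar_label)

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=dpi, format="png")
    plt.close(fig)
    return out
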