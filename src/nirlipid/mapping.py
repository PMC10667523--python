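"""Visual outputs: pseudo-color NIR images, per-pixel prediction maps,
region summaries and the HCL/DS scatter with fatty-acid vertices.

Mapping adds no numerics beyond masking and color scaling: map values
are exactly the per-pixel regression outputs, and every figure is
written with a sibling CSV of the plotted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import ReflectanceCube

__all__ = [
    "PredictionMap",
    "RegionSummary",
    "pseudo_color",
    "summarize_region",
    "render_maps",
    "render_hcl_ds_plot",
]

#: Default pseudo-color band assignment (nm): R, G, B.
PSEUDO_RGB_NM = (1210.0, 1190.0, 1080.0)


@dataclass
class PredictionMap:
    """Per-pixel rasters (lipid mg/g, HCL, DS) over one image grid."""

    rasters: dict[str, np.ndarray]  # name -> (y, x) raster, NaN off-mask
    mask: np.ndarray
    color_limits: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, r in self.rasters.items():
            if r.shape != self.mask.shape:
                raise ValueError(f"raster {name!r} does not match the mask grid")
            if np.isfinite(r[~self.mask]).any():
                raise ValueError(f"raster {name!r} has values off the tissue mask")


@dataclass(frozen=True)
class RegionSummary:
    """Mean/SD of each raster inside one region of the tissue mask."""

    label: str
    n_pixels: int
    means: dict[str, float]
    sds: dict[str, float]


def _nearest_band(wavelengths: np.ndarray, nm: float) -> int:
    i = int(np.argmin(np.abs(wavelengths - nm)))
    spacing = float(np.median(np.diff(wavelengths))) if wavelengths.size > 1 else np.inf
    if abs(wavelengths[i] - nm) > spacing:
        raise ValueError(
            f"requested {nm} nm is outside the cube grid "
            f"(nearest band {wavelengths[i]:.1f} nm)"
        )
    return i


def pseudo_color(
    cube: ReflectanceCube,
    rgb_nm: tuple[float, float, float] = PSEUDO_RGB_NM,
) -> np.ndarray:
    """Pseudo-color NIR image from three bands (nearest-band lookup).

    Each channel is its band rescaled to [0, 1] by the masked-in min/max;
    constant bands map to mid-gray.  Off-mask pixels are black.
    """
    img = np.zeros((*cube.shape[:2], 3))
    for c, nm in enumerate(rgb_nm):
        band = cube.values[:, :, _nearest_band(cube.wavelengths, nm)]
        vals = band[cube.mask]
        lo, hi = float(vals.min()), float(vals.max())
        channel = np.zeros_like(band)
        if hi > lo:
            channel[cube.mask] = (vals - lo) / (hi - lo)
        else:
            channel[cube.mask] = 0.5
        img[:, :, c] = channel
    return img


def summarize_region(
    pmap: PredictionMap, region: np.ndarray, label: str = "region"
) -> RegionSummary:
    """Mean and SD of every raster within ``region`` (ANDed with the
    tissue mask).  Raises on an empty region."""
    sel = np.asarray(region, bool) & pmap.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"region {label!r} selects no tissue pixel")
    means = {k: float(r[sel].mean()) for k, r in pmap.rasters.items()}
    sds = {k: float(r[sel].std(ddof=0)) for k, r in pmap.rasters.items()}
    return RegionSummary(label=label, n_pixels=n, means=means, sds=sds)


_RASTER_STYLE = {
    "lipid": ("Total lipid (mg/g)", "viridis"),
    "hcl": ("HCL", "plasma"),
    "ds": ("DS", "cividis"),
}


def render_maps(
    pmap: PredictionMap,
    out_prefix: str | Path,
    pseudo: np.ndarray | None = None,
) -> list[Path]:
    """Write the prediction maps (and optional pseudo-color image) as PNGs
    with sibling CSVs of the per-pixel values."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if pseudo is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(pseudo)
        ax.set_axis_off()
        p = out_prefix.with_name(out_prefix.name + "_pseudo_color.png")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    for name, raster in pmap.rasters.items():
        title, cmap = _RASTER_STYLE.get(name, (name, "viridis"))
        lo, hi = pmap.color_limits.get(
            name,
            (float(np.nanmin(raster)), float(np.nanmax(raster))),
        )
        fig, ax = plt.subplots(figsize=(4.4, 4))
        im = ax.imshow(raster, cmap=cmap, vmin=lo, vmax=hi)
        fig.colorbar(im, ax=ax, label=title)
        ax.set_axis_off()
        p = out_prefix.with_name(f"{out_prefix.name}_{name}.png")
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        ys, xs = np.where(pmap.mask)
        pd.DataFrame({"y": ys, "x": xs, name: raster[pmap.mask]}).to_csv(
            p.with_suffix(".csv"), index=False
        )
        written += [p, p.with_suffix(".csv")]
    return written


def render_hcl_ds_plot(
    points: pd.DataFrame,
    out_path: str | Path,
) -> tuple[Path, Path]:
    """The HCL/DS scatter: tissue points per group plus per-fatty-acid
    vertices (from :func:`nirlipid.chem.hcl_ds_scatter_data`).

    Writes the figure and a CSV holding exactly the plotted coordinates;
    returns both paths.
    """
    if points.empty:
        raise ValueError("no points to plot")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    tissue = points[points["kind"] == "tissue"]
    for label, grp in tissue.groupby("label", sort=False):
        ax.scatter(grp["hcl"], grp["ds"], s=28, label=label or "tissue")
    fas = points[points["kind"] == "fatty_acid"]
    ax.scatter(
        fas["hcl"], fas["ds"], marker="x", c="k", s=40, label="fatty acids"
    )
    for _, row in fas.iterrows():
        ax.annotate(
            row["label"], (row["hcl"], row["ds"]),
            textcoords="offset points", xytext=(4, 3), fontsize=7,
        )
    ax.set_xlabel("HCL (hydrocarbon chain length)")
    ax.set_ylabel("DS (degree of saturation)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    csv_path = out_path.with_suffix(".csv")
    points.to_csv(csv_path, index=False)
    return out_path, csv_path
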