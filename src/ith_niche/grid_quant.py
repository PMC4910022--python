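"""Tile-grid quantification of marker positivity on label images.

The section image is overlaid with a virtual lattice of squares (1 mm^2 at
native resolution).  Per square, positivity is the percentage of positive
nuclei (PNC) or positive pixels (PPC) within the square's cancerous area;
squares partly covered by non-cancerous tissue are normalized to the
corrected (cancerous) area.
"""

from __future__ import annotations

import logging

import numpy as np
from matplotlib.colors import LinearSegmentedColormap
import matplotlib

from .grids import MarkerGrid, SquareStatus, write_grid_tsv

__all__ = [
    "build_grid",
    "positive_nuclear_count",
    "positive_pixel_count",
    "quantify_slide",
    "heatmap_export",
    "stain_mask_from_rgb",
]

log = logging.getLogger(__name__)

#: squares with tumour fraction below this are treated as non-tumour
#: (unstable denominators); not a value stated by the source workflow
MIN_TUMOUR_FRACTION = 0.05


def _block_sums(img: np.ndarray, sq: int) -> np.ndarray:
    """Per-square sums of ``img``, handling partial squares at the edges."""
    H, W = img.shape
    rows = -(-H // sq)
    cols = -(-W // sq)
    out = np.zeros((rows, cols), dtype=float)
    for r in range(rows):
        for c in range(cols):
            out[r, c] = img[r * sq : (r + 1) * sq, c * sq : (c + 1) * sq].sum()
    return out


def _block_counts(shape: tuple[int, int], sq: int) -> np.ndarray:
    """Pixel count of each square (smaller for partial edge squares)."""
    return _block_sums(np.ones(shape, dtype=float), sq)


def build_grid(
    tumour_mask: np.ndarray,
    square_size_px: int,
    marker: str = "unknown",
    mode: str = "PNC",
    min_tumour_fraction: float = MIN_TUMOUR_FRACTION,
) -> MarkerGrid:
    """Overlay the virtual grid and derive square statuses from the mask.

    Square status: tumour if the mask covers the whole square, non-tumour
    if none of it (or less than ``min_tumour_fraction``), mixed otherwise.
    ``area_fraction`` is the tumour-pixel fraction of each square's actual
    pixel count (edge squares may be partial).
    """
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    if not tumour_mask.any():
        raise ValueError("no tumour area in mask")
    if square_size_px < 1:
        raise ValueError("square_size_px must be >= 1")
    npx = _block_counts(tumour_mask.shape, square_size_px)
    frac = _block_sums(tumour_mask.astype(float), square_size_px) / npx
    status = np.full(frac.shape, SquareStatus.MIXED, dtype=np.int8)
    status[frac >= 1.0] = SquareStatus.TUMOUR
    status[frac < min_tumour_fraction] = SquareStatus.NONTUMOUR
    frac = np.where(status == SquareStatus.NONTUMOUR, 0.0, frac)
    return MarkerGrid(
        marker=marker,
        mode=mode,
        status=status,
        area_fraction=frac,
        values=np.full(frac.shape, np.nan),
    )


def positive_nuclear_count(
    grid: MarkerGrid,
    nuclei_labels: np.ndarray,
    nuclei_positive: np.ndarray,
    square_size_px: int,
    tumour_mask: np.ndarray | None = None,
) -> MarkerGrid:
    """Fill a grid skeleton with % positive nuclei (PNC) per square.

    Each nucleus is assigned to exactly one square by its centroid; in
    mixed squares only nuclei whose centroid lies in the cancerous area are
    counted.  Squares with zero nuclei keep a NaN value (flagged, excluded
    from downstream statistics).
    """
    from scipy import ndimage

    nuclei_labels = np.asarray(nuclei_labels)
    labels = np.arange(1, nuclei_labels.max() + 1)
    if len(labels) == 0:
        raise ValueError("no nuclei in label image")
    centroids = ndimage.center_of_mass(
        np.ones_like(nuclei_labels), nuclei_labels, index=labels
    )
    values = np.full(grid.shape, np.nan)
    n_all = np.zeros(grid.shape)
    n_pos = np.zeros(grid.shape)
    for lab, (cy, cx) in zip(labels, centroids):
        iy, ix = int(cy), int(cx)
        if tumour_mask is not None and not tumour_mask[iy, ix]:
            continue
        r, c = iy // square_size_px, ix // square_size_px
        if grid.status[r, c] == SquareStatus.NONTUMOUR:
            continue
        n_all[r, c] += 1
        if nuclei_positive[lab]:
            n_pos[r, c] += 1
    quantifiable = (n_all > 0) & (grid.status != SquareStatus.NONTUMOUR)
    values[quantifiable] = 100.0 * n_pos[quantifiable] / n_all[quantifiable]
    n_nuclei = np.where(grid.status != SquareStatus.NONTUMOUR, n_all, np.nan)
    return MarkerGrid(
        marker=grid.marker,
        mode="PNC",
        status=grid.status.copy(),
        area_fraction=grid.area_fraction.copy(),
        values=values,
        n_nuclei=n_nuclei,
        square_size_mm=grid.square_size_mm,
    )


def positive_pixel_count(
    grid: MarkerGrid,
    stain: np.ndarray,
    tumour_mask: np.ndarray,
    square_size_px: int,
) -> MarkerGrid:
    """Fill a grid skeleton with % positive pixels (PPC) per square.

    The denominator is the square's cancerous-area pixel count (corrected
    area), so a half-tumour square whose tumour half is 50% stained scores
    50, not 25.
    """
    stain = np.asarray(stain, dtype=bool)
    tumour_mask = np.asarray(tumour_mask, dtype=bool)
    pos = _block_sums((stain & tumour_mask).astype(float), square_size_px)
    area = _block_sums(tumour_mask.astype(float), square_size_px)
    values = np.full(grid.shape, np.nan)
    analysed = grid.status != SquareStatus.NONTUMOUR
    if (analysed & (area == 0)).any():
        raise ValueError("analysed square with zero cancerous area — status contract violated")
    values[analysed] = 100.0 * pos[analysed] / area[analysed]
    return MarkerGrid(
        marker=grid.marker,
        mode="PPC",
        status=grid.status.copy(),
        area_fraction=grid.area_fraction.copy(),
        values=values,
        square_size_mm=grid.square_size_mm,
    )


def quantify_slide(slide, mode: str | None = None) -> MarkerGrid:
    """Quantify a :class:`~ith_niche.simulate_grids.SlideImage` end to end:
    build the grid from the pixel mask, then apply PNC or PPC."""
    mode = mode or slide.expected_grid.mode
    skel = build_grid(
        slide.tumour_mask_px,
        slide.px_per_square,
        marker=slide.expected_grid.marker,
        mode=mode,
    )
    if mode == "PNC":
        return positive_nuclear_count(
            skel,
            slide.nuclei_labels,
            slide.nuclei_positive,
            slide.px_per_square,
            tumour_mask=slide.tumour_mask_px,
        )
    return positive_pixel_count(skel, slide.stain, slide.tumour_mask_px, slide.px_per_square)


_GREEN_RED = LinearSegmentedColormap.from_list(
    "positivity", ["#00a000", "#ffff00", "#ff0000"]
)


def heatmap_export(
    grid: MarkerGrid,
    out_png: str | None = None,
    out_tsv: str | None = None,
    scale_max: float | None = None,
):
    """Render a grid as a green→red positivity heat map.

    Colour ramps over [0, scale_max] (default 100 for full-range PNC
    markers, 25 otherwise); non-tumour squares are white/open.  Values
    above scale_max are clipped to red with a warning.  Returns the
    matplotlib figure.
    """
    import matplotlib.pyplot as plt

    if scale_max is None:
        scale_max = 100.0 if grid.mode == "PNC" and grid.marker in ("HIF1A", "HIF2A") else 25.0
    over = np.isfinite(grid.values) & (grid.values > scale_max)
    if over.any():
        log.warning(
            "%d square(s) exceed scale_max=%g and are clipped to red", over.sum(), scale_max
        )
    shown = np.clip(grid.values, 0, scale_max)
    cmap = _GREEN_RED.copy()
    cmap.set_bad("white")
    fig, ax = plt.subplots(figsize=(max(3, grid.shape[1] / 3), max(3, grid.shape[0] / 3)))
    im = ax.imshow(np.ma.masked_invalid(shown), cmap=cmap, vmin=0, vmax=scale_max)
    ax.set_title(f"{grid.marker} ({grid.mode})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label=f"% positivity (0–{scale_max:g})")
    if out_png:
        fig.savefig(out_png, dpi=120, bbox_inches="tight")
    if out_tsv:
        write_grid_tsv(grid, out_tsv)
    if matplotlib.get_backend().lower() == "agg" and out_png:
        plt.close(fig)
    return fig


def stain_mask_from_rgb(rgb: np.ndarray, brown_threshold: float = 0.2) -> np.ndarray:
    """Crude DAB-positivity mask from an RGB image (brown vs other colours).

    Provided for exploratory use on real scans; the validated analysis path
    consumes label images or precomputed grids, not raw RGB.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.max() > 1:
        rgb = rgb / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    brownness = r - b
    return (brownness > brown_threshold) & (r > g) & (g > b)
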