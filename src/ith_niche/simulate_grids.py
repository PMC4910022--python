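"""Synthetic marker grids, aligned panels and slide-like label images.

The generator emulates the measurement structure of the tile-grid IHC
workflow: one connected tumour region per section (~60-90 analysable 1 mm^2
squares, matching real section scale), a per-square positivity value with a
configurable additive enrichment in the outermost tumour layer, and
Gaussian measurement noise truncated to the marker's value range.  Ground
truth (layer depth, noiseless values) is returned alongside every grid so
downstream zone and heterogeneity analyses can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grids import MarkerGrid, SquareStatus, TumourPanel, default_mode
from .zones import layer_depths

__all__ = [
    "GridSimConfig",
    "GridTruth",
    "SlideImage",
    "simulate_marker_grid",
    "simulate_slide_image",
    "simulate_panel",
    "simulate_cohort",
    "STUDY_MARKERS",
]

#: default marker panel: (name, baseline %, peripheral delta %, noise sd %, range max %)
STUDY_MARKERS = (
    ("HIF1A", 30.0, 12.0, 6.0, 100.0),
    ("HIF2A", 25.0, 10.0, 6.0, 100.0),
    ("pmTOR", 8.0, 4.0, 2.0, 25.0),
    ("pS6RP", 7.0, 4.0, 2.0, 25.0),
    ("KI67", 5.0, 6.0, 2.0, 25.0),
)


@dataclass(frozen=True)
class GridSimConfig:
    """Parameters of one simulated marker grid.

    ``peripheral_delta`` is the additive % enrichment of the outermost
    tumour layer over ``baseline``; it encodes the ground truth that the
    zonal analysis is meant to recover.  ``value_range_max`` is 100 for
    full-range (PNC HIF-type) markers and 25 for the restricted-range
    markers.
    """

    rows: int = 12
    cols: int = 12
    tumour_shape: str = "blob"  # "ellipse" | "blob"
    nontumor_fraction: float = 0.45
    baseline: float = 10.0
    peripheral_delta: float = 0.0
    noise_sd: float = 2.0
    value_range_max: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.tumour_shape not in ("ellipse", "blob"):
            raise ValueError(f"unknown tumour_shape {self.tumour_shape!r}")
        if not 0 <= self.nontumor_fraction < 1:
            raise ValueError("nontumor_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.baseline <= self.value_range_max:
            raise ValueError("baseline must lie in [0, value_range_max]")
        if self.peripheral_delta < -self.baseline:
            raise ValueError("peripheral_delta must be >= -baseline")


@dataclass
class GridTruth:
    """Noise-free ground truth of a simulated grid."""

    layer_depth: np.ndarray  # int; 1 = outermost tumour layer, 0 = non-tumour
    noiseless: np.ndarray  # expected value per square (NaN off-tumour)

    @property
    def tumour_mask(self) -> np.ndarray:
        return self.layer_depth > 0


def _tumour_mask(cfg: GridSimConfig, rng: np.random.Generator) -> np.ndarray:
    target = 1.0 - cfg.nontumor_fraction
    if cfg.tumour_shape == "ellipse":
        f = min(1.0, np.sqrt(4.0 * target / np.pi))
        ry, rx = f * cfg.rows / 2.0, f * cfg.cols / 2.0
        cy, cx = (cfg.rows - 1) / 2.0, (cfg.cols - 1) / 2.0
        r, c = np.mgrid[0 : cfg.rows, 0 : cfg.cols]
        mask = ((r - cy) / max(ry, 0.5)) ** 2 + ((c - cx) / max(rx, 0.5)) ** 2 <= 1.0
    else:  # irregular blob: thresholded smoothed Gaussian field
        fieldv = rng.standard_normal((cfg.rows, cfg.cols))
        fieldv = ndimage.gaussian_filter(fieldv, sigma=max(cfg.rows, cfg.cols) / 4.0)
        thresh = np.quantile(fieldv, 1.0 - target)
        mask = fieldv >= thresh
    # keep the largest 8-connected component so the tumour is one region
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    if n == 0:
        raise ValueError("simulated tumour region is empty; relax the geometry")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def simulate_marker_grid(
    cfg: GridSimConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerGrid, GridTruth]:
    """Simulate one marker grid with outermost-layer enrichment.

    Each tumour square's expected value is ``baseline + peripheral_delta``
    if the square lies in the outermost tumour layer, else ``baseline``;
    Gaussian noise of s.d. ``noise_sd`` is added and the result truncated
    to [0, value_range_max].  Identical config and seed give identical
    output.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mask = _tumour_mask(cfg, rng)
    depth = layer_depths(mask)
    noiseless = np.where(
        mask,
        np.clip(
            cfg.baseline + cfg.peripheral_delta * (depth == 1),
            0.0,
            cfg.value_range_max,
        ),
        np.nan,
    )
    values = noiseless + rng.normal(0.0, cfg.noise_sd, size=mask.shape)
    values = np.where(mask, np.clip(values, 0.0, cfg.value_range_max), np.nan)
    grid = MarkerGrid(
        marker="synthetic",
        mode="PNC" if cfg.value_range_max > 25 else "PPC",
        status=np.where(mask, SquareStatus.TUMOUR, SquareStatus.NONTUMOUR),
        area_fraction=mask.astype(float),
        values=values,
    )
    return grid, GridTruth(layer_depth=depth, noiseless=noiseless)


# --------------------------------------------------------------------------
# slide-like label images


@dataclass
class SlideImage:
    """Rasterized grid realization with constructed cell/pixel labels.

    ``nuclei_labels`` is a label image of disjoint nucleus disks (0 =
    background); ``nuclei_positive[label]`` marks positive nuclei.
    ``stain`` marks positive pixels.  ``expected_grid`` holds the exact
    per-square fractions the raster encodes, so grid quantification can be
    checked for exact round-trip recovery.
    """

    tumour_mask_px: np.ndarray
    nuclei_labels: np.ndarray
    nuclei_positive: np.ndarray  # bool, indexed by label id (0 unused)
    stain: np.ndarray
    px_per_square: int
    expected_grid: MarkerGrid
    truth: GridTruth


def simulate_slide_image(
    cfg: GridSimConfig,
    px_per_square: int = 12,
    mode: str = "PNC",
    nuclei_per_square: int = 20,
) -> SlideImage:
    """Rasterize a simulated grid into a slide-like label image.

    Counts are constructed first and drawn second: for PNC mode each tumour
    square gets ``nuclei_per_square`` disjoint nucleus disks of which
    ``round(value/100 * n)`` are positive; for PPC mode ``round(value/100 *
    n_px)`` pixels are stained.  ``expected_grid`` carries the resulting
    exact fractions, so the raster→grid round trip is an identity.
    """
    if px_per_square < 8:
        raise ValueError("px_per_square must be >= 8")
    if mode not in ("PNC", "PPC"):
        raise ValueError("mode must be PNC or PPC")
    grid, truth = simulate_marker_grid(cfg)
    rows, cols = grid.shape
    H, W = rows * px_per_square, cols * px_per_square
    tumour_px = np.kron(grid.tumour_mask, np.ones((px_per_square, px_per_square), bool))
    nuclei_labels = np.zeros((H, W), dtype=np.int32)
    stain = np.zeros((H, W), dtype=bool)
    expected = np.full((rows, cols), np.nan)
    n_nuclei = np.full((rows, cols), np.nan)

    # nucleus centres on a regular sub-lattice, radius 1 px => disjoint disks
    per_side = px_per_square // 2 - 1
    if mode == "PNC" and nuclei_per_square > per_side**2:
        raise ValueError(
            f"cannot place {nuclei_per_square} disjoint nuclei in a "
            f"{px_per_square}px square (max {per_side ** 2})"
        )
    label = 0
    positive_flags = [False]  # index 0 = background
    for r in range(rows):
        for c in range(cols):
            if not grid.tumour_mask[r, c]:
                continue
            v = grid.values[r, c]
            y0, x0 = r * px_per_square, c * px_per_square
            if mode == "PNC":
                n = nuclei_per_square
                n_pos = int(round(v / 100.0 * n))
                expected[r, c] = 100.0 * n_pos / n
                n_nuclei[r, c] = n
                for k in range(n):
                    gy, gx = divmod(k, per_side)
                    cy = y0 + 1 + 2 * gy
                    cx = x0 + 1 + 2 * gx
                    label += 1
                    nuclei_labels[cy, cx] = label
                    positive_flags.append(k < n_pos)
                    if k < n_pos:
                        stain[cy, cx] = True
            else:
                n_px = px_per_square**2
                n_pos = int(round(v / 100.0 * n_px))
                expected[r, c] = 100.0 * n_pos / n_px
                block = np.zeros(n_px, dtype=bool)
                block[:n_pos] = True
                stain[y0 : y0 + px_per_square, x0 : x0 + px_per_square] = block.reshape(
                    px_per_square, px_per_square
                )
    expected_grid = MarkerGrid(
        marker=grid.marker,
        mode=mode,
        status=grid.status.copy(),
        area_fraction=grid.area_fraction.copy(),
        values=expected,
        n_nuclei=n_nuclei if mode == "PNC" else None,
    )
    return SlideImage(
        tumour_mask_px=tumour_px,
        nuclei_labels=nuclei_labels,
        nuclei_positive=np.asarray(positive_flags, dtype=bool),
        stain=stain,
        px_per_square=px_per_square,
        expected_grid=expected_grid,
        truth=truth,
    )


# --------------------------------------------------------------------------
# aligned panels and cohorts


def simulate_panel(
    cfg: GridSimConfig,
    tumour_id: str = "T01",
    subgroup: str = "pT1M0",
    markers=STUDY_MARKERS,
    noise_corr: float = 0.5,
    delta_scale: float = 1.0,
) -> tuple[TumourPanel, GridTruth]:
    """Simulate one tumour's aligned five-marker panel.

    All markers share one tumour mask (the alignment contract).  Noise is
    correlated across markers through a shared latent Gaussian field with
    weight ``noise_corr``, producing configurable inter-marker rank
    correlation.  Each marker's peripheral delta is scaled by
    ``delta_scale`` (set 0 for a null cohort).
    """
    rng = np.random.default_rng(cfg.seed)
    mask = _tumour_mask(cfg, rng)
    depth = layer_depths(mask)
    shared = rng.standard_normal(mask.shape)
    grids: dict[str, MarkerGrid] = {}
    truth = None
    a = np.sqrt(noise_corr)
    b = np.sqrt(1.0 - noise_corr)
    for name, baseline, delta, sd, vmax in markers:
        noiseless = np.where(
            mask,
            np.clip(baseline + delta_scale * delta * (depth == 1), 0.0, vmax),
            np.nan,
        )
        noise = sd * (a * shared + b * rng.standard_normal(mask.shape))
        values = np.where(mask, np.clip(noiseless + noise, 0.0, vmax), np.nan)
        grids[name] = MarkerGrid(
            marker=name,
            mode=default_mode(name),
            status=np.where(mask, SquareStatus.TUMOUR, SquareStatus.NONTUMOUR),
            area_fraction=mask.astype(float),
            values=values,
        )
        if truth is None:
            truth = GridTruth(layer_depth=depth, noiseless=noiseless)
    return TumourPanel(tumour_id=tumour_id, subgroup=subgroup, grids=grids), truth


def simulate_cohort(
    n_per_subgroup: int = 10,
    subgroups: tuple[str, ...] = ("pT1M0", "pT1M1", "pT3/4"),
    base_cfg: GridSimConfig = GridSimConfig(),
    seed: int = 0,
    **panel_kwargs,
) -> list[tuple[TumourPanel, GridTruth]]:
    """Simulate a study-style cohort: three prognostic subgroups of tumours,
    each with five aligned marker grids."""
    out = []
    i = 0
    for sg in subgroups:
        for _ in range(n_per_subgroup):
            cfg = replace(base_cfg, seed=seed * 100_003 + i)
            out.append(
                simulate_panel(cfg, tumour_id=f"T{i + 1:02d}", subgroup=sg, **panel_kwargs)
            )
            i += 1
    return out
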