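"""Virtual-grid containers for tile-based IHC quantification.

A whole-slide section is overlaid with a lattice of 1 mm^2 squares; each
square carries a tumour/non-tumour/mixed status, the fraction of its area
that is cancerous ("corrected area"), and a positivity value — % positive
nuclei (PNC markers) or % positive pixels (PPC markers).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SquareStatus",
    "MarkerGrid",
    "TumourPanel",
    "PNC_MARKERS",
    "PPC_MARKERS",
    "default_mode",
    "read_grid_tsv",
    "write_grid_tsv",
]

#: markers scored by positive nuclear count vs positive pixel count
PNC_MARKERS = ("HIF1A", "HIF2A", "KI67")
PPC_MARKERS = ("pmTOR", "pS6RP")


class SquareStatus(enum.IntEnum):
    NONTUMOUR = 0
    TUMOUR = 1
    MIXED = 2


def default_mode(marker: str) -> str:
    """Quantification mode conventionally used for a marker.

    HIF-1α, HIF-2α and Ki-67 are scored by positive nuclear count (PNC);
    phospho-mTOR and phospho-S6RP by positive pixel count (PPC).  Unknown
    markers default to PNC.
    """
    return "PPC" if marker in PPC_MARKERS else "PNC"


@dataclass
class MarkerGrid:
    """Lattice of grid squares for one section/marker.

    Attributes
    ----------
    marker : str
        Marker identifier (``HIF1A``, ``HIF2A``, ``pmTOR``, ``pS6RP``,
        ``KI67`` or user-defined).
    mode : str
        ``"PNC"`` or ``"PPC"``.
    status : ndarray of int8, shape (rows, cols)
        Per-square :class:`SquareStatus` code.
    area_fraction : ndarray of float
        Cancerous fraction of each square; 0 for non-tumour squares.
    values : ndarray of float
        % positivity in [0, 100]; NaN for non-tumour squares and for
        analysable squares flagged as unquantifiable (e.g. zero nuclei).
    n_nuclei : ndarray of float or None
        Nucleus count per square (PNC mode only); NaN where not counted.
    square_size_mm : float
        Physical edge length of one square (default 1 mm).
    """

    marker: str
    mode: str
    status: np.ndarray
    area_fraction: np.ndarray
    values: np.ndarray
    n_nuclei: np.ndarray | None = None
    square_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        self.area_fraction = np.asarray(self.area_fraction, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.status.shape == self.area_fraction.shape == self.values.shape):
            raise ValueError("status, area_fraction and values must share one shape")
        if self.mode not in ("PNC", "PPC"):
            raise ValueError(f"mode must be PNC or PPC, got {self.mode!r}")
        bad = np.isfinite(self.values) & ((self.values < 0) | (self.values > 100))
        if bad.any():
            raise ValueError("square values must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.status.shape

    @property
    def tumour_mask(self) -> np.ndarray:
        """Boolean lattice: squares containing cancerous tissue."""
        return self.status != SquareStatus.NONTUMOUR

    def analysed_values(self) -> np.ndarray:
        """Finite values of tumour/mixed squares, flattened."""
        v = self.values[self.tumour_mask]
        return v[np.isfinite(v)]

    def same_lattice(self, other: "MarkerGrid") -> bool:
        return self.shape == other.shape and np.array_equal(self.status, other.status)


@dataclass
class TumourPanel:
    """The aligned marker grids of one tumour plus its prognostic subgroup.

    All grids must share lattice dimensions and square statuses — the
    alignment contract for adjacent-section comparison.
    """

    tumour_id: str
    subgroup: str  # pT1M0 / pT1M1 / pT3/4
    grids: dict[str, MarkerGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.grids.values())
        for g in grids[1:]:
            if not grids[0].same_lattice(g):
                raise ValueError(
                    f"panel {self.tumour_id}: marker grids have mismatched lattices"
                )

    @property
    def markers(self) -> list[str]:
        return list(self.grids)

    def reference_grid(self) -> MarkerGrid:
        return next(iter(self.grids.values()))


def write_grid_tsv(grid: MarkerGrid, path: str | Path) -> None:
    """Write a grid as TSV with columns row, col, status, area_fraction, value."""
    rows, cols = grid.shape
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    df = pd.DataFrame(
        {
            "row": r.ravel(),
            "col": c.ravel(),
            "status": [SquareStatus(s).name.lower() for s in grid.status.ravel()],
            "area_fraction": grid.area_fraction.ravel(),
            "value": grid.values.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_grid_tsv(path: str | Path, marker: str = "", mode: str | None = None) -> MarkerGrid:
    """Read a grid TSV written by :func:`write_grid_tsv`."""
    df = pd.read_csv(path, sep="\t")
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    status = np.zeros((rows, cols), dtype=np.int8)
    area = np.zeros((rows, cols), dtype=float)
    values = np.full((rows, cols), np.nan)
    codes = {s.name.lower(): int(s) for s in SquareStatus}
    for rec in df.itertuples(index=False):
        status[rec.row, rec.col] = codes[rec.status]
        area[rec.row, rec.col] = rec.area_fraction
        values[rec.row, rec.col] = rec.value
    marker = marker or Path(path).stem
    return MarkerGrid(
        marker=marker,
        mode=mode or default_mode(marker),
        status=status,
        area_fraction=area,
        values=values,
    )
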