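"""Spatial quality control.

Rasterized UMI / barcode density maps over the flow-cell canvas, automatic
tissue-boundary detection on those rasters, and per-barcode summary metrics
(UMI count, gene count, mitochondrial fraction) of the kind usually shown as
violin plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.ndimage

from .sdge_io import SpatialMatrix

__all__ = [
    "DensityRaster",
    "TissueMask",
    "NoTissueError",
    "density_raster",
    "density_raster_from_points",
    "detect_tissue",
    "per_barcode_qc",
    "plot_density",
    "plot_qc_violin",
]

#: 4-connectivity structuring element (no diagonal bridges)
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class NoTissueError(ValueError):
    """No raster cell exceeds the tissue threshold."""


@dataclass
class DensityRaster:
    """2-D histogram of UMIs (or barcodes) over square raster cells.

    ``values[i, j]`` covers x in ``[origin_x + j*cell_size, origin_x + (j+1)*cell_size)``
    and the analogous y slab for row ``i`` (row index = y, column index = x).
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class TissueMask:
    """Largest connected component of above-threshold raster cells."""

    mask: np.ndarray  # same shape as the raster
    bbox_cells: tuple[int, int, int, int]  # (row_min, row_max, col_min, col_max), half-open
    raster: DensityRaster
    threshold: float

    @property
    def area(self) -> float:
        """Masked area in squared length units."""
        return float(self.mask.sum()) * self.raster.cell_size**2

    def world_rect(self) -> tuple[float, float, float, float]:
        """Bounding rectangle ``(xmin, xmax, ymin, ymax)`` in length units."""
        r0, r1, c0, c1 = self.bbox_cells
        ox, oy = self.raster.origin
        cs = self.raster.cell_size
        return (ox + c0 * cs, ox + c1 * cs, oy + r0 * cs, oy + r1 * cs)


def density_raster_from_points(
    coords: np.ndarray,
    weights: np.ndarray | None,
    cell_size: float,
    origin: tuple[float, float] | None = None,
) -> DensityRaster:
    """Accumulate point weights into square raster cells by the floor rule
    ``index = floor((coord - origin) / cell_size)``."""
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("coords must be a non-empty (n, 2) array")
    if origin is None:
        origin = (float(coords[:, 0].min()), float(coords[:, 1].min()))
    ix = np.floor((coords[:, 0] - origin[0]) / cell_size).astype(int)
    iy = np.floor((coords[:, 1] - origin[1]) / cell_size).astype(int)
    if ix.min() < 0 or iy.min() < 0:
        raise ValueError("a coordinate lies before the raster origin")
    values = np.zeros((iy.max() + 1, ix.max() + 1), dtype=float)
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, dtype=float)
    np.add.at(values, (iy, ix), w)
    return DensityRaster(origin=origin, cell_size=float(cell_size), values=values)


def density_raster(
    matrix: SpatialMatrix,
    cell_size: float,
    statistic: str = "umi",
    origin: tuple[float, float] | None = None,
    layer: str | None = None,
) -> DensityRaster:
    """Rasterize a SpatialMatrix: each barcode contributes its UMI total
    (``statistic="umi"``) or 1 (``statistic="barcode"``) to exactly one cell."""
    if statistic == "umi":
        weights = np.asarray(matrix.layer(layer).sum(axis=1)).ravel()
    elif statistic == "barcode":
        weights = None
    else:
        raise ValueError(f"unknown statistic: {statistic!r} (use 'umi' or 'barcode')")
    return density_raster_from_points(matrix.coords, weights, cell_size, origin)


def detect_tissue(
    raster: DensityRaster,
    method: str = "quantile",
    q: float = 0.5,
    threshold: float | None = None,
) -> TissueMask:
    """Detect the tissue region of a density raster.

    A cell passes if its density is >= a threshold — by default the ``q``
    quantile of *nonzero* cells (``method="quantile"``), or Otsu's threshold
    over all cells (``method="otsu"``), or an explicit ``threshold``.  The
    largest 4-connected component of passing cells is the tissue; its bounding
    rectangle is reported in raster cell indices (half-open).
    """
    values = raster.values
    if values.size == 0 or not (values > 0).any():
        raise NoTissueError("density raster is empty: no tissue to detect")
    if threshold is None:
        if method == "quantile":
            threshold = float(np.quantile(values[values > 0], q))
        elif method == "otsu":
            from skimage.filters import threshold_otsu

            threshold = float(threshold_otsu(values))
        else:
            raise ValueError(f"unknown method: {method!r}")
    if threshold > values.max():
        raise NoTissueError(
            f"threshold {threshold} exceeds maximum density {values.max()}: no tissue"
        )
    binary = values >= threshold
    labels, n_components = scipy.ndimage.label(binary, structure=_CROSS)
    if n_components == 0:
        raise NoTissueError("no raster cell reaches the tissue threshold")
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)
    return TissueMask(mask=mask, bbox_cells=bbox, raster=raster, threshold=float(threshold))


def per_barcode_qc(
    matrix: SpatialMatrix,
    mito_patterns: Sequence[str] = ("mt-",),
    layer: str | None = None,
) -> pd.DataFrame:
    """Per-barcode UMI count, expressed-gene count and mitochondrial fraction.

    Mitochondrial genes are identified by case-insensitive gene-name prefix
    match against ``mito_patterns``.  The fraction uses
    ``mito_umis / max(umi_count, 1)`` so empty barcodes yield 0.
    """
    X = matrix.layer(layer)
    umi = np.asarray(X.sum(axis=1)).ravel()
    gene_count = X.getnnz(axis=1)
    names = matrix.genes["gene_name"].str.lower()
    is_mito = np.zeros(matrix.n_genes, dtype=bool)
    for pat in mito_patterns:
        is_mito |= names.str.startswith(pat.lower()).to_numpy()
    mito_umi = (
        np.asarray(X[:, np.flatnonzero(is_mito)].sum(axis=1)).ravel()
        if is_mito.any()
        else np.zeros_like(umi)
    )
    return pd.DataFrame(
        {
            "umi_count": umi.astype(int),
            "gene_count": gene_count.astype(int),
            "mito_fraction": mito_umi / np.maximum(umi, 1),
        },
        index=pd.Index(matrix.barcodes, name="barcode"),
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_density(raster: DensityRaster, path: str | Path | None = None, cmap: str = "viridis"):
    """Heatmap of a density raster; writes a PNG when ``path`` is given."""
    fig, ax = plt.subplots(figsize=(6, 6))
    h, w = raster.values.shape
    ox, oy = raster.origin
    cs = raster.cell_size
    im = ax.imshow(
        raster.values,
        origin="upper",
        extent=(ox, ox + w * cs, oy + h * cs, oy),
        cmap=cmap,
        interpolation="nearest",
    )
    fig.colorbar(im, ax=ax, label="density per cell")
    ax.set_xlabel("x (length units)")
    ax.set_ylabel("y (length units)")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_qc_violin(qc: pd.DataFrame, path: str | Path | None = None):
    """Violin summary of per-barcode QC metrics."""
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.5))
    for ax, col in zip(axes, ("umi_count", "gene_count", "mito_fraction")):
        data = qc[col].to_numpy(dtype=float)
        if np.ptp(data) > 0:
            ax.violinplot(data, showmedians=True)
        else:  # degenerate (constant) metric: violin KDE undefined
            ax.axhline(data[0] if len(data) else 0.0, color="C0")
        ax.set_title(col)
        ax.set_xticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
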