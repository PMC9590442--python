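"""Spatial aggregation of barcode-level counts.

Submicrometer platforms capture too few UMIs per barcode to cluster barcodes
directly, so counts are pooled over square regions.  Two tracks are provided:

* **Simple grid** — non-overlapping square bins of side ``side`` (step ==
  side).  Coarse but statistically well-powered; feeds reference clustering.
* **Sliding window (MSSW)** — overlapping square windows of side ``side``
  advanced by ``step < side`` on both axes.  An interior barcode belongs to
  exactly ``(side/step)**2`` windows, so the lattice of window centers is
  ``(side/step)**2``-fold denser per unit area than the simple grid at the
  same side (25x for side 10 µm, step 2 µm) while each window still pools a
  full ``side x side`` region's transcripts.

Both tracks use the half-open membership rule ``w <= coord < w + side`` on
each axis, so within one track no barcode is ever double-counted by
overlapping *grid cells* (windows overlap by design).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .sdge_io import SpatialMatrix, read_mtx_dir, write_mtx_dir

__all__ = [
    "BinSpec",
    "BinnedMatrix",
    "EmptyBinningError",
    "simple_grid_bin",
    "sliding_window_bin",
    "multiscale_bin",
    "binned_to_spatial",
    "save_binned",
    "load_binned",
]


class EmptyBinningError(ValueError):
    """A binning filter removed every bin."""


@dataclass(frozen=True)
class BinSpec:
    """Square-bin geometry.

    ``side`` is the bin/window edge length, ``step`` the anchor spacing
    (``step == side`` gives a non-overlapping grid; ``step < side`` a sliding
    window).  ``side`` must be an integer multiple of ``step`` so that every
    interior barcode falls in exactly ``(side/step)**2`` windows.  ``anchor``
    is the (x0, y0) origin of the bin lattice; ``None`` defers to the data (or
    tissue) minimum corner at binning time.
    """

    side: float
    step: float | None = None
    anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("side must be positive")
        step = self.side if self.step is None else self.step
        if step <= 0 or step > self.side:
            raise ValueError(f"step must satisfy 0 < step <= side, got step={step}, side={self.side}")
        ratio = self.side / step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"side ({self.side}) must be an integer multiple of step ({step})"
            )
        object.__setattr__(self, "step", float(step))
        object.__setattr__(self, "side", float(self.side))

    @property
    def ratio(self) -> int:
        """Windows per axis sharing an interior barcode: ``side / step``."""
        return int(round(self.side / self.step))

    @property
    def is_grid(self) -> bool:
        return self.ratio == 1

    def name(self) -> str:
        return f"side{self.side:g}_step{self.step:g}"


@dataclass
class BinnedMatrix:
    """Aggregated bin x gene counts with bin geometry.

    ``bin_ids`` encode the bin's lower-left corner and side
    (``"x{wx}_y{wy}_s{side}"``) for deterministic joins across runs.
    """

    bin_ids: np.ndarray
    centers: np.ndarray  # (n_bins, 2)
    spec: BinSpec
    counts: sp.csr_matrix  # bins x genes
    n_barcodes_per_bin: np.ndarray
    genes: pd.DataFrame
    source_layer: str

    @property
    def n_bins(self) -> int:
        return len(self.bin_ids)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def equals(self, other: "BinnedMatrix") -> bool:
        return (
            np.array_equal(self.bin_ids, other.bin_ids)
            and np.array_equal(self.centers, other.centers)
            and np.array_equal(self.n_barcodes_per_bin, other.n_barcodes_per_bin)
            and (self.counts != other.counts).nnz == 0
        )


def _resolve_anchor(matrix: SpatialMatrix, spec: BinSpec) -> tuple[float, float]:
    if spec.anchor is not None:
        return spec.anchor
    return float(matrix.coords[:, 0].min()), float(matrix.coords[:, 1].min())


def _make_ids(wx: np.ndarray, wy: np.ndarray, side: float) -> np.ndarray:
    return np.array([f"x{x:g}_y{y:g}_s{side:g}" for x, y in zip(wx, wy)], dtype=object)


def _assemble(
    ii: np.ndarray,
    jj: np.ndarray,
    counts: sp.csr_matrix,
    n_barcodes: np.ndarray,
    spec: BinSpec,
    anchor: tuple[float, float],
    genes: pd.DataFrame,
    layer: str,
    min_umi: int,
    what: str,
) -> BinnedMatrix:
    """Order bins by (y, x) index, apply the min-UMI filter, build the result."""
    order = np.lexsort((ii, jj))
    ii, jj = ii[order], jj[order]
    counts = sp.csr_matrix(counts[order])
    n_barcodes = n_barcodes[order]

    totals = np.asarray(counts.sum(axis=1)).ravel()
    keep = totals >= min_umi
    if not keep.any():
        raise EmptyBinningError(
            f"min_umi={min_umi} removed every {what} (max bin total was {int(totals.max())})"
        )
    if not keep.all():
        idx = np.flatnonzero(keep)
        ii, jj, n_barcodes = ii[idx], jj[idx], n_barcodes[idx]
        counts = sp.csr_matrix(counts[idx])

    x0, y0 = anchor
    wx = x0 + ii * spec.step
    wy = y0 + jj * spec.step
    centers = np.column_stack([wx + spec.side / 2, wy + spec.side / 2])
    return BinnedMatrix(
        bin_ids=_make_ids(wx, wy, spec.side),
        centers=centers,
        spec=replace(spec, anchor=anchor),
        counts=counts.astype(np.int64),
        n_barcodes_per_bin=n_barcodes.astype(int),
        genes=genes.copy(),
        source_layer=layer,
    )


def simple_grid_bin(
    matrix: SpatialMatrix,
    spec: BinSpec,
    min_umi: int = 0,
    layer: str | None = None,
) -> BinnedMatrix:
    """Aggregate counts over a non-overlapping square grid.

    Barcode ``b`` joins the bin indexed ``(floor((x - x0)/side),
    floor((y - y0)/side))``; bin counts are the sums over member barcodes.
    Bins containing no barcode are absent; bins with total UMI below
    ``min_umi`` are dropped (error if nothing survives).  With ``min_umi=0``
    total UMIs are conserved exactly.
    """
    if not spec.is_grid:
        raise ValueError("simple_grid_bin requires step == side (use sliding_window_bin)")
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    layer_name = matrix.default_layer if layer is None else layer
    X = matrix.layer(layer_name)
    anchor = _resolve_anchor(matrix, spec)
    ix = np.floor((matrix.coords[:, 0] - anchor[0]) / spec.side).astype(np.int64)
    iy = np.floor((matrix.coords[:, 1] - anchor[1]) / spec.side).astype(np.int64)

    keys = np.stack([ix, iy], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    assign = sp.csr_matrix(
        (np.ones(len(ix), dtype=np.int64), (inverse, np.arange(len(ix)))),
        shape=(len(uniq), len(ix)),
    )
    counts = sp.csr_matrix(assign @ X)
    n_barcodes = np.asarray(assign.sum(axis=1)).ravel()
    return _assemble(
        uniq[:, 0], uniq[:, 1], counts, n_barcodes, spec, anchor,
        matrix.genes, layer_name, min_umi, "grid bin",
    )


def sliding_window_bin(
    matrix: SpatialMatrix,
    spec: BinSpec,
    min_umi: int = 0,
    layer: str | None = None,
) -> BinnedMatrix:
    """Aggregate counts over overlapping sliding windows (MSSW).

    Windows are anchored at ``(x0 + i*step, y0 + j*step)`` for all integer
    ``i, j``; a window's counts sum over barcodes with ``x in [wx, wx+side)``
    and ``y in [wy, wy+side)``.  Only windows containing at least one barcode
    are materialized.  With ``step == side`` the output is identical to
    :func:`simple_grid_bin`.

    Implementation: barcodes are first pooled into the fine ``step``-sized
    lattice; each window is then the exact sum of its ``ratio x ratio`` block
    of fine cells, applied as one sparse matrix product.
    """
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    layer_name = matrix.default_layer if layer is None else layer
    X = matrix.layer(layer_name)
    anchor = _resolve_anchor(matrix, spec)
    r = spec.ratio

    fx = np.floor((matrix.coords[:, 0] - anchor[0]) / spec.step).astype(np.int64)
    fy = np.floor((matrix.coords[:, 1] - anchor[1]) / spec.step).astype(np.int64)
    fine_keys = np.stack([fx, fy], axis=1)
    fine, inverse = np.unique(fine_keys, axis=0, return_inverse=True)
    n_fine = len(fine)
    fine_assign = sp.csr_matrix(
        (np.ones(len(fx), dtype=np.int64), (inverse, np.arange(len(fx)))),
        shape=(n_fine, len(fx)),
    )
    fine_counts = sp.csr_matrix(fine_assign @ X)
    fine_barcodes = np.asarray(fine_assign.sum(axis=1)).ravel()

    # candidate windows: every (i, j) such that some occupied fine cell lies in
    # the window's r x r block, i.e. offsets 0..r-1 back from each occupied cell
    offs = np.arange(r, dtype=np.int64)
    dx, dy = np.meshgrid(offs, offs, indexing="ij")
    dx, dy = dx.ravel(), dy.ravel()
    cand_i = (fine[:, 0][:, None] - dx[None, :]).ravel()
    cand_j = (fine[:, 1][:, None] - dy[None, :]).ravel()
    windows = np.unique(np.stack([cand_i, cand_j], axis=1), axis=0)
    n_win = len(windows)

    # membership matrix W (windows x fine cells): W[w, f] = 1 iff fine cell f
    # lies in window w's block; counts = W @ fine_counts
    big = np.int64(1) << 32
    fine_code = fine[:, 0] * big + fine[:, 1]
    code_order = np.argsort(fine_code)
    sorted_codes = fine_code[code_order]
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for a, b in zip(dx, dy):
        target = (windows[:, 0] + a) * big + (windows[:, 1] + b)
        pos = np.searchsorted(sorted_codes, target)
        pos_clip = np.minimum(pos, n_fine - 1)
        hit = sorted_codes[pos_clip] == target
        rows.append(np.flatnonzero(hit))
        cols.append(code_order[pos_clip[hit]])
    W = sp.csr_matrix(
        (
            np.ones(sum(len(x) for x in rows), dtype=np.int64),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(n_win, n_fine),
    )
    counts = sp.csr_matrix(W @ fine_counts)
    n_barcodes = np.asarray(W @ fine_barcodes[:, None]).ravel()

    occupied = n_barcodes > 0  # true by construction, kept as a guard
    return _assemble(
        windows[occupied, 0], windows[occupied, 1],
        sp.csr_matrix(counts[np.flatnonzero(occupied)]), n_barcodes[occupied],
        spec, anchor, matrix.genes, layer_name, min_umi, "window",
    )


def multiscale_bin(
    matrix: SpatialMatrix,
    specs: Sequence[BinSpec],
    min_umi: int | Sequence[int] = 0,
    layer: str | None = None,
) -> dict[str, BinnedMatrix]:
    """Bin at several scales; returns ``{spec.name(): BinnedMatrix}``.

    ``min_umi`` may be a single value or one per spec.
    """
    if len(specs) == 0:
        raise ValueError("at least one BinSpec is required")
    thresholds = (
        list(min_umi) if isinstance(min_umi, Sequence) and not isinstance(min_umi, (str, bytes))
        else [min_umi] * len(specs)
    )
    if len(thresholds) != len(specs):
        raise ValueError("min_umi must be scalar or one value per spec")
    out: dict[str, BinnedMatrix] = {}
    for spec, thr in zip(specs, thresholds):
        fn = simple_grid_bin if spec.is_grid else sliding_window_bin
        out[spec.name()] = fn(matrix, spec, min_umi=int(thr), layer=layer)
    return out


# ---------------------------------------------------------------------------
# persistence: a BinnedMatrix round-trips through the same MTX dialect as the
# barcode-level matrices, plus a bins table and a small geometry JSON
# ---------------------------------------------------------------------------

def binned_to_spatial(binned: BinnedMatrix) -> SpatialMatrix:
    """View a BinnedMatrix as a SpatialMatrix (bins as pseudo-barcodes at
    their centers), e.g. for MTX export or rendering."""
    return SpatialMatrix(
        barcodes=binned.bin_ids,
        genes=binned.genes.copy(),
        coords=binned.centers,
        layers={binned.source_layer: binned.counts},
        default_layer=binned.source_layer,
    )


def save_binned(binned: BinnedMatrix, path: str | Path) -> Path:
    path = Path(path)
    write_mtx_dir(binned_to_spatial(binned), path)
    pd.DataFrame(
        {
            "bin_id": binned.bin_ids,
            "x": binned.centers[:, 0],
            "y": binned.centers[:, 1],
            "n_barcodes": binned.n_barcodes_per_bin,
        }
    ).to_csv(path / "bins.tsv", sep="\t", index=False, float_format="%.17g")
    (path / "binspec.json").write_text(
        json.dumps(
            {
                "side": binned.spec.side,
                "step": binned.spec.step,
                "anchor": list(binned.spec.anchor) if binned.spec.anchor else None,
                "source_layer": binned.source_layer,
            }
        )
    )
    return path


def load_binned(path: str | Path) -> BinnedMatrix:
    path = Path(path)
    meta = json.loads((path / "binspec.json").read_text())
    spec = BinSpec(
        side=meta["side"],
        step=meta["step"],
        anchor=tuple(meta["anchor"]) if meta["anchor"] else None,
    )
    sm = read_mtx_dir(path, default_layer=meta["source_layer"])
    bins = pd.read_csv(path / "bins.tsv", sep="\t").set_index("bin_id")
    n_barcodes = bins.loc[list(sm.barcodes), "n_barcodes"].to_numpy()
    return BinnedMatrix(
        bin_ids=sm.barcodes,
        centers=sm.coords,
        spec=spec,
        counts=sm.X,
        n_barcodes_per_bin=n_barcodes,
        genes=sm.genes,
        source_layer=meta["source_layer"],
    )
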