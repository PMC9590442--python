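"""Spatial digital gene expression (DGE) I/O.

A spatial DGE is a sparse barcode x gene UMI count matrix with one spatial
coordinate per barcode, stored on disk as 10x-Genomics-style MatrixMarket
triples (``matrix.mtx`` with genes as rows and barcodes as columns, 1-based
indices, plus ``barcodes.tsv`` / ``features.tsv``) and a ``coordinates.tsv``
sidecar.  Additional count layers — exonic-only (Gene), exonic+intronic
(GeneFull) and spliced/unspliced/ambiguous read classes — live in sibling
subdirectories holding their own ``matrix.mtx``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["SpatialMatrix", "FormatError", "EmptySelectionError", "read_mtx_dir", "write_mtx_dir", "subset"]

#: layer subdirectories discovered automatically on read
KNOWN_EXTRA_LAYERS = ("GeneFull", "spliced", "unspliced", "ambiguous")


class FormatError(ValueError):
    """An on-disk matrix directory is inconsistent or incomplete."""


class EmptySelectionError(ValueError):
    """A subset operation selected no barcodes."""


@dataclass
class SpatialMatrix:
    """In-memory spatial DGE: barcodes x genes counts with coordinates.

    Attributes
    ----------
    barcodes
        Ordered barcode identifiers (length ``n``).
    genes
        DataFrame with columns ``gene_id`` and ``gene_name`` (length ``g``).
    coords
        ``(n, 2)`` float array of (x, y) positions in length units.
    layers
        Mapping layer name -> ``(n, g)`` sparse CSR matrix of non-negative
        integer counts.  All layers share shape and orderings.
    default_layer
        The layer operations use when none is named (usually ``"Gene"``).
    """

    barcodes: np.ndarray
    genes: pd.DataFrame
    coords: np.ndarray
    layers: dict[str, sp.csr_matrix]
    default_layer: str = "Gene"

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = len(self.barcodes), len(self.genes)
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must have shape ({n}, 2), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.default_layer not in self.layers:
            raise ValueError(f"default layer {self.default_layer!r} missing from layers")
        if not {"gene_id", "gene_name"}.issubset(self.genes.columns):
            raise ValueError("genes must have columns gene_id and gene_name")
        for name, mat in self.layers.items():
            if mat.shape != (n, g):
                raise ValueError(f"layer {name!r} has shape {mat.shape}, expected ({n}, {g})")
            if mat.nnz and mat.data.min() < 0:
                raise ValueError(f"layer {name!r} contains negative counts")
            self.layers[name] = sp.csr_matrix(mat)

    # -- convenience ---------------------------------------------------------
    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def X(self) -> sp.csr_matrix:
        return self.layers[self.default_layer]

    def layer(self, name: str | None = None) -> sp.csr_matrix:
        return self.layers[self.default_layer if name is None else name]

    def total_counts(self, layer: str | None = None) -> int:
        return int(self.layer(layer).sum())

    def equals(self, other: "SpatialMatrix") -> bool:
        """Exact equality of barcodes, genes, coordinates and every layer."""
        if (
            not np.array_equal(self.barcodes, other.barcodes)
            or set(self.layers) != set(other.layers)
            or self.default_layer != other.default_layer
            or not self.genes[["gene_id", "gene_name"]].equals(
                other.genes[["gene_id", "gene_name"]].set_axis(self.genes.index)
            )
            or not np.array_equal(self.coords, other.coords)
        ):
            return False
        return all((self.layers[k] != other.layers[k]).nnz == 0 for k in self.layers)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _find(path: Path, stem: str) -> Path | None:
    for candidate in (path / stem, path / (stem + ".gz")):
        if candidate.exists():
            return candidate
    return None


def _read_tsv(path: Path, **kwargs) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def _read_matrix(path: Path) -> sp.csr_matrix:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    return sp.csr_matrix(mat)


def _decode_barcode_names(barcodes: Sequence[str], scale: float) -> dict[str, tuple[float, float]]:
    """Decode ``lane_tile_x_y`` barcode names into coordinates (x*scale, y*scale)."""
    out: dict[str, tuple[float, float]] = {}
    for b in barcodes:
        parts = str(b).split("_")
        if len(parts) != 4:
            continue
        try:
            _, _, x, y = (int(p) for p in parts)
        except ValueError:
            continue
        out[b] = (x * scale, y * scale)
    return out


def read_mtx_dir(
    path: str | Path,
    coords_source: str | Path | None = None,
    coord_scale: float = 1.0,
    default_layer: str = "Gene",
) -> SpatialMatrix:
    """Read a 10x-style MTX directory (plus sibling layers) into a SpatialMatrix.

    Coordinate precedence: an explicit ``coords_source`` TSV, else a
    ``coordinates.tsv[.gz]`` sidecar in ``path``, else decoding barcode names
    of the ``lane_tile_x_y`` dialect scaled by ``coord_scale``.  Barcodes
    without a coordinate are dropped (logged).
    """
    path = Path(path)
    mtx = _find(path, "matrix.mtx")
    bc_path = _find(path, "barcodes.tsv")
    ft_path = _find(path, "features.tsv") or _find(path, "genes.tsv")
    if mtx is None or bc_path is None or ft_path is None:
        raise FormatError(f"{path}: need matrix.mtx, barcodes.tsv and features.tsv")

    barcodes = _read_tsv(bc_path, header=None)[0].astype(str).to_numpy(dtype=object)
    features = _read_tsv(ft_path, header=None)
    genes = pd.DataFrame(
        {
            "gene_id": features[0].astype(str),
            "gene_name": (features[1] if features.shape[1] > 1 else features[0]).astype(str),
        }
    )

    main = _read_matrix(mtx)  # genes x barcodes on disk
    if main.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{path}: matrix.mtx declares shape {main.shape} but features/barcodes "
            f"files have {len(genes)}/{len(barcodes)} entries"
        )
    layers = {default_layer: sp.csr_matrix(main.T.astype(np.int64))}

    for name in KNOWN_EXTRA_LAYERS:
        sub = path / name
        sub_mtx = _find(sub, "matrix.mtx") if sub.is_dir() else None
        if sub_mtx is None:
            continue
        mat = _read_matrix(sub_mtx)
        if mat.shape != (len(genes), len(barcodes)):
            raise FormatError(f"{sub}: layer shape {mat.shape} disagrees with main matrix")
        layers[name] = sp.csr_matrix(mat.T.astype(np.int64))

    # coordinates
    coord_map: dict[str, tuple[float, float]]
    src = Path(coords_source) if coords_source is not None else _find(path, "coordinates.tsv")
    if src is not None:
        df = _read_tsv(src, float_precision="round_trip")
        if not {"barcode", "x", "y"}.issubset(df.columns):
            raise FormatError(f"{src}: coordinates table needs columns barcode, x, y")
        coord_map = {
            str(b): (float(x), float(y)) for b, x, y in zip(df["barcode"], df["x"], df["y"])
        }
    else:
        coord_map = _decode_barcode_names(barcodes, coord_scale)
        if not coord_map:
            raise FormatError(
                f"{path}: no coordinate source (no sidecar TSV and barcode names "
                "do not decode as lane_tile_x_y)"
            )

    have = np.array([b in coord_map for b in barcodes], dtype=bool)
    n_dropped = int((~have).sum())
    if n_dropped:
        logger.info("%s: dropped %d barcode(s) lacking coordinates", path, n_dropped)
    if not have.any():
        raise FormatError(f"{path}: no barcode has a coordinate")
    barcodes = barcodes[have]
    layers = {k: sp.csr_matrix(v[np.flatnonzero(have)]) for k, v in layers.items()}
    coords = np.array([coord_map[b] for b in barcodes], dtype=float)

    return SpatialMatrix(
        barcodes=barcodes, genes=genes, coords=coords, layers=layers, default_layer=default_layer
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _write_triple(mat_barcodes_by_genes: sp.spmatrix, genes: pd.DataFrame, barcodes: np.ndarray, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    disk = sp.csr_matrix(mat_barcodes_by_genes.T)  # genes x barcodes, row-major entry order
    disk.sort_indices()
    scipy.io.mmwrite(str(path / "matrix.mtx"), disk.astype(np.int64), field="integer")
    with open(path / "barcodes.tsv", "w") as fh:
        fh.writelines(str(b) + "\n" for b in barcodes)
    with open(path / "features.tsv", "w") as fh:
        for gid, gname in zip(genes["gene_id"], genes["gene_name"]):
            fh.write(f"{gid}\t{gname}\tGene Expression\n")


def write_mtx_dir(matrix: SpatialMatrix, path: str | Path) -> Path:
    """Write a SpatialMatrix as 10x-style MTX triples.

    The default layer goes in ``path`` itself; every other layer goes in a
    subdirectory named after it.  Coordinates are written to
    ``coordinates.tsv``.  Entry order is deterministic (gene-major).
    """
    path = Path(path)
    _write_triple(matrix.X, matrix.genes, matrix.barcodes, path)
    with open(path / "coordinates.tsv", "w") as fh:
        fh.write("barcode\tx\ty\n")
        for b, (x, y) in zip(matrix.barcodes, matrix.coords):
            fh.write(f"{b}\t{x:.17g}\t{y:.17g}\n")
    for name, layer in matrix.layers.items():
        if name == matrix.default_layer:
            continue
        _write_triple(layer, matrix.genes, matrix.barcodes, path / name)
    return path


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------

def subset(
    matrix: SpatialMatrix,
    barcode_mask: np.ndarray | Sequence[bool] | None = None,
    region: tuple[float, float, float, float] | None = None,
) -> SpatialMatrix:
    """Subset barcodes by boolean mask or by a half-open region rectangle.

    ``region`` is ``(xmin, xmax, ymin, ymax)`` with membership
    ``xmin <= x < xmax`` and ``ymin <= y < ymax`` (half-open on both axes, so
    tiled rectangles never double-count).  Exactly one selector must be given.
    """
    if (barcode_mask is None) == (region is None):
        raise ValueError("give exactly one of barcode_mask or region")
    if region is not None:
        xmin, xmax, ymin, ymax = region
        x, y = matrix.coords[:, 0], matrix.coords[:, 1]
        mask = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    else:
        mask = np.asarray(barcode_mask, dtype=bool)
        if mask.shape != (matrix.n_barcodes,):
            raise ValueError(
                f"mask length {mask.shape} does not match barcode count {matrix.n_barcodes}"
            )
    if not mask.any():
        raise EmptySelectionError("selection contains no barcodes")
    idx = np.flatnonzero(mask)
    return SpatialMatrix(
        barcodes=matrix.barcodes[idx],
        genes=matrix.genes.copy(),
        coords=matrix.coords[idx],
        layers={k: sp.csr_matrix(v[idx]) for k, v in matrix.layers.items()},
        default_layer=matrix.default_layer,
    )
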