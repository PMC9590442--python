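"""Rendering: RGB geneset images, cluster maps and UMAP scatter plots.

The RGB renderer paints raw spatial expression at up to sub-micrometre pixel
size: each colour channel carries the summed UMIs of an arbitrary marker gene
set (optionally from a specific count layer, e.g. spliced vs unspliced), so a
single image can contrast cell types or subcellular compartments without any
aggregation or smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np
from PIL import Image

from .binning import BinnedMatrix
from .sdge_io import SpatialMatrix

__all__ = ["GenesetRGB", "RGBRender", "render_rgb", "render_cluster_map", "plot_umap"]

_CHANNELS = ("red", "green", "blue")


@dataclass
class GenesetRGB:
    """Per-channel gene sets and rendering parameters.

    ``layer_per_channel`` maps a channel name to the count layer it reads
    (default: the matrix's default layer).  ``scaling_quantile`` is the
    quantile of nonzero raw intensities used as the per-channel clipping
    value — robust against single hot pixels.
    """

    red: Sequence[str] = ()
    green: Sequence[str] = ()
    blue: Sequence[str] = ()
    layer_per_channel: Mapping[str, str] = field(default_factory=dict)
    pixel_size: float = 1.0
    scaling_quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 < self.scaling_quantile <= 1:
            raise ValueError("scaling_quantile must be in (0, 1]")

    def genes(self, channel: str) -> Sequence[str]:
        return getattr(self, channel)


@dataclass
class RGBRender:
    """Rasterized RGB image with its raw intensities and scaling metadata."""

    image: np.ndarray  # H x W x 3, intensities in [0, 1]
    raw: np.ndarray  # H x W x 3, summed UMIs before scaling
    origin: tuple[float, float]
    pixel_size: float
    channel_max_used: tuple[float, float, float]

    def to_png(self, path: str | Path) -> Path:
        path = Path(path)
        Image.fromarray((self.image * 255 + 0.5).astype(np.uint8), mode="RGB").save(path)
        return path

    def raw_to_tsv(self, path_prefix: str | Path) -> list[Path]:
        """Dump per-channel raw intensity arrays as TSV for exact inspection."""
        out = []
        for c, name in enumerate(_CHANNELS):
            p = Path(f"{path_prefix}.{name}.tsv")
            np.savetxt(p, self.raw[:, :, c], delimiter="\t", fmt="%.17g")
            out.append(p)
        return out


def render_rgb(
    matrix: SpatialMatrix,
    spec: GenesetRGB,
    region: tuple[float, float, float, float] | None = None,
) -> RGBRender:
    """Render marker-geneset expression as an RGB image.

    Per pixel and channel, the raw intensity is the summed UMIs of that
    channel's genes (from that channel's layer) over barcodes whose
    coordinates fall in the pixel (half-open floor rule, matching binning).
    Displayed intensity is ``min(raw / clip, 1)`` with ``clip`` the
    ``scaling_quantile`` quantile of nonzero raw values of that channel
    (falling back to 1 when a channel is everywhere zero).

    ``region`` is a half-open ``(xmin, xmax, ymin, ymax)`` rectangle; by
    default the data's bounding box.  Unknown gene names warn and are
    skipped; an entirely empty geneset (all three channels) is an error.
    """
    if not any(len(spec.genes(c)) for c in _CHANNELS):
        raise ValueError("all three channels are empty: nothing to render")
    if region is None:
        x, y = matrix.coords[:, 0], matrix.coords[:, 1]
        region = (float(x.min()), float(x.max()) + spec.pixel_size, float(y.min()), float(y.max()) + spec.pixel_size)
    xmin, xmax, ymin, ymax = region
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"empty region: {region}")
    W = int(np.ceil((xmax - xmin) / spec.pixel_size))
    H = int(np.ceil((ymax - ymin) / spec.pixel_size))

    x, y = matrix.coords[:, 0], matrix.coords[:, 1]
    inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    if not inside.any():
        raise ValueError("region contains no barcodes")
    ix = np.floor((x[inside] - xmin) / spec.pixel_size).astype(int)
    iy = np.floor((y[inside] - ymin) / spec.pixel_size).astype(int)

    name_index: dict[str, list[int]] = {}
    for j, name in enumerate(matrix.genes["gene_name"]):
        name_index.setdefault(name, []).append(j)

    raw = np.zeros((H, W, 3))
    maxima = []
    for c, channel in enumerate(_CHANNELS):
        genes = spec.genes(channel)
        cols: list[int] = []
        for g in genes:
            if g in name_index:
                cols.extend(name_index[g])
            else:
                warnings.warn(f"channel {channel!r}: unknown gene {g!r} skipped", stacklevel=2)
        if cols:
            layer = spec.layer_per_channel.get(channel, matrix.default_layer)
            per_barcode = np.asarray(
                matrix.layers[layer][:, cols].sum(axis=1)
            ).ravel()[inside]
            np.add.at(raw[:, :, c], (iy, ix), per_barcode)
        nonzero = raw[:, :, c][raw[:, :, c] > 0]
        clip = float(np.quantile(nonzero, spec.scaling_quantile)) if nonzero.size else 1.0
        maxima.append(clip)
    image = np.minimum(raw / np.array(maxima)[None, None, :], 1.0)
    return RGBRender(
        image=image,
        raw=raw,
        origin=(xmin, ymin),
        pixel_size=spec.pixel_size,
        channel_max_used=tuple(maxima),
    )


def _default_palette(labels: np.ndarray) -> dict:
    uniq = sorted(set(labels.tolist()))
    cmap = plt.get_cmap("tab20" if len(uniq) > 10 else "tab10")
    return {lab: np.array(cmap(i % cmap.N)[:3]) for i, lab in enumerate(uniq)}


def render_cluster_map(
    binned: BinnedMatrix,
    labels: np.ndarray | Mapping,
    pixel_size: float = 1.0,
    palette: Mapping | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Paint cluster labels as an image.

    Each bin is painted as a square of side ``spec.step`` centered on the bin
    center, so sliding-window maps render at *step* (not side) granularity.
    Where painted squares overlap, the nearest bin center wins.  Returns the
    ``H x W x 3`` image and its (x, y) origin.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if isinstance(labels, Mapping):
        missing = [b for b in binned.bin_ids if b not in labels]
        if missing:
            raise ValueError(f"missing label for bin {missing[0]!r}")
        lab = np.array([labels[b] for b in binned.bin_ids])
    else:
        lab = np.asarray(labels)
        if len(lab) != binned.n_bins:
            raise ValueError(
                f"got {len(lab)} labels for {binned.n_bins} bins"
            )
    colors = dict(palette) if palette is not None else _default_palette(lab)
    for value in np.unique(lab):
        if value not in colors:
            raise ValueError(f"palette has no colour for label {value!r}")

    half = binned.spec.step / 2
    centers = binned.centers
    xmin, ymin = centers[:, 0].min() - half, centers[:, 1].min() - half
    xmax, ymax = centers[:, 0].max() + half, centers[:, 1].max() + half
    W = int(np.ceil((xmax - xmin) / pixel_size))
    H = int(np.ceil((ymax - ymin) / pixel_size))
    image = np.zeros((H, W, 3))
    best = np.full((H, W), np.inf)

    px = xmin + (np.arange(W) + 0.5) * pixel_size
    py = ymin + (np.arange(H) + 0.5) * pixel_size
    for (cx, cy), value in zip(centers, lab):
        c0 = max(int(np.floor((cx - half - xmin) / pixel_size)), 0)
        c1 = min(int(np.ceil((cx + half - xmin) / pixel_size)), W)
        r0 = max(int(np.floor((cy - half - ymin) / pixel_size)), 0)
        r1 = min(int(np.ceil((cy + half - ymin) / pixel_size)), H)
        if c1 <= c0 or r1 <= r0:
            continue
        d2 = (px[c0:c1][None, :] - cx) ** 2 + (py[r0:r1][:, None] - cy) ** 2
        block = best[r0:r1, c0:c1]
        closer = d2 < block
        block[closer] = d2[closer]
        image[r0:r1, c0:c1][closer] = np.asarray(colors[value])[:3]
    return image, (float(xmin), float(ymin))


def plot_umap(
    embedding: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
):
    """2-D UMAP layout of an embedding, coloured by label.

    Delegates the manifold layout to umap-learn with a fixed random state, so
    repeated calls with the same seed give identical coordinates.  Returns
    ``(figure, layout)`` where ``layout`` is the ``n x 2`` coordinate array.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or len(embedding) < 2:
        raise ValueError("need at least two points to lay out")
    import umap  # deferred: numba-backed import is expensive

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(embedding) - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a seed disables parallelism
        layout = reducer.fit_transform(embedding)

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 5))
    palette = _default_palette(labels)
    for value in sorted(set(labels.tolist())):
        pts = layout[labels == value]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, color=palette[value], label=str(value))
    ax.legend(title="cluster", markerscale=2, fontsize=8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    return fig, layout
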