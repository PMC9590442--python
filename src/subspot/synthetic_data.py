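"""Synthetic Seq-Scope-like fixtures.

Every pipeline stage is testable without downloads: this module generates
coordinate-encoded first-run FASTQ files, ground-truth barcode maps, and
spatially structured sparse count matrices with spliced/unspliced layers.

The default fixture emulates a zonated liver section: three vertical stripe
domains with disjoint marker gene sets over a 300 x 300 µm extent, 10,000
barcodes and 200 genes, in the sparse regime typical of submicrometer
platforms (a few UMIs per barcode).  Stripe boundaries sit 1.5 µm off the
thirds of the extent — deliberately off the 10 µm coarse-bin lattice, because
a boundary coinciding with a coarse bin edge would be localized exactly by
*any* binning and the resolution advantage of sliding windows would be
unmeasurable.

All randomness flows from explicit seed arguments; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry_io import TileLayout
from .sdge_io import SpatialMatrix

__all__ = [
    "Stripe",
    "Disk",
    "HalfPlane",
    "Domain",
    "DomainModel",
    "GroundTruth",
    "default_layout",
    "default_domain_model",
    "generate_barcodes",
    "simulate_counts",
    "write_first_seq_fastq",
    "default_fixture",
    "disk_fixture",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# geometries and the domain model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stripe:
    """Vertical stripe: ``x_min <= x < x_max``."""

    x_min: float
    x_max: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= self.x_min) & (x < self.x_max)


@dataclass(frozen=True)
class Disk:
    cx: float
    cy: float
    radius: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class HalfPlane:
    """``coord < threshold`` (side="below") or ``>=`` (side="above") on one axis."""

    axis: str  # "x" or "y"
    threshold: float
    side: str = "below"

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        v = x if self.axis == "x" else y
        return v < self.threshold if self.side == "below" else v >= self.threshold


@dataclass(frozen=True)
class Domain:
    """A named spatial domain with mean UMI rates per barcode for its genes.

    ``geometry=None`` marks the default domain that applies wherever no other
    geometry matches.
    """

    name: str
    geometry: Stripe | Disk | HalfPlane | None
    rates: Mapping[str, float]  # gene_id -> mean UMIs per barcode


@dataclass
class DomainModel:
    """Spatial expression model: ordered domains (first match wins), a flat
    background rate added to every gene everywhere, and per-gene spliced
    fractions (scalar = shared by all genes)."""

    domains: Sequence[Domain]
    genes: pd.DataFrame  # gene_id, gene_name
    background_rate: float = 0.0
    spliced_fraction: float | Mapping[str, float] = 0.7

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for d in self.domains:
            if any(r < 0 for r in d.rates.values()):
                raise ValueError(f"domain {d.name!r} has a negative rate")
        sf = self.spliced_fraction
        values = [sf] if not isinstance(sf, Mapping) else list(sf.values())
        if any(not 0 <= v <= 1 for v in values):
            raise ValueError("spliced_fraction values must lie in [0, 1]")

    @property
    def domain_names(self) -> list[str]:
        return [d.name for d in self.domains]

    def domain_index_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Index (into ``domains``) of the domain owning each coordinate."""
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        out = np.full(x.shape, -1, dtype=int)
        default = -1
        for i, d in enumerate(self.domains):
            if d.geometry is None:
                default = i
                continue
            hit = d.geometry.contains(x, y) & (out == -1)
            out[hit] = i
        if (out == -1).any():
            if default == -1:
                raise ValueError("a coordinate is covered by no domain and no default exists")
            out[out == -1] = default
        return out

    def rate_matrix(self) -> np.ndarray:
        """(n_domains, n_genes) mean-rate matrix including background."""
        gene_ids = self.genes["gene_id"].tolist()
        rates = np.full((len(self.domains), len(gene_ids)), self.background_rate)
        col = {g: j for j, g in enumerate(gene_ids)}
        for i, d in enumerate(self.domains):
            for g, r in d.rates.items():
                rates[i, col[g]] += r
        return rates

    def spliced_vector(self) -> np.ndarray:
        sf = self.spliced_fraction
        if isinstance(sf, Mapping):
            return np.array([sf.get(g, 0.7) for g in self.genes["gene_id"]])
        return np.full(len(self.genes), float(sf))


@dataclass
class GroundTruth:
    """Generator truth: one row per barcode with its coordinate, read-identifier
    encoding (lane/tile/pixels) and, after count simulation, its domain."""

    table: pd.DataFrame  # barcode, x, y, lane, tile, x_px, y_px, [domain]
    extent: tuple[float, float]
    layout: TileLayout
    expected_totals: dict[str, float] = field(default_factory=dict)

    @property
    def barcodes(self) -> np.ndarray:
        return self.table["barcode"].to_numpy(dtype=object)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    def barcode_map_entries(self) -> dict[str, tuple[float, float]]:
        return {
            b: (float(x), float(y))
            for b, x, y in zip(self.table["barcode"], self.table["x"], self.table["y"])
        }


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

def default_layout(extent: tuple[float, float] = (300.0, 300.0), units_per_pixel: float = 0.01) -> TileLayout:
    """A 2 x 2 tile arrangement (lane 1, tiles 1101..1104) covering ``extent``,
    with instrument pixels of ``units_per_pixel`` length units."""
    w, h = extent
    return TileLayout.row_major(
        [1101, 1102, 1103, 1104],
        n_cols=2,
        tile_width=w / 2,
        tile_height=h / 2,
        gap=0.0,
        units_per_pixel=units_per_pixel,
    )


def default_domain_model(
    n_genes: int = 200, extent: tuple[float, float] = (300.0, 300.0)
) -> DomainModel:
    """Three vertical stripe domains with disjoint markers plus shared
    housekeeping and mitochondrial genes.

    Rates (mean UMIs per barcode): 0.1 per marker gene inside its own stripe,
    0.02 per housekeeping/mitochondrial gene everywhere, and a 0.002 flat
    background on every gene — about 7 UMIs per barcode in total, the sparse
    regime of submicrometer platforms.  Stripe boundaries at ``w/3 + 1.5`` and
    ``2w/3 - 1.5`` (off the 10 µm lattice; see the module docstring).
    """
    if n_genes < 25:
        raise ValueError("need at least 25 genes for the default composition")
    w, _ = extent
    b1, b2 = w / 3 + 1.5, 2 * w / 3 - 1.5

    n_mito, n_house = 5, 15
    n_marker = (n_genes - n_mito - n_house) // 3
    mito_names = ["mt-Nd1", "mt-Co1", "mt-Co2", "mt-Cytb", "mt-Atp6"][:n_mito]

    gene_ids, gene_names = [], []
    per_domain: list[list[str]] = [[], [], []]
    i = 0
    for d in range(3):
        for j in range(n_marker):
            gid = f"SYNG{i:05d}"
            gene_ids.append(gid)
            gene_names.append(f"Dom{d + 1}Mk{j:03d}")
            per_domain[d].append(gid)
            i += 1
    house: list[str] = []
    while i < n_genes - n_mito:
        gid = f"SYNG{i:05d}"
        gene_ids.append(gid)
        gene_names.append(f"Hk{len(house):03d}")
        house.append(gid)
        i += 1
    mito: list[str] = []
    for name in mito_names:
        gid = f"SYNG{i:05d}"
        gene_ids.append(gid)
        gene_names.append(name)
        mito.append(gid)
        i += 1

    shared = {g: 0.02 for g in house + mito}
    # outer stripes extend well past the extent so edge-window centers are covered
    stripes = [Stripe(-1e6, b1), Stripe(b1, b2), Stripe(b2, w + 1e6)]
    domains = [
        Domain(
            name=f"zone{d + 1}",
            geometry=stripes[d],
            rates={**{g: 0.1 for g in per_domain[d]}, **shared},
        )
        for d in range(3)
    ]
    genes = pd.DataFrame({"gene_id": gene_ids, "gene_name": gene_names})
    return DomainModel(domains=domains, genes=genes, background_rate=0.002, spliced_fraction=0.7)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _random_unique_barcodes(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        draw = _BASES[rng.integers(0, 4, size=(n - len(out), k))]
        for row in draw:
            b = "".join(row)
            if b not in seen:
                seen.add(b)
                out.append(b)
    return np.array(out, dtype=object)


def generate_barcodes(
    n: int,
    extent: tuple[float, float] = (300.0, 300.0),
    barcode_length: int = 20,
    seed: int = 0,
    layout: TileLayout | None = None,
) -> GroundTruth:
    """Generate ``n`` unique barcodes at uniform random pixel positions.

    Positions are drawn on the instrument pixel lattice of ``layout`` (default
    :func:`default_layout`), so every coordinate is exactly representable in a
    read identifier.  Requires ``4**barcode_length >= 10 * n`` (collision
    headroom).  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if 4**barcode_length < 10 * n:
        raise ValueError(
            f"barcode_length={barcode_length} is too short for n={n} unique barcodes "
            "(need 4**K >= 10*n)"
        )
    layout = layout if layout is not None else default_layout(extent)
    rng = np.random.default_rng(seed)
    barcodes = _random_unique_barcodes(n, barcode_length, rng)

    keys = sorted(layout.grid_assignment)
    pick = rng.integers(0, len(keys), size=n)
    w_px = int(round(layout.tile_width / layout.units_per_pixel))
    h_px = int(round(layout.tile_height / layout.units_per_pixel))
    x_px = rng.integers(0, w_px, size=n)
    y_px = rng.integers(0, h_px, size=n)

    lanes = np.array([keys[i][0] for i in pick])
    tiles = np.array([keys[i][1] for i in pick])
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        xs[i], ys[i] = layout.globalize(lanes[i], tiles[i], int(x_px[i]), int(y_px[i]))

    table = pd.DataFrame(
        {
            "barcode": barcodes,
            "x": xs,
            "y": ys,
            "lane": lanes,
            "tile": tiles,
            "x_px": x_px,
            "y_px": y_px,
        }
    )
    return GroundTruth(table=table, extent=extent, layout=layout)


def simulate_counts(
    truth: GroundTruth,
    model: DomainModel,
    genes: pd.DataFrame | None = None,
    seed: int = 0,
    overdispersion: float | None = None,
) -> SpatialMatrix:
    """Simulate sparse counts: per barcode and gene, total UMIs are Poisson
    with the rate of the barcode's domain (plus background), split into
    spliced/unspliced by a per-gene binomial.  Layers: ``Gene`` (= total),
    ``spliced``, ``unspliced``.

    ``overdispersion``, if given, is a gamma shape parameter: rates are
    multiplied by Gamma(shape, 1/shape) noise, yielding negative-binomial
    marginals.  Writes each barcode's domain name into ``truth.table`` and the
    per-layer expected totals into ``truth.expected_totals``.
    """
    genes = model.genes if genes is None else genes
    rng = np.random.default_rng(seed)
    coords = truth.coords
    didx = model.domain_index_at(coords[:, 0], coords[:, 1])
    truth.table["domain"] = [model.domains[i].name for i in didx]

    rates = model.rate_matrix()  # domains x genes
    lam = rates[didx]  # barcodes x genes
    if overdispersion is not None:
        if overdispersion <= 0:
            raise ValueError("overdispersion (gamma shape) must be positive")
        lam = lam * rng.gamma(overdispersion, 1.0 / overdispersion, size=lam.shape)
    total = rng.poisson(lam)
    sf = model.spliced_vector()
    spliced = rng.binomial(total, sf[None, :])
    unspliced = total - spliced

    layers = {
        "Gene": sp.csr_matrix(total.astype(np.int64)),
        "spliced": sp.csr_matrix(spliced.astype(np.int64)),
        "unspliced": sp.csr_matrix(unspliced.astype(np.int64)),
    }
    truth.expected_totals = {
        "Gene": float(lam.sum()) if overdispersion is None else float(rates[didx].sum()),
        "spliced": float((rates[didx] * sf[None, :]).sum()),
        "unspliced": float((rates[didx] * (1 - sf[None, :])).sum()),
    }
    return SpatialMatrix(
        barcodes=truth.barcodes,
        genes=genes.copy(),
        coords=coords,
        layers=layers,
        default_layer="Gene",
    )


def write_first_seq_fastq(
    truth: GroundTruth,
    layout: TileLayout | None = None,
    path: str | Path = "first_seq.fastq",
    seed: int = 0,
    error_rate: float = 0.0,
    reads_per_barcode: int = 1,
) -> pd.DataFrame:
    """Write a coordinate-encoded first-run FASTQ for the truth's barcodes.

    Read identifiers follow ``instrument:run:flowcell:lane:tile:x:y`` with the
    truth's stored lane/tile/pixels.  With ``error_rate > 0``, each base is
    substituted independently with that probability (for error-correction
    tests).  Returns a manifest with one row per read: ``barcode_true``,
    ``barcode_observed``, ``n_errors``.
    """
    layout = layout if layout is not None else truth.layout
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    rows: list[tuple[str, str, int]] = []
    for _, row in truth.table.iterrows():
        # validate that the coordinate is representable under the layout
        layout.globalize(int(row["lane"]), int(row["tile"]), int(row["x_px"]), int(row["y_px"]))
        for rep in range(reads_per_barcode):
            barcode = str(row["barcode"])
            observed = barcode
            n_err = 0
            if error_rate > 0:
                chars = list(barcode)
                for i in range(len(chars)):
                    if rng.random() < error_rate:
                        choices = [b for b in "ACGT" if b != chars[i]]
                        chars[i] = choices[rng.integers(0, 3)]
                        n_err += 1
                observed = "".join(chars)
            ident = (
                f"SYN01:1:FCSYN:{int(row['lane'])}:{int(row['tile'])}"
                f":{int(row['x_px'])}:{int(row['y_px'])}"
            )
            rec = SeqRecord(Seq(observed), id=ident, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(observed)
            records.append(rec)
            rows.append((barcode, observed, n_err))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return pd.DataFrame(rows, columns=["barcode_true", "barcode_observed", "n_errors"])


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def default_fixture(
    n_barcodes: int = 10_000,
    n_genes: int = 200,
    extent: tuple[float, float] = (300.0, 300.0),
    seed: int = 0,
    barcode_length: int = 20,
) -> tuple[GroundTruth, SpatialMatrix, DomainModel]:
    """The standard three-stripe fixture used throughout the test suite."""
    model = default_domain_model(n_genes=n_genes, extent=extent)
    truth = generate_barcodes(
        n_barcodes, extent=extent, barcode_length=barcode_length, seed=seed
    )
    matrix = simulate_counts(truth, model, seed=seed + 1)
    return truth, matrix, model


def disk_fixture(
    n_dense: int = 3000,
    n_background: int = 150,
    disk: Disk = Disk(150.0, 150.0, 80.0),
    extent: tuple[float, float] = (300.0, 300.0),
    barcode_length: int = 12,
    seed: int = 0,
) -> tuple[SpatialMatrix, Disk]:
    """Dense barcodes inside a disk on a sparse background — a tissue-section
    stand-in for boundary-detection tests.  Each barcode carries one UMI of a
    single marker gene."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n_dense)
    r = disk.radius * np.sqrt(rng.uniform(0, 1, n_dense))
    inside = np.column_stack([disk.cx + r * np.cos(theta), disk.cy + r * np.sin(theta)])
    outside = np.column_stack(
        [rng.uniform(0, extent[0], n_background), rng.uniform(0, extent[1], n_background)]
    )
    coords = np.vstack([inside, outside])
    n = len(coords)
    barcodes = _random_unique_barcodes(n, barcode_length, rng)
    genes = pd.DataFrame({"gene_id": ["SYNG00000"], "gene_name": ["Marker"]})
    counts = sp.csr_matrix(np.ones((n, 1), dtype=np.int64))
    matrix = SpatialMatrix(
        barcodes=barcodes, genes=genes, coords=coords, layers={"Gene": counts}
    )
    return matrix, disk
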