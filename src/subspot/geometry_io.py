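"""Spatial barcode geometry.

Sequencing platforms such as Seq-Scope determine the physical location of every
spatial barcode in a dedicated first sequencing run: the barcode sequence is in
the read, and its flow-cell position (lane, tile, local x/y pixel) is in the
Illumina read identifier.  This module parses those identifiers, places tiles on
one global canvas, builds an error-corrected barcode -> coordinate map, and
writes the whitelist artifacts an aligner (e.g. STARsolo) consumes.

Coordinates are expressed in length units (micrometres by default), origin at
the top-left corner, y increasing downward.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ReadIdentifierError",
    "FastqFormatError",
    "TileLayout",
    "BarcodeMap",
    "parse_read_identifier",
    "globalize",
    "build_barcode_map",
    "correct_barcode",
    "write_whitelist",
    "read_coordinates_table",
]


class ReadIdentifierError(ValueError):
    """A read identifier does not follow the expected Illumina dialect."""


class FastqFormatError(ValueError):
    """A FASTQ file is empty, truncated or otherwise malformed."""


def parse_read_identifier(read_id: str, dialect: str = "illumina") -> tuple[int, int, int, int]:
    """Extract (lane, tile, x_local, y_local) from an Illumina read identifier.

    The identifier dialect is the colon-delimited
    ``instrument:run:flowcell:lane:tile:x:y`` form, optionally with trailing
    fields or a whitespace-separated comment.

    Raises
    ------
    ReadIdentifierError
        If the identifier has fewer than seven colon fields, the positional
        fields are not integers, or they are out of range.
    """
    if dialect != "illumina":
        raise ValueError(f"unknown read-identifier dialect: {dialect!r}")
    token = read_id.split()[0].lstrip("@") if read_id.strip() else ""
    fields = token.split(":")
    if len(fields) < 7:
        raise ReadIdentifierError(
            f"malformed read identifier {read_id!r}: expected at least 7 ':'-delimited "
            f"fields (instrument:run:flowcell:lane:tile:x:y), got {len(fields)}"
        )
    try:
        lane, tile, x_local, y_local = (int(fields[i]) for i in (3, 4, 5, 6))
    except ValueError as exc:
        raise ReadIdentifierError(
            f"malformed read identifier {read_id!r}: non-integer lane/tile/x/y field ({exc})"
        ) from None
    if lane <= 0 or tile <= 0:
        raise ReadIdentifierError(f"read {read_id!r}: lane and tile must be positive")
    if x_local < 0 or y_local < 0:
        raise ReadIdentifierError(f"read {read_id!r}: negative local coordinates")
    return lane, tile, x_local, y_local


@dataclass(frozen=True)
class TileLayout:
    """Placement of flow-cell tiles on one global canvas.

    Parameters
    ----------
    grid_assignment
        Mapping ``(lane, tile) -> (row, col)`` giving each tile's position in a
        rectangular arrangement of tiles.  Must be injective.
    tile_width, tile_height
        Tile extent in length units (per tile, excluding the gap).
    gap
        Spacing between adjacent tiles, in length units.
    units_per_pixel
        Length units per instrument pixel (local read-identifier coordinates
        are in pixels).
    """

    grid_assignment: Mapping[tuple[int, int], tuple[int, int]]
    tile_width: float
    tile_height: float
    gap: float = 0.0
    units_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if self.tile_width <= 0 or self.tile_height <= 0:
            raise ValueError("tile_width and tile_height must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.units_per_pixel <= 0:
            raise ValueError("units_per_pixel must be positive")
        cells = list(self.grid_assignment.values())
        if len(set(cells)) != len(cells):
            raise ValueError("grid_assignment must be injective (one grid cell per tile)")

    @classmethod
    def row_major(
        cls,
        tiles: Mapping[int, list[int]] | list[int],
        n_cols: int,
        tile_width: float,
        tile_height: float,
        gap: float = 0.0,
        units_per_pixel: float = 1.0,
    ) -> "TileLayout":
        """Build a row-major layout. ``tiles`` is either ``{lane: [tile, ...]}``
        or a flat tile list (assumed lane 1); tiles fill rows left to right."""
        if not isinstance(tiles, Mapping):
            tiles = {1: list(tiles)}
        assignment: dict[tuple[int, int], tuple[int, int]] = {}
        i = 0
        for lane in sorted(tiles):
            for tile in tiles[lane]:
                assignment[(lane, tile)] = (i // n_cols, i % n_cols)
                i += 1
        return cls(assignment, tile_width, tile_height, gap, units_per_pixel)

    def tile_origin(self, lane: int, tile: int) -> tuple[float, float]:
        try:
            row, col = self.grid_assignment[(lane, tile)]
        except KeyError:
            known = sorted(self.grid_assignment)
            raise KeyError(
                f"unknown (lane, tile) = ({lane}, {tile}); known tiles: {known}"
            ) from None
        return col * (self.tile_width + self.gap), row * (self.tile_height + self.gap)

    def globalize(self, lane: int, tile: int, x_local: int, y_local: int) -> tuple[float, float]:
        ox, oy = self.tile_origin(lane, tile)
        return ox + x_local * self.units_per_pixel, oy + y_local * self.units_per_pixel

    def localize(self, x: float, y: float) -> tuple[int, int, int, int]:
        """Invert :meth:`globalize`: global coordinate -> (lane, tile, x_px, y_px).

        Pixels are rounded to the nearest integer; raises ``ValueError`` if the
        coordinate falls outside every tile.
        """
        for (lane, tile), _ in self.grid_assignment.items():
            ox, oy = self.tile_origin(lane, tile)
            if ox <= x < ox + self.tile_width and oy <= y < oy + self.tile_height:
                return (
                    lane,
                    tile,
                    int(round((x - ox) / self.units_per_pixel)),
                    int(round((y - oy) / self.units_per_pixel)),
                )
        raise ValueError(f"coordinate ({x}, {y}) lies outside every tile of the layout")

    # -- serialisation (used by the CLI's --layout option) -------------------
    def to_dict(self) -> dict:
        return {
            "tile_width": self.tile_width,
            "tile_height": self.tile_height,
            "gap": self.gap,
            "units_per_pixel": self.units_per_pixel,
            "tiles": [
                {"lane": lane, "tile": tile, "row": row, "col": col}
                for (lane, tile), (row, col) in sorted(self.grid_assignment.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TileLayout":
        assignment = {
            (int(t["lane"]), int(t["tile"])): (int(t["row"]), int(t["col"]))
            for t in d["tiles"]
        }
        return cls(
            assignment,
            float(d["tile_width"]),
            float(d["tile_height"]),
            float(d.get("gap", 0.0)),
            float(d.get("units_per_pixel", 1.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TileLayout":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def globalize(
    lane: int, tile: int, x_local: int, y_local: int, layout: TileLayout
) -> tuple[float, float]:
    """Map a (lane, tile, local pixel) position to a global coordinate."""
    return layout.globalize(lane, tile, x_local, y_local)


@dataclass
class BarcodeMap:
    """Error-free mapping from spatial barcode sequence to global coordinate."""

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_collisions: int = 0
    n_total_reads: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def whitelist(self) -> set[str]:
        return set(self.entries)

    def to_frame(self) -> pd.DataFrame:
        barcodes = sorted(self.entries)
        return pd.DataFrame(
            {
                "barcode": barcodes,
                "x": [self.entries[b][0] for b in barcodes],
                "y": [self.entries[b][1] for b in barcodes],
            }
        )


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fastq(path: str | Path) -> Iterator:
    """Yield Biopython FASTQ records, converting parser failures into
    :class:`FastqFormatError` that names the failing record index."""
    with _open_maybe_gzip(path) as handle:
        it = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            try:
                record = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: truncated or malformed FASTQ record at index {index}: {exc}"
                ) from None
            yield record
            index += 1


def build_barcode_map(
    fastq_path: str | Path,
    barcode_length: int,
    layout: TileLayout,
    barcode_start: int = 0,
    collision_policy: str = "drop",
) -> BarcodeMap:
    """Construct a :class:`BarcodeMap` from a coordinate-encoded FASTQ file.

    The barcode is the ``[barcode_start, barcode_start + barcode_length)``
    slice of each read sequence; the coordinate comes from the read identifier
    via :func:`parse_read_identifier` and ``layout``.

    Rules
    -----
    * Barcodes containing ``N`` are discarded (they cannot be matched exactly).
    * Duplicate reads of one barcode at one coordinate collapse to one entry.
    * A barcode observed at more than one distinct coordinate is ambiguous and
      is handled per ``collision_policy``: ``"drop"`` (default) removes it and
      counts it in ``n_collisions``; ``"keep-first"`` keeps the first-seen
      coordinate (still counted).
    """
    if collision_policy not in ("drop", "keep-first"):
        raise ValueError(f"unknown collision_policy: {collision_policy!r}")
    if barcode_start < 0 or barcode_length <= 0:
        raise ValueError("barcode_start must be >= 0 and barcode_length positive")

    seen: dict[str, list[tuple[float, float]]] = {}
    n_reads = 0
    for record in _iter_fastq(fastq_path):
        n_reads += 1
        seq = str(record.seq)
        end = barcode_start + barcode_length
        if end > len(seq):
            raise FastqFormatError(
                f"read {record.id!r}: barcode slice [{barcode_start}, {end}) exceeds "
                f"read length {len(seq)}"
            )
        barcode = seq[barcode_start:end].upper()
        if any(c not in "ACGT" for c in barcode):
            continue  # N (or other ambiguity codes): unmatchable, discard
        lane, tile, x_local, y_local = parse_read_identifier(record.description or record.id)
        coord = layout.globalize(lane, tile, x_local, y_local)
        coords = seen.setdefault(barcode, [])
        if coord not in coords:
            coords.append(coord)
    if n_reads == 0:
        raise FastqFormatError(f"{fastq_path}: FASTQ file contains no reads")

    entries: dict[str, tuple[float, float]] = {}
    n_collisions = 0
    for barcode, coords in seen.items():
        if len(coords) == 1:
            entries[barcode] = coords[0]
        else:
            n_collisions += 1
            if collision_policy == "keep-first":
                entries[barcode] = coords[0]
    if n_collisions:
        logger.info(
            "%d barcode(s) observed at multiple coordinates (policy=%s)",
            n_collisions,
            collision_policy,
        )
    return BarcodeMap(entries=entries, n_collisions=n_collisions, n_total_reads=n_reads)


def correct_barcode(observed: str, whitelist: set[str] | frozenset[str]) -> str | None:
    """Error-correct a barcode against a whitelist.

    Returns the exact whitelist match if there is one, else the *unique*
    whitelist member at Hamming distance 1, else ``None`` (no match, or two or
    more distance-1 candidates: ambiguous).  Only substitutions are considered.

    Raises
    ------
    ValueError
        If ``observed`` and the whitelist disagree on barcode length.
    """
    if not whitelist:
        return None
    k = len(next(iter(whitelist)))
    if len(observed) != k:
        raise ValueError(
            f"barcode length mismatch: observed has {len(observed)} bases, whitelist has {k}"
        )
    if observed in whitelist:
        return observed
    hits: list[str] = []
    for i, base in enumerate(observed):
        prefix, suffix = observed[:i], observed[i + 1 :]
        for b in "ACGT":
            if b != base:
                candidate = prefix + b + suffix
                if candidate in whitelist:
                    hits.append(candidate)
                    if len(hits) > 1:
                        return None
    return hits[0] if len(hits) == 1 else None


def write_whitelist(barcode_map: BarcodeMap, path: str | Path) -> Path:
    """Write an aligner-compatible whitelist plus a coordinates sidecar.

    The whitelist at ``path`` has one barcode per line in lexicographic order;
    the sidecar ``<path stem>.coords.tsv`` has columns barcode, x, y.
    Returns the sidecar path.
    """
    if len(barcode_map) == 0:
        raise ValueError("refusing to write an empty whitelist")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    barcodes = sorted(barcode_map.entries)
    path.write_text("".join(b + "\n" for b in barcodes))
    sidecar = path.with_name(path.stem + ".coords.tsv")
    with open(sidecar, "w") as fh:
        fh.write("barcode\tx\ty\n")
        for b in barcodes:
            x, y = barcode_map.entries[b]
            fh.write(f"{b}\t{x:.17g}\t{y:.17g}\n")
    return sidecar


def read_coordinates_table(path: str | Path) -> BarcodeMap:
    """Re-read a coordinates sidecar written by :func:`write_whitelist`."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str}, float_precision="round_trip")
    expected = {"barcode", "x", "y"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}")
    entries = {
        str(b): (float(x), float(y)) for b, x, y in zip(df["barcode"], df["x"], df["y"])
    }
    return BarcodeMap(entries=entries)
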