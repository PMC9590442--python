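"""Barcode-geometry tests: identifier parsing, tile globalization, barcode-map
construction and Hamming-1 error correction."""

import gzip

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subspot.geometry_io import (
    BarcodeMap,
    FastqFormatError,
    ReadIdentifierError,
    TileLayout,
    build_barcode_map,
    correct_barcode,
    globalize,
    parse_read_identifier,
    read_coordinates_table,
    write_whitelist,
)
from subspot.synthetic_data import default_layout, generate_barcodes, write_first_seq_fastq


# ---------------------------------------------------------------------------
# read identifiers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "read_id, expected",
    [
        ("M0001:42:FC1:1:1101:5000:7000", (1, 1101, 5000, 7000)),
        ("M0001:42:FC1:2:2214:0:0", (2, 2214, 0, 0)),
        ("@M0001:42:FC1:1:1101:5000:7000 1:N:0:ACGT", (1, 1101, 5000, 7000)),
    ],
)
def test_parse_read_identifier(read_id, expected):
    assert parse_read_identifier(read_id) == expected


@pytest.mark.parametrize(
    "read_id",
    [
        "M0001:42:FC1:1:1101:5000",  # missing field
        "M0001:42:FC1:1:1101:five:7000",  # non-integer
        "",
    ],
)
def test_parse_read_identifier_rejects_malformed(read_id):
    with pytest.raises(ReadIdentifierError):
        parse_read_identifier(read_id)


# ---------------------------------------------------------------------------
# tile globalization
# ---------------------------------------------------------------------------

def _layout(**kwargs):
    defaults = dict(
        grid_assignment={(1, 1): (0, 0), (1, 2): (0, 2), (1, 3): (1, 0)},
        tile_width=100.0,
        tile_height=100.0,
    )
    defaults.update(kwargs)
    return TileLayout(**defaults)


def test_globalize_origin_and_row_offset():
    layout = _layout()
    assert globalize(1, 1, 0, 0, layout) == (0.0, 0.0)
    # tile at row 1: y = 1*(100+0) + 5*1
    assert globalize(1, 3, 0, 5, layout) == (0.0, 105.0)


def test_globalize_with_gap_and_pixel_scale():
    layout = _layout(gap=10.0, units_per_pixel=0.5)
    # col 2: x = 2*(100+10) + 1*0.5 = 220.5
    assert globalize(1, 2, 1, 0, layout) == (220.5, 0.0)


def test_globalize_unknown_tile_lists_known():
    with pytest.raises(KeyError, match="known tiles"):
        globalize(1, 99, 0, 0, _layout())


def test_globalize_injective_within_bounds():
    """Distinct (tile, pixel) positions map to distinct global coordinates."""
    layout = TileLayout.row_major([1, 2, 3, 4], n_cols=2, tile_width=10.0, tile_height=10.0)
    seen = set()
    for tile in (1, 2, 3, 4):
        for xp in range(10):
            for yp in range(10):
                seen.add(layout.globalize(1, tile, xp, yp))
    assert len(seen) == 4 * 100


def test_layout_yaml_round_trip(tmp_path):
    layout = _layout(gap=2.5, units_per_pixel=0.25)
    layout.to_yaml(tmp_path / "layout.yaml")
    assert TileLayout.from_yaml(tmp_path / "layout.yaml") == layout


# ---------------------------------------------------------------------------
# barcode map construction
# ---------------------------------------------------------------------------

def _write_fastq(path, reads):
    """reads: list of (identifier, sequence)."""
    text = "".join(f"@{ident}\n{seq}\n+\n{'I' * len(seq)}\n" for ident, seq in reads)
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)
    return path


UNIT_LAYOUT = TileLayout({(1, 1101): (0, 0)}, tile_width=1000.0, tile_height=1000.0)


def test_build_barcode_map_dedups_identical_reads(tmp_path):
    fq = _write_fastq(
        tmp_path / "r.fastq",
        [
            ("I:1:F:1:1101:10:10", "AAAA"),
            ("I:1:F:1:1101:10:10", "AAAA"),
            ("I:1:F:1:1101:20:5", "CCCC"),
        ],
    )
    bmap = build_barcode_map(fq, barcode_length=4, layout=UNIT_LAYOUT)
    assert len(bmap) == 2
    assert bmap.n_collisions == 0
    assert bmap.entries == {"AAAA": (10.0, 10.0), "CCCC": (20.0, 5.0)}


def test_build_barcode_map_collision_policies(tmp_path):
    reads = [("I:1:F:1:1101:10:10", "AAAA"), ("I:1:F:1:1101:30:30", "AAAA")]
    fq = _write_fastq(tmp_path / "r.fastq", reads)
    dropped = build_barcode_map(fq, barcode_length=4, layout=UNIT_LAYOUT)
    assert len(dropped) == 0 and dropped.n_collisions == 1
    kept = build_barcode_map(fq, barcode_length=4, layout=UNIT_LAYOUT, collision_policy="keep-first")
    assert kept.entries == {"AAAA": (10.0, 10.0)} and kept.n_collisions == 1


def test_build_barcode_map_drops_n_and_slices(tmp_path):
    fq = _write_fastq(
        tmp_path / "r.fastq",
        [("I:1:F:1:1101:1:1", "TTANGG"), ("I:1:F:1:1101:2:2", "TTACGG")],
    )
    # slice [2, 6): first read contains N -> dropped
    bmap = build_barcode_map(fq, barcode_start=2, barcode_length=4, layout=UNIT_LAYOUT)
    assert bmap.entries == {"ACGG": (2.0, 2.0)}
    assert bmap.n_total_reads == 2


def test_build_barcode_map_empty_and_truncated(tmp_path):
    empty = tmp_path / "empty.fastq"
    empty.write_text("")
    with pytest.raises(FastqFormatError, match="no reads"):
        build_barcode_map(empty, barcode_length=4, layout=UNIT_LAYOUT)
    bad = tmp_path / "bad.fastq"
    bad.write_text("@I:1:F:1:1101:1:1\nACGT\n+\nII\n")  # quality shorter than sequence
    with pytest.raises(FastqFormatError, match="index 0"):
        build_barcode_map(bad, barcode_length=4, layout=UNIT_LAYOUT)


def test_build_barcode_map_recovers_generator_truth(tmp_path):
    """A clean synthetic FASTQ reproduces the generator's truth table exactly."""
    truth = generate_barcodes(1000, extent=(100.0, 100.0), barcode_length=12, seed=7,
                              layout=default_layout((100.0, 100.0)))
    fq = tmp_path / "first.fastq"
    write_first_seq_fastq(truth, path=fq, seed=0, error_rate=0.0)
    bmap = build_barcode_map(fq, barcode_length=12, layout=truth.layout)
    assert bmap.entries == truth.barcode_map_entries()


# ---------------------------------------------------------------------------
# error correction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "observed, whitelist, expected",
    [
        ("ACGT", {"ACGT", "TTTT"}, "ACGT"),  # exact
        ("ACGA", {"ACGT", "TTTT"}, "ACGT"),  # unique Hamming-1
        ("ACGA", {"ACGT", "ACGG"}, None),  # ambiguous
        ("GGGG", {"ACGT", "TTTT"}, None),  # no match
        ("ACGN", {"ACGT", "TTTT"}, "ACGT"),  # N rescued by substitution
    ],
)
def test_correct_barcode(observed, whitelist, expected):
    assert correct_barcode(observed, whitelist) == expected


def test_correct_barcode_length_mismatch():
    with pytest.raises(ValueError, match="length mismatch"):
        correct_barcode("ACG", {"ACGT"})


@settings(max_examples=200, deadline=None)
@given(
    whitelist=st.sets(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1, max_size=8),
    observed=st.text(alphabet="ACGT", min_size=6, max_size=6),
)
def test_correct_barcode_idempotent_and_closed(whitelist, observed):
    """Corrections are whitelist members, and correcting a correction is a no-op."""
    result = correct_barcode(observed, whitelist)
    if result is not None:
        assert result in whitelist
        assert correct_barcode(result, whitelist) == result


# ---------------------------------------------------------------------------
# whitelist I/O
# ---------------------------------------------------------------------------

def test_write_whitelist_sorted_round_trip(tmp_path):
    bmap = BarcodeMap(entries={"TTTT": (1.0, 1.0), "AAAA": (2.0, 2.0)})
    out = tmp_path / "whitelist.txt"
    sidecar = write_whitelist(bmap, out)
    assert out.read_text().splitlines() == ["AAAA", "TTTT"]
    assert read_coordinates_table(sidecar).entries == bmap.entries


def test_write_whitelist_rejects_empty(tmp_path):
    with pytest.raises(ValueError, match="empty"):
        write_whitelist(BarcodeMap(), tmp_path / "w.txt")
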