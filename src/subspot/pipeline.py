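"""Step registry and orchestration.

The labelled steps mirror the workflow's three phases — alignment preparation
(A1 coordinate extraction, A2 spatial QC, A3 external alignment hand-off),
clustering (C1 grid binning, C2 sliding-window binning, C3 two-track
clustering) and visualization (V1 RGB / cluster-map rendering).  Steps run
individually or as any consecutive chain from one declarative YAML config;
each run writes a JSON-lines manifest with parameters and output checksums.

Alignment itself (STARsolo) is an external-tool boundary: A3 only writes the
whitelist hand-off and a documented command template, and downstream steps
ingest the aligner's MTX output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import binning, cluster, geometry_io, qc, viz
from .sdge_io import read_mtx_dir

logger = logging.getLogger(__name__)

__all__ = ["StepConfig", "PipelineError", "STEP_ORDER", "run_steps", "external_align_handoff"]

STEP_ORDER = ("A1", "A2", "A3", "C1", "C2", "C3", "V1")


class PipelineError(RuntimeError):
    """A step cannot run: unknown id, broken chain or missing upstream artifact."""


@dataclass
class StepConfig:
    """Declarative run configuration.

    ``params`` holds one mapping per step id; ``workdir`` receives one
    subdirectory per executed step; ``seed`` feeds every stochastic step.
    """

    workdir: Path
    seed: int = 0
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StepConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            workdir=Path(doc.get("workdir", ".")),
            seed=int(doc.get("seed", 0)),
            params={k: dict(v or {}) for k, v in doc.get("steps", {}).items()},
        )

    def step_params(self, step: str) -> dict[str, Any]:
        return dict(self.params.get(step, {}))

    def step_dir(self, step: str) -> Path:
        return Path(self.workdir) / step


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksums(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def _require(path: Path, producer: str, what: str) -> Path:
    if not Path(path).exists():
        raise PipelineError(
            f"missing input {what!r} at {path}: run step {producer} first or point "
            f"the config at an existing artifact"
        )
    return Path(path)


def _load_layout(params: dict[str, Any]) -> geometry_io.TileLayout:
    layout = params.get("layout")
    if layout is None:
        from .synthetic_data import default_layout

        return default_layout()
    if isinstance(layout, geometry_io.TileLayout):
        return layout
    return geometry_io.TileLayout.from_yaml(layout)


def _resolve_sdge(config: StepConfig, params: dict[str, Any]):
    src = params.get("sdge_dir") or config.step_params("C1").get("sdge_dir")
    if src is None:
        raise PipelineError(
            "no spatial expression matrix configured (set steps.C1.sdge_dir): the "
            "alignment step A3 is external and its MTX output must be supplied"
        )
    _require(Path(src), "A3 (external alignment)", "sdge_dir")
    return read_mtx_dir(src, coords_source=params.get("coords"), default_layer=params.get("layer", "Gene"))


# ---------------------------------------------------------------------------
# step implementations
# ---------------------------------------------------------------------------

def _run_a1(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    fastq = _require(Path(params["fastq"]), "upstream sequencing", "fastq")
    layout = _load_layout(params)
    bmap = geometry_io.build_barcode_map(
        fastq,
        barcode_length=int(params.get("barcode_length", 20)),
        layout=layout,
        barcode_start=int(params.get("barcode_start", 0)),
        collision_policy=params.get("collision_policy", "drop"),
    )
    out = config.step_dir("A1")
    out.mkdir(parents=True, exist_ok=True)
    geometry_io.write_whitelist(bmap, out / "whitelist.txt")
    return [out / "whitelist.txt", out / "whitelist.coords.tsv"]


def _run_a2(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    coords_path = Path(params.get("coords", config.step_dir("A1") / "whitelist.coords.tsv"))
    _require(coords_path, "A1", "coordinates table")
    bmap = geometry_io.read_coordinates_table(coords_path)
    coords = bmap.to_frame()[["x", "y"]].to_numpy()
    raster = qc.density_raster_from_points(
        coords, None, cell_size=float(params.get("cell_size", 10.0))
    )
    tissue = qc.detect_tissue(
        raster,
        method=params.get("method", "quantile"),
        q=float(params.get("q", 0.5)),
    )
    out = config.step_dir("A2")
    out.mkdir(parents=True, exist_ok=True)
    qc.plot_density(raster, out / "barcode_density.png")
    rows, cols = np.nonzero(tissue.mask)
    with open(out / "tissue_mask_cells.tsv", "w") as fh:
        fh.write("row\tcol\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\n")
    (out / "tissue_bbox.json").write_text(json.dumps({"world_rect": tissue.world_rect()}))
    return list(out.iterdir())


def _run_a3(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    whitelist = Path(params.get("whitelist", config.step_dir("A1") / "whitelist.txt"))
    coords = Path(params.get("coords", config.step_dir("A1") / "whitelist.coords.tsv"))
    out = config.step_dir("A3")
    external_align_handoff(whitelist, coords, out)
    return list(out.iterdir())


def _run_c1(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    matrix = _resolve_sdge(config, params)
    spec = binning.BinSpec(side=float(params.get("side", 10.0)))
    binned = binning.simple_grid_bin(
        matrix, spec, min_umi=int(params.get("min_umi", 10)), layer=params.get("layer")
    )
    out = config.step_dir("C1")
    binning.save_binned(binned, out)
    return list(out.rglob("*"))


def _run_c2(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    matrix = _resolve_sdge(config, params)
    spec = binning.BinSpec(
        side=float(params.get("side", 10.0)), step=float(params.get("step", 2.0))
    )
    # windows feed projection, which requires positive totals; min_umi=1 drops
    # only windows that could never be labelled anyway
    binned = binning.sliding_window_bin(
        matrix, spec, min_umi=int(params.get("min_umi", 1)), layer=params.get("layer")
    )
    out = config.step_dir("C2")
    binning.save_binned(binned, out)
    return list(out.rglob("*"))


def _run_c3(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    grid_dir = Path(params.get("grid", config.step_dir("C1")))
    mssw_dir = Path(params.get("mssw", config.step_dir("C2")))
    _require(grid_dir / "matrix.mtx", "C1", "grid bins")
    _require(mssw_dir / "matrix.mtx", "C2", "sliding-window bins")
    grid = binning.load_binned(grid_dir)
    mssw = binning.load_binned(mssw_dir)
    model = cluster.fit_reference(
        grid,
        n_hvg=int(params.get("n_hvg", 2000)),
        n_pcs=int(params.get("n_pcs", 20)),
        k_neighbors=int(params.get("k_neighbors", 20)),
        resolution=float(params.get("resolution", 0.5)),
        seed=config.seed,
    )
    embedding = cluster.project(model, mssw)
    labels = cluster.transfer_labels(model, embedding, k=int(params.get("k_transfer", 5)))

    out = config.step_dir("C3")
    out.mkdir(parents=True, exist_ok=True)
    model.to_json(out / "model.json")
    for name, binned, lab in (
        ("grid_labels.tsv", grid, model.reference_labels),
        ("mssw_labels.tsv", mssw, labels),
    ):
        with open(out / name, "w") as fh:
            fh.write("bin_id\tx\ty\tcluster\n")
            for bid, (x, y), c in zip(binned.bin_ids, binned.centers, lab):
                fh.write(f"{bid}\t{x:.17g}\t{y:.17g}\t{c}\n")
    np.savetxt(out / "mssw_embedding.tsv", embedding, delimiter="\t", fmt="%.17g")
    return list(out.iterdir())


def _run_v1(config: StepConfig, params: dict[str, Any]) -> list[Path]:
    out = config.step_dir("V1")
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    genesets = params.get("genesets")
    if genesets:
        matrix = _resolve_sdge(config, params)
        spec = viz.GenesetRGB(
            red=genesets.get("red", ()),
            green=genesets.get("green", ()),
            blue=genesets.get("blue", ()),
            layer_per_channel=params.get("layer_per_channel", {}),
            pixel_size=float(params.get("pixel_size", 1.0)),
        )
        render = viz.render_rgb(matrix, spec)
        outputs.append(render.to_png(out / "rgb.png"))

    labels_path = config.step_dir("C3") / "mssw_labels.tsv"
    if labels_path.exists():
        import pandas as pd

        mssw = binning.load_binned(config.step_dir("C2"))
        lab = pd.read_csv(labels_path, sep="\t").set_index("bin_id")["cluster"]
        image, _ = viz.render_cluster_map(
            mssw,
            lab.loc[list(mssw.bin_ids)].to_numpy(),
            pixel_size=float(params.get("pixel_size", 1.0)),
        )
        from PIL import Image

        png = out / "mssw_cluster_map.png"
        Image.fromarray((image * 255 + 0.5).astype("uint8"), mode="RGB").save(png)
        outputs.append(png)
    if not outputs:
        raise PipelineError("V1 has nothing to render: configure genesets or run C3 first")
    return outputs


_STEP_IMPL = {
    "A1": _run_a1,
    "A2": _run_a2,
    "A3": _run_a3,
    "C1": _run_c1,
    "C2": _run_c2,
    "C3": _run_c3,
    "V1": _run_v1,
}


def run_steps(config: StepConfig, steps: Sequence[str]) -> list[dict[str, Any]]:
    """Execute a consecutive chain of steps; returns (and writes) the manifest.

    ``steps`` must be a non-empty subset of :data:`STEP_ORDER` in order and
    with no gaps (the external alignment step A3 may be skipped over, since it
    never runs in-process).  Each entry of the returned manifest records the
    step id, parameters, elapsed time and output checksums; the manifest is
    appended to ``<workdir>/manifest.jsonl``.
    """
    if not steps:
        raise PipelineError("no steps requested")
    unknown = [s for s in steps if s not in STEP_ORDER]
    if unknown:
        raise PipelineError(f"unknown step id(s) {unknown}; known steps: {list(STEP_ORDER)}")
    positions = [STEP_ORDER.index(s) for s in steps]
    if sorted(positions) != positions or len(set(positions)) != len(positions):
        raise PipelineError(f"steps must be requested in pipeline order {list(STEP_ORDER)}")
    span = [STEP_ORDER[i] for i in range(positions[0], positions[-1] + 1)]
    skipped = [s for s in span if s not in steps and s != "A3"]
    if skipped:
        raise PipelineError(
            f"steps {list(steps)} are not consecutive: {skipped} missing from the chain "
            "(only the external step A3 may be skipped)"
        )

    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict[str, Any]] = []
    for step in steps:
        t0 = time.monotonic()
        logger.info("running step %s", step)
        outputs = _STEP_IMPL[step](config, config.step_params(step))
        entry = {
            "step": step,
            "params": config.step_params(step),
            "seed": config.seed,
            "elapsed_s": round(time.monotonic() - t0, 3),
            "outputs": {
                str(p.relative_to(workdir)): _sha256(p) for p in sorted(set(outputs)) if p.is_file()
            },
        }
        manifest.append(entry)
        with open(workdir / "manifest.jsonl", "a") as fh:
            fh.write(json.dumps(entry, default=str) + "\n")
    return manifest


def external_align_handoff(
    whitelist: str | Path, coords: str | Path, out_dir: str | Path
) -> Path:
    """Prepare the hand-off to an external aligner.

    Copies the whitelist (and coordinates sidecar) into ``out_dir`` and writes
    a documented STARsolo command template; downstream ingestion expects the
    aligner's MTX output directory plus these coordinates.
    """
    whitelist = Path(whitelist)
    if not whitelist.exists() or whitelist.stat().st_size == 0:
        raise PipelineError(f"whitelist {whitelist} is missing or empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shutil.copy(whitelist, out_dir / "whitelist.txt")
    coords = Path(coords)
    if coords.exists():
        shutil.copy(coords, out_dir / "coordinates.tsv")
    template = f"""\
# External alignment hand-off
#
# Align the cDNA reads (2nd sequencing run) with STARsolo using the spatial
# barcode whitelist below, then feed the resulting MTX directory back in as
# steps.C1.sdge_dir together with coordinates.tsv.
#
# Example command (fill in genome index and FASTQ paths):
#
#   STAR --soloType CB_UMI_Simple \\
#        --soloCBwhitelist {out_dir / 'whitelist.txt'} \\
#        --soloCBstart 1 --soloCBlen <K> --soloUMIstart <K+1> --soloUMIlen <L> \\
#        --soloFeatures Gene GeneFull Velocyto \\
#        --genomeDir <genome_index> \\
#        --readFilesIn <cdna.fastq.gz> <barcode.fastq.gz> \\
#        --outSAMtype BAM Unsorted
"""
    (out_dir / "ALIGN_README.txt").write_text(template)
    return out_dir
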