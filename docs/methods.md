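# Methods

## The problem

Submicrometer spatial transcriptomics platforms attach spatial barcodes to
cDNA at <1 µm pitch. Two consequences drive the design of this package:
(i) barcode counts are extremely sparse (a few UMIs per barcode), so no
per-barcode quantity is statistically usable on its own; (ii) any aggregation
large enough to be usable (~10 µm) is larger than the features one wants to
see. subspot's answer is the two-track scheme: learn on coarse,
well-powered bins; apply at a fine, overlapping bin lattice.

## Coordinate geometry

Read identifiers follow the colon-delimited Illumina dialect
`instrument:run:flowcell:lane:tile:x:y[...]`; lane, tile and the local pixel
coordinates are fields 4–7. Tiles are placed on a global canvas by a
user-configurable `TileLayout`: a tile at grid cell (row, col) has origin
`(col·(w+gap), row·(h+gap))` and a local pixel maps to
`origin + pixel·units_per_pixel`. Global coordinates are length units (µm by
convention), origin top-left, y increasing downward; the mapping is injective
whenever local coordinates stay within tile bounds and `gap ≥ 0`. The
instrument-specific tile arrangement is deliberately *not* hard-coded — it is
configuration, with a simple row-major constructor.

Barcode-map rules: barcodes containing `N` are discarded (they can never
match exactly and inflate ambiguity); identical (barcode, coordinate)
duplicates collapse; a barcode seen at two distinct coordinates has no
defined spatial origin and is dropped by default (`collision_policy="drop"`,
counted). Error correction accepts an exact whitelist match or the *unique*
whitelist member at Hamming distance 1; two or more candidates mean the read
is ambiguous and is left uncorrected. Indels and distance-2 corrections are
excluded to keep the operation deterministic and in line with standard
barcode-correction practice.

## Binning

Both tracks use the half-open floor rule: barcode *b* is in the bin/window
anchored at `w` iff `w ≤ coord < w + side` on each axis. The anchor defaults
to the data minimum corner (or the tissue bounding box when one is supplied).
`side` must be an integer multiple of `step`, which makes the overlap count
exact: an interior barcode belongs to exactly `(side/step)²` windows, and the
window-center lattice is `(side/step)²`-fold denser per unit area than the
grid's. Sliding-window counts are computed exactly by first pooling barcodes
into the fine `step` lattice and then summing each window's `ratio × ratio`
block of fine cells as a sparse matrix product; a brute-force
barcode × window double loop is kept in the test suite as the oracle.
Only windows containing at least one barcode are materialized; edge windows
partially covering the extent are retained (they carry tissue-margin signal).

`min_umi` defaults: 0 for plain binning calls. The pipeline's fine-track step
uses `min_umi = 1` because projection requires positive bin totals — the
filter removes only windows that could never be normalized or labelled.
The grid track that feeds clustering uses `min_umi = 10` in the pipeline,
removing near-empty margin bins whose profiles are pure noise.

## Two-track clustering

Reference fit (grid track):

1. **Normalization** `ln(1 + scale·count/bin_total)` with `scale = 10,000` —
   the log1p counts-per-10k convention of the single-cell ecosystem; values
   are invariant to a bin's sequencing depth and zeros map to zero.
2. **HVG selection**: top `n_hvg` genes by variance of normalized values
   (stable sort; ties resolved by gene order). `n_hvg` is capped at the gene
   count; zero-variance genes are excluded so stored SDs are positive.
3. **Scaling**: per-gene z-score clipped at ±10 (clip keeps single hot bins
   from dominating a PC).
4. **PCA**: centered, full SVD (deterministic); default 20 components. The
   stored embedding is `Z · loadings` *without* re-subtracting the PCA mean,
   so out-of-sample projection with the same formula reproduces the
   reference embedding exactly (the constant shift is irrelevant to
   neighbour structure).
5. **Graph + communities**: k-nearest-neighbour graph (k = 20, counting the
   point itself), shared-neighbour Jaccard weights pruned below 1/15, Leiden
   (RB-configuration modularity) at resolution 0.5 with a fixed seed.
   Everything downstream of the seed is deterministic.

Fine-track application: normalize with the model's scale → restrict to the
model's HVGs (genes absent from the query count as zero — the only
imputation consistent with no external data) → z-score with the *reference*
means/SDs, clipped → multiply by the loadings → k-NN majority label transfer
(k = 5) with ties broken by the single nearest reference bin. The label map
therefore has the fine lattice's granularity while every identity decision
was made on statistically solid coarse bins.

Parameter defaults in one place: `scale` 10,000; `clip` 10; `n_hvg` 2000
(capped); `n_pcs` 20; `k_neighbors` 20; `resolution` 0.5; `seed` 0;
transfer `k` 5. On the default synthetic fixture, `k_neighbors` matters most:
small values (≈10) leave the within-domain SNN graph so local that Leiden
subdivides homogeneous domains; 20 is stable.

## Tissue detection

A density raster (UMIs or barcodes per square cell, floor rule) is
thresholded either at the q-quantile of *nonzero* cells (default q = 0.5) or
by Otsu's method; cells pass at `density ≥ threshold`, and the largest
4-connected component (no diagonal bridges) is the tissue, reported with its
bounding rectangle. The quantile rule is a deliberate, simple default for the
common case of a tissue section surrounded by abundant sparse background; in
that regime the median of nonzero cells sits between the background and
tissue density modes. When tissue fills most of the nonzero cells the median
lands *inside* the tissue density distribution and erodes the mask — for such
data Otsu's bimodal split is the better choice (the disk-recovery test uses
it, and recovers the disk area within a few percent).

## RGB rendering

Per pixel (default 1 µm²) and channel, the raw intensity is the sum of UMIs
of that channel's gene set over barcodes in the pixel, taken from that
channel's layer (e.g. spliced vs unspliced). Display intensities are
`min(raw/clip, 1)` with `clip` the 0.99 quantile of nonzero raw values per
channel — robust to single hot pixels, unlike scaling by the maximum. Raw
arrays are retained for exact inspection. Cluster maps paint each bin as a
square of side `step` centered on the bin center; where sliding-window
squares overlap, the nearest bin center wins, giving a single label per
location at step granularity.

## The synthetic study conditions

The default fixture emulates a zonated liver section: a 300 × 300 µm extent,
10,000 barcodes uniform on the instrument pixel lattice (2 × 2 tiles,
0.01 µm/pixel), 200 genes, three vertical stripe domains. Rates per barcode:
0.1 for each of a domain's 60 private markers inside its stripe, 0.02 for 15
housekeeping and 5 mitochondrial genes everywhere, 0.002 flat background —
about 7 UMIs per barcode, the sparse regime these platforms produce. Counts
are Poisson (optionally gamma-mixed for overdispersion); spliced/unspliced
layers split each count binomially (fraction 0.7).

Two generator choices deserve explanation:

* **Stripe boundaries at w/3 + 1.5 and 2w/3 − 1.5 µm.** A boundary lying on
  the 10 µm bin lattice is localized exactly by *both* tracks, making the
  fine track's resolution advantage unmeasurable; real tissue boundaries are
  generic with respect to any bin lattice. The 1.5 µm offset keeps boundary
  bins strongly dominated by one side (≤15% admixture) while remaining off
  the lattice.
* **Bin-level truth = member-barcode majority.** Ground truth is defined per
  barcode; a bin's recoverable identity is the composition it actually
  sampled. A bin straddling a boundary whose draw fell mostly on one side
  *is* a bin of that side. Bins whose sampled composition is near-tied
  (e.g. 21 vs 22 marker UMIs from adjacent zones) are intrinsically
  ambiguous, which bounds any agreement score slightly below unity at finite
  sampling — the measured grid-track ARI of ≈0.993 on the seed-0 fixture
  reflects exactly two such bins out of 900.

Boundary displacement is measured per raster row as the distance from each
true boundary to the nearest midpoint between adjacently-differing labels,
averaged over rows; its precision is limited by the bin-center spacing, which
is the quantitative form of "finer boundaries": ≈1.59 µm for the 2 µm
sliding-window track vs ≈1.74 µm for the 10 µm grid on the default fixture.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: gene-specific capture efficiency and strong
per-gene dispersion differences, segmented cell bodies (domains are
geometric, not cellular), spatial autocorrelation within a domain, doublets,
diffusion/bleed of transcripts between neighbouring positions, realistic
sequencing quality scores, and the alignment step itself (2nd-run cDNA reads
are out of scope; the aligner is an external boundary).

## Numerical details and degenerate inputs

Coordinates round-trip losslessly (written `%.17g`, parsed with round-trip
float precision). MTX output is 1-based, integer, genes-as-rows, gene-major
entry order. Zero-total bins are rejected by normalization with the bin
named; empty FASTQ files, truncated records, empty selections, all-zero
rasters, unknown tiles and missing labels all raise typed errors naming the
offending object. HVG ties break by gene order; transfer ties by nearest
neighbour; constant-metric violin panels fall back to a line (KDE undefined).
All randomness flows through explicit integer seeds; repeated runs are
bit-identical.

## Known limitations

Sliding windows adjacent on the step lattice share most of their contents,
so neighbouring fine-track labels are strongly correlated — the fine map has
higher *boundary* resolution, not 25× more independent measurements. Windows
(~10 µm) remain larger than subcellular compartments, so subcellular
structure is accessible through RGB rendering only, not through clustering.
Label transfer is k-NN majority in PCA space; it cannot create clusters
absent from the reference track. Tissue detection assumes a single dominant
connected section.
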