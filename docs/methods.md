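# Methods

This note records the measurement model, the conventions that were fixed
where several reasonable choices existed, what the synthetic generator does
and does not emulate, and the known limitations.

## Measurement model

All measurements operate on calibrated single-plane integer images
(`pixel_size_um` µm per isotropic pixel; declared bit depth 8, 12 or 16).
A region is a binary pixel set; foreground connectivity is 8-connected
everywhere, matching the wand-tool behaviour on thresholded images that the
interactive workflow relies on.

Per-region statistics follow ImageJ's measurement semantics so that the
downstream defaults (mean + k·SD detection threshold, 0.09–0.5 µm² particle
window) keep their calibrated meaning:

* `area_um2` = pixel count × pixel_size²; `intden` = area × mean;
  `rawintden` = exact integer sum of pixel values (held as a Python int, so
  conservation identities hold exactly, not to float precision).
* mode = most frequent value, ties to the smaller value; median = lower
  middle of the sorted values for even counts.
* skewness and kurtosis are population (÷n) standardized moments, kurtosis
  excess; both reported as 0 when the SD is 0 (constant region).
* **Standard deviation is the population SD (ddof = 0).** ImageJ's Measure
  uses the sample SD (n−1); the population form was chosen for internal
  consistency with the moment family. For the region sizes involved
  (hundreds to tens of thousands of pixels) the relative difference is
  < 1/(2n) and has no practical effect on the mean + 4·SD threshold.

### Otsu thresholding

The histogram always has 256 bins spanning the full nominal range
[0, 2^bits − 1] — not the per-image data range — so 8-/12-/16-bit
acquisitions of the same scene threshold identically and thresholds are
comparable across images taken with identical settings. The threshold is the
top value of the last background bin, and the foreground is *strictly above*
it. The between-class-variance maximization is evaluated in exact integer
arithmetic (the variance at each candidate is a ratio of integers, compared
by cross-multiplication), with ties broken toward the smallest threshold.
This matters: a bimodal image with an empty gap between its classes has a
plateau of mathematically equivalent thresholds, and floating-point noise
would otherwise pick an arbitrary one. A constant-bin image has no threshold
and raises a degenerate-histogram error.

### Region enlargement

`enlarge_region` grows a region by a calibrated Euclidean distance using the
exact Euclidean distance transform: pixel p joins iff
dist(p, region) ≤ d/pixel_size (+1e−9 slack absorbing only the division).
This is deliberately *not* an iterated square/diamond dilation: a 1 µm
enlargement at 1 µm pixels adds the four edge neighbours of an isolated
pixel, excluding diagonals at √2 µm. It is monotone in d and verified
against a brute-force all-pairs oracle.

### 8-bit conversion

Linear map of the full nominal range onto [0, 255] with half-up rounding,
never per-image min–max scaling: absolute comparability across images
acquired with identical settings is a prerequisite of the whole workflow.
8-bit input passes through unchanged.

### Chain-code perimeter and circularity

The perimeter of a dot is the closed Moore trace over the boundary pixel
centres of each 8-connected component: edge steps count 1 pixel, diagonal
steps √2. A single-pixel component is assigned its pixel outline, 4 pixels
(the centre trace would give 0 and an undefined circularity). Circularity
4π·area/perimeter² is capped at 1 because centre-trace perimeters of
few-pixel particles push the raw formula above 1 (a 3×3 square: area 9,
perimeter 8 → raw 1.77). Consequently compact small dots report circularity
exactly 1, and the statistic discriminates only elongated from compact
shapes — which is why the default circularity window is [0, 1] (no
filtering), consistent with the observation that puncta circularity is not a
reliable selector.

## Shell pipeline conventions

* Rows 5–6 measure the *enlarged region including the zeroed bouton
  interior* — faithful to the clear-then-enlarge-then-measure order. The
  mean is therefore diluted by interior zeros while the integrated density
  is shell-pure; the release index uses raw integrated density and is
  insensitive to the choice. An annulus-only measurement (interior excluded)
  is available via `annulus_stats=True`, off by default.
* The release index defaults to shell-protein ÷ shell-membrane raw
  integrated density. Integrated density rather than mean is used because
  the quantity of interest is the *amount* of released marker, not its
  concentration over an arbitrary measurement area. The older
  inside/outside-ratio readout (shell protein ÷ bouton-interior protein) is
  available as `index_mode="inside-outside"`.
* A zero shell-membrane signal makes the index undefined: NaN with a
  warning, never an exception.
* Pixels at the bit-depth maximum inside the measured region trigger a
  saturation warning; quantification proceeds (saturation outside the
  measured area is harmless).

## Puncta pipeline conventions

* The median filter uses a Euclidean-disk footprint: radius 1 is a pixel
  plus its four edge neighbours. Borders use the in-bounds neighbourhood
  only (lower-middle value on even counts).
* Candidate pixels are *strictly above* the threshold, so a constant ROI
  (SD 0 → threshold = mean) yields zero detections rather than the whole
  region.
* The detection threshold's mean/SD come from the median-filtered ROI
  (row 2), the region in which the filter is applied; `threshold_source=
  "unfiltered"` switches to row 3.
* The size window is interpreted as an *area* window in µm² (the particle
  analyzer's convention). `size_unit="um-diameter"` converts a diameter
  window to areas via π(d/2)² for users who calibrated the window from line
  profiles across puncta.
* Merging: the closest pair with centroid distance ≤ the limit merges
  first (ties broken toward the pair with the smaller row-major centroid);
  the merged dot is the pixel-set union with recomputed mass-weighted
  centroid, perimeter and circularity, and re-enters the pool. The fixed
  point is reached when all pairwise distances exceed the limit; merging is
  idempotent. Note that with mass-weighted centroids an equally-sized chain
  at 0.4/0.4 µm spacings does *not* collapse (the first merge moves the pair
  centroid 0.6 µm from the third dot), whereas a 0.3/0.3 µm chain does.
  Merged dots are exempt from re-applying the size filter (filtering
  precedes merging). An edge-to-edge metric is available via
  `merge_metric="edge"`.
* Row 1 measures the binarized (0/255) Otsu foreground of the surround
  channel over the full frame; row 4 measures the protein channel over its
  own Otsu foreground intersected with the ROI (`row4_mode="detection"`
  uses the mean + k·SD region instead — the interactive workflow's wording
  is ambiguous here, so both constructions are emitted rather than guessed).
  A degenerate row-4 region (e.g. a constant protein channel) reports an
  all-zero row with a warning so the count itself is still produced.
* The summary row is computed over the 0/255 binarized detection image
  restricted to dot pixels: mean/median/mode are 255 whenever any dot
  exists, skew/kurtosis 0 (constant values), `intden` = 255 × total dot
  area, `percent_area` = 100 × total dot area / ROI area.
* Dot centroids use pixel centres at (index + 0.5) × pixel_size, x along
  columns; the distance of a centroid to the nearest outside-ROI pixel
  centre is exposed per dot (distance to the "plasma membrane").

## Synthetic generator

The generator renders the geometry the pipelines assume, with exhaustive
ground truth, at the study conditions used throughout the tests: 256×256
frames at 0.1 µm/px, 12 bits, a 2 µm-radius bouton disk (within the 2–5 µm
bouton-diameter range) — sizes chosen to keep a full pipeline run well under
a second so hundreds of seeded replicates fit in a normal test run.

* **Exosome fixtures**: membrane channel = bouton disk at 3000 over
  background 0; protein channel = 300 inside the bouton; both channels get
  *single-pixel* plants (amplitudes 800–2400) in the 1 µm shell annulus.
  Single-pixel plants with no blur make every compartment sum exact, so
  `release_index = S/M` can be asserted to machine precision. Membrane
  plants are restricted to shell pixels more than 1.5 px from the bouton so
  no plant can 8-connect to the bouton component and corrupt the
  segmentation.
* **Autophagosome fixtures**: surround channel = 4 µm-radius disk (the
  postsynaptic DLG region is larger than the bouton; with the mean + 4·SD
  rule a 2 µm region cannot host 10 in-range spots without the threshold
  leaving the 8-bit range — with flat background b, spot level p and spot
  area fraction f, detectability requires f + 4√(f(1−f)) < 1 regardless of
  p − b); protein channel = flat background 320 with uniform spots at 3200,
  disk radius 0.2 µm (optionally elongated up to a stated axis ratio at
  preserved area), pairwise separation ≥ 1 µm. Ground truth records spot
  centres, pixel sets, areas and the expected post-merge count (obtained by
  running the same closest-pair rule on the planted centroids).
* A planted 0.2 µm-radius digital disk covers 13 px; the radius-1 median
  filter removes its four single-pixel tips, so the detected component is
  the 9-px (0.09 µm²) core — exactly at the inclusive lower edge of the
  default size window. The window bounds are treated as inclusive for this
  reason, and the noisy-recovery tests exercise precisely this boundary.
* Degradations are opt-in: additive Gaussian noise (clipped, rounded),
  Poisson noise, Gaussian blur. The noise-free default is the reference
  condition for exact assertions; noisy tests use σ = (peak − background)/10
  and assert ≥95% count recovery over 100 seeded replicates.

What the generator does **not** emulate: optics (no PSF; blur is a generic
Gaussian), multi-bouton chains, SSR texture, anti-marker bleed-through,
uneven illumination, or staining artifacts. Passing the planted-recovery
tests therefore demonstrates the correctness of the measurement logic under
the stated geometry, not robustness to every real-world acquisition defect;
the interactive-era advice to inspect image quality before quantifying still
applies (the `--review` overlay exists for exactly that).

## Determinism and I/O

All randomness flows from explicit seeds through `numpy.random.default_rng`.
Batch processing is stateless per image with sorted input order; identical
inputs and configuration produce byte-identical CSV/JSON outputs, and every
report carries the package version and a SHA-256 hash of the canonical
configuration. Timestamps exist on the in-memory report object only, never
in serialized outputs, to keep them reproducible. 12-bit data is expected in
16-bit TIFF containers with the bit depth declared in configuration; pixel
size comes from TIFF resolution tags (inch or centimetre units) or an
explicit override, and anisotropic pixels are rejected.

## Known limitations

* 2D single-plane only; no z-stacks, time series or 3D measurements.
* The Otsu bin-alignment convention (threshold at a bin boundary of the
  nominal range) can differ from tools that bin over the data range; within
  this package it is exact and deterministic.
* Sub-diffraction exosomes (30–150 nm) are not individually resolvable in
  2D confocal data; the shell pipeline quantifies aggregate shell intensity
  by design and does not count vesicles.
* Circularity saturates at 1 for compact particles of ≲ 30 px (see above);
  it is useful as an elongation filter, not a roundness measure, at these
  scales.
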