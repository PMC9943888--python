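# Methods

## Model

The landscape is modelled as a resistor network on a regular square grid.
Each valid raster cell is a vertex; adjacent cells are joined by a
resistor. With cell resistances r_a, r_b, the inter-cell resistance is
(r_a + r_b)/2 for orthogonal neighbours and √2·(r_a + r_b)/2 for diagonal
neighbours (Queen's case, the default; rook-4 is available). This
"average resistance, 8 neighbours" convention is the established one for
raster circuit analyses; distance scaling beyond the √2 diagonal factor is
deliberately omitted so that a uniform 1×n chain of cell resistance r has
the closed-form end-to-end resistance (n−1)·r.

For a source/ground pair (s, t), unit current is injected at s and t is
held at zero potential. Potentials solve the graph Laplacian system
L·v = e_s − e_t. The effective resistance is v_s − v_t. Branch currents
are potential differences times conductance; the per-cell current is half
the sum of absolute incident branch currents, except the two terminal
cells, which are assigned the full injected current (1). The terminal
convention makes injection sites the map maxima and keeps per-edge maps
mutually comparable. Pairs falling in different graph components get
infinite resistance and an all-zero map with a logged warning — isolated
fragments are a property of real landscapes, not an error.

Current maps are non-negative and sum linearly, so the cumulative
connectivity map is the plain cell-wise sum over all network edges; pairs
are not weighted by their genetic covariance.

## Prioritization conventions

* **Percentiles** use the linear-interpolation quantile over all valid
  cells, zeros included (configurable to positive-only); cells *equal* to
  the threshold are kept (≥ rule), which is conservative — ties enlarge
  the conservation footprint. Both choices are fixed so masks are
  bit-reproducible.
* **Spanning tree**: the tree retaining maximum summed genetic covariance
  (Kruskal; ties break on ascending edge id). The minimum sense is
  available for distance-like weights.
* **Edge betweenness** defaults to shortest-path betweenness with edge
  length = 1/weight, so high-covariance edges attract paths; unit-length
  mode exists for sensitivity. Provided betweenness attributes on the edge
  table are preferred when present, because upstream network analyses may
  use conventions (normalizations, full-network vs tree-restricted counts)
  that cannot be reconstructed from the edge list alone.
* **Pathway delineation** thresholds each edge's *own* current-map
  distribution at the 99/99.5/99.75th percentiles; masks are nested by
  construction.

## Overlay statistics

Polygons are rasterized by cell-centre containment (an all-touched mode
exists for sensitivity). "Proportion of connectivity within PACs" is
value-weighted — the sum of cell values inside over the total — with an
area-weighted (cell-count) mode for comparison. Decile tables bin valid
cells by the 10% quantiles of the cumulative map and report the in/out
split per bin; in + out = 1 per row by construction.

The random baseline translates each PAC polygon independently (optionally
rotated by a random multiple of 90° about its centroid) to a uniform
position fully inside the grid extent, preserving shape and area, and
recomputes the captured proportion per replicate. The observed/mean ratio
is the headline "how much better than random" factor. This is an
interpretation of an equal-area spatial bootstrap; toroidal-shift and
pattern-reconstruction nulls are out of scope.

## Impedance action maps

Land-cover fractions are averaged in a circular moving window of radius
6.44 km (cells whose centres lie within the radius). Windows truncate at
edges and nodata — the mean is over available cells — to avoid biasing
range-edge fractions toward zero. Exceedance is strict (> threshold): a
cell exactly at 25% cultivation does not exceed. Two named rule sets ship
because the source conventions conflict on management zone V:
`cultivation25-all` (default: cultivation > 25% in MZs I, II, IV, V) and
`cultivation5-mzV` (> 5% in MZ V). Canopy > 10% applies in MZs I, II, IV
in both. Resampling to the analysis grid is by centre-point binning
(mean) for fractions and nearest-centre sampling for categorical layers;
no reprojection across CRS is attempted. Areas are reported in km² with
hectare twins (×100).

## Synthetic data

The generators emulate the structure the analysis assumes, not any
particular empirical landscape:

* resistance fields are Gaussian-smoothed white noise affinely rescaled to
  1–161 at 1200 m cells (the value convention of composite range-wide
  resistance surfaces), with optional planted straight corridors of
  resistance 1;
* nodes sample cells with weight ∝ 1/resistance (breeding sites sit in
  permeable habitat);
* edge weights are exp(−decay × effective resistance) + Gaussian noise,
  floored at 1e−6, with decay 0.3 by default — using *effective
  resistance*, not Euclidean distance, keeps network and landscape
  structure mutually consistent, which is what makes corridor-recovery
  tests meaningful;
* PAC blobs are buffers around node positions with the radius bisected to
  hit a target coverage of 0.30 (real PACs cover roughly a quarter to a
  third of the range); MZs are an equal-width vertical-band partition
  labelled I..k (five by default, matching the five modelled zones);
* cultivation is a binary thresholded smooth field, canopy a continuous
  [0, 1] field, both with configurable patch density (default 0.15, a
  moderate level that exercises both exceeding and non-exceeding zones).

The default scene is 50×50 cells with 15 nodes and a complete network
(105 edges) — large enough for spatial structure, small enough for
second-scale runs. The `corridor-50x50` fixture plants a single 21-cell
straight corridor with the two network nodes at its endpoints; 21 cells
was chosen so the 99th-percentile pathway mask (25 cells on a 50×50 grid)
can geometrically contain ≥ 80% of the corridor.

A green synthetic run establishes that the machinery recovers structure it
planted under its own assumptions (isotropic autocorrelation, corridors
aligned with the resistance field, covariance generated from the same
landscape). It does not establish calibration against empirical genetic
data, behaviour under anisotropy, multi-cell source regions, or the scale
of the deposited range-wide surfaces (~14 000 pairs on a continental
grid), which require the archived datasets.

## Numerical choices

* Sparse solves: one LU factorization (SuperLU) per graph component with
  the component's first vertex grounded, reused across all pairs in that
  component; solution shifted so the ground terminal is at zero potential.
  Residual ‖Lv − b‖/‖b‖ must be ≤ 1e−8 or the solve fails loudly.
* Node snapping: coordinates map to the containing cell (boundary ties to
  the lower row, then lower column); a node on nodata falls back to the
  nearest valid cell within one cell radius, else errors naming the node.
* All generator randomness flows from a single integer seed per call via
  `numpy.random.default_rng`; the pipeline derives per-stage seeds from
  one config seed with `SeedSequence.spawn`. No global random state.
* Tie-breaks (tree edges, rankings) resolve on ascending edge id.

## Known limitations

* Single-cell terminals: multi-cell source regions (e.g. lek clusters as
  polygons) are not supported; this may diverge from analyses that used
  focal regions.
* No GeoTIFF I/O — rasters travel as ESRI ASCII grids; georeferencing is
  a lightweight north-up square-cell model with a free-text CRS label and
  no reprojection.
* Advanced solver modes (one-to-all, focal regions, short-circuit
  regions) and mask post-processing (smoothing, least-cost corridors) are
  out of scope.
* The bootstrap baseline constrains placements to the grid bounding box;
  with large nodata oceans the replicate distribution would include
  low-coverage placements, overstating the observed/random ratio.
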