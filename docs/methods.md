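# Methods

This note records the models behind each analysis stage, the defaults and
their rationale, what the synthetic generators do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Track statistics

A track is a time-ordered sequence of positions in µm with strictly
increasing timestamps. Metrics are defined on net and accumulated
displacement:

- accumulated distance: sum of Euclidean step lengths; gaps in frames are
  spanned by a single step (no interpolation), the simplest convention
  consistent with "total length of the track";
- straightness: |net displacement| / accumulated distance;
- forward motion index (FMI): signed net displacement projected on the
  chemoattractant axis, divided by accumulated distance. The axis is a
  configurable unit vector, +y by default, positive toward the attractant;
- mean speed: accumulated distance over elapsed time. Speed could also be
  defined as the mean of instantaneous speeds; the track-level
  distance-over-time definition is used because the metrics are reported
  per track. For uniform frame intervals the two coincide.

Net displacement is computed as the sum of per-step increments rather
than last-minus-first. The two are equal in exact arithmetic; the summed
form makes a straight constant-direction track score straightness and FMI
of exactly 1.0 in floating point, because the identical sum appears in
numerator and denominator.

Degenerate tracks: a single-point track has zero accumulated distance and
undefined shape metrics; scalar functions raise, while the table API
reports NaN with a `degenerate` flag so condition summaries stay total.
Zero-motion tracks score straightness and FMI 0 by convention.

QC filters follow time-lapse tracking practice: minimum number of
timepoints (default 3), optional latest allowed first frame (strictly
less-than), and proximity exclusion that removes tracks starting within a
radius (default 35 µm) of any other cell in the same frame. Whether
proximity should be re-evaluated at every frame is genuinely open; the
start-frame rule is the default and a per-frame mode is provided.

Group comparisons: Kruskal–Wallis omnibus with Dunn's rank-based pairwise
z tests (tie-corrected), Holm-adjusted by default since the test family
does not fix a correction; Kolmogorov–Smirnov, Mann–Whitney and t tests
for two groups. All tests are deterministic given the data.

### Track simulator

Headings follow a persistent random walk with chemotactic drift:

    h_t = normalize((1 - b) * (p * h_{t-1} + (1 - p) * u_rand) + b * g)

with persistence p, drift bias b and unit gradient axis g; step lengths
are Normal(speed_mean·dt, speed_sd·dt) truncated at zero. The convex
mixing in b was chosen so the two endpoints are exact: b = 0 is an
undirected persistent random walk (mean FMI statistically zero) and b = 1
moves every step exactly along the axis (FMI exactly 1). Because
persistence feeds the drifted heading back into the next step, mean FMI
rises steeply with b; it is strictly monotone over a b grid, which is the
property the recovery tests exercise. Defaults (0.01 µm/s mean speed,
10 min frame interval, 73 frames) emulate a 12 h smooth-muscle-cell
invasion time lapse. Tracks reflect at arena edges when an arena is
configured; the default is unbounded so that pure-drift trajectories are
never clipped.

The simulator emulates the *output* of a commercial tracker (per-frame
positions), not detection or linking; real tracks additionally contain
gaps, merges and localisation noise that the generator does not model, so
passing recovery tests demonstrate estimator correctness, not robustness
to tracking artefacts.

## Pillar traction

The observed pillar-top positions are modelled as an affine lattice
o + i·u1 + j·u2 fitted by linear least squares to reference pillars
(outside the cell) only; allowing independent basis vectors absorbs
lattice shear/scale and global rotation instead of assuming an
axis-aligned grid. Displacements are observed minus ideal positions, in
nm. Index assignment uses the nearest ideal site with a spacing/2
rejection radius; ambiguous observations are flagged, never guessed. For
unindexed centroid sets the initial spacing and orientation are estimated
from nearest-neighbour difference vectors (median distance, circular mean
of angles modulo 90°) and refined by alternating assignment and refit.

The noise floor is mean + 2 SD of reference deviation magnitudes. The
underlying statistic is not fixed by convention, so 95th-percentile and
RMS alternatives are exposed; mean + 2 SD was chosen as a conservative
exclusion bound — with isotropic per-axis Gaussian localisation error σ
the magnitudes are Rayleigh(σ) and the floor is σ(√(π/2) + 2√(2−π/2)) ≈
2.563σ, putting the common ~20 nm operating point at σ ≈ 7.8 nm. Fewer
than 10 references triggers a low-confidence flag.

Stiffness chain (units: E in Pa, geometry in µm, k in N/m ≡ nN/nm):

- k_bend = (3/64)·π·E·D⁴/H³ (Euler–Bernoulli cantilever, point load at
  the top);
- corr = (16/3)(L/D)³ / [(16/3)(L/D)³ + ((7+6ν)/3)(L/D) +
  8·T_tilt(ν)·(L/D)²], the ratio of bending compliance to total
  compliance including shear and base tilt of a pillar on an elastic half
  space; corr ∈ (0,1], → 1 for slender pillars, → 0 for stubby ones, and
  is monotone in L/D;
- T_tilt(ν) = (1+ν)/(2π)·{2(1−ν) + (1 − 1/(4(1−ν)))}, dimensionless
  (11/(8π) at ν = 0, finite on [0, 0.5));
- k = k_bend·corr; E_eff = 9k/(4πa) with pillar radius a = D/2.

The bending length L defaults to the pillar height H but is exposed
separately in case the loaded length differs. The substrate modulus E is
a required input; no default is applied silently. Since the assay's
force read-out is k·deflection per pillar, forces are reported in nN; a
per-pillar stress (force over pillar cross-section) is additionally
available because conventions differ between groups.

Centroid detection uses local maxima at roughly the expected spacing
followed by an iterative background-subtracted intensity-weighted
centroid in a circular window of radius spacing/3, re-centred on the
running estimate. The small window keeps contamination from neighbouring
pillar tails (Gaussian spots with FWHM ≈ pillar diameter by default)
below ~0.005 px of bias; noiseless synthetic lattices localise to better
than 0.05 px.

## Focal-adhesion morphometry

The cell mask is pixels above background + offset (default 100 AU) on
the whole-cell stain, keeping the largest connected component and filling
holes (hole-filling is an option because the original acquisition
software's behaviour is not documented). Background defaults to the
median of pixels below Otsu's threshold — robust when the bright cell
occupies much of the field — and can be fixed explicitly.

Foci are connected components above a fixed threshold (default
10000 AU), clipped to the cell mask *before* the area test (the literal
reading of restricting the foci mask to the cell region), and removed if
smaller than 0.5 µm². Labelling connectivity defaults to 8 and is
configurable. Intensities are raw AU; no normalisation precedes the
fixed thresholds.

Edge distance is, per focus, the minimum over its pixels of the exact
Euclidean distance transform of the cell mask, in physical units; the
per-image summary is the mean over foci. The distance-transform
convention measures pixel centre to pixel centre, so a focus touching the
boundary scores one pixel, and comparisons with analytic polygon
geometry agree to one pixel (two half-pixel rasterisation conventions).
On small images the transform is verified exactly against brute-force
nearest-boundary-pixel search.

The adhesion-image generator fills elliptical foci uniformly at a set
intensity inside a polygonal cell; truth areas are analytic (πab) and
truth edge distances come from exact polygon geometry. It does not model
TIRF optics, intensity gradients within adhesions, or multi-cell scenes.

## Turnover

The index averages, over consecutive frame pairs, the exchanged fraction
(appearing + disappearing)/(n_t + n_{t+1}), where an object persists if
it overlaps any object in the next frame by at least `overlap_min`
pixels (default 1; an IoU criterion is available). The index is bounded
in [0,1], hits exactly 0/1 on the static and full-replacement extremes,
and is invariant to relabelling and time reversal. Pairs with no objects
on either side are skipped. This is a transparent overlap-based
reimplementation of the adhesion-map idea; bit-equivalence with any
specific prior tool is not claimed. No registration is applied before
overlap counting.

The simulator places static disk adhesions on a site lattice with
per-frame disappearance probability q and Poisson appearance rate λ;
freed sites are withheld for one frame so an appearing object never
overlaps its predecessor, which makes the pixel-based index equal the
event-log index exactly and lets the binomial oracle score the pipeline.
At birth–death balance the expected pair index is ≈ 2q/(2−q).

## Colocalisation

Thresholds come from the Costes procedure: an orthogonal (total least
squares) regression of channel 2 on channel 1 defines the threshold line;
candidate T1 values are walked downward (one grey level for
integer-valued data, range/512 otherwise, ties toward the higher
threshold) until the pixels below both thresholds are uncorrelated
(Pearson ≤ 0; degenerate below-sets count as uncorrelated). When the
principal axis is vertical — uncorrelated channels with unequal
variances — the slope falls back to ordinary least squares.

tM1 is the summed channel-1 intensity where both channels exceed their
thresholds divided by the summed channel-1 intensity above its own
threshold (the dual-threshold convention of the common plugins); tM2 is
symmetric; a zero-threshold classical mode is also provided. Pearson
above threshold is computed over pixels where at least one channel
exceeds its threshold, excluding zero-zero pixels; degenerate sets are
NaN-flagged rather than forced to a number. Percent volume colocalised
uses pixel counts (the intensity-sum variant would be tM itself).

The pair generator realises a requested colocalised fraction by pixel
counts at constant integer-valued intensity, so the realised fraction
(returned as truth) is exact and tM1 recovers it bit-exactly in the
noiseless case.

## Problem sizes and determinism

Every stochastic test and the acceptance script draw from seeded
`numpy.random.Generator` instances; identical seeds give byte-identical
outputs. Representative sizes: 500 tracks × 73 frames per drift level,
20×20 pillar lattices (≈320 reference pillars), 256²–512² images, 20-frame
turnover movies with ~200 adhesions, and 2000-replicate null calibrations
of the Kruskal–Wallis layer — sizes at which the Monte-Carlo bands in the
tests are comfortably resolved while the whole suite runs in seconds.

## Known limitations

- The track model has no cell–cell interactions, divisions or gaps, and
  drift strength interacts with persistence (see above): FMI-vs-drift is
  monotone but not linear.
- The grid fit assumes a single affine lattice per field; lens distortion
  or stitched tiles violate this.
- Morphometry assumes one cell per image and fixed-AU thresholds;
  cross-instrument data would need recalibrated thresholds.
- The turnover index aggregates events; it does not track individual
  adhesion lifetimes.
- Costes thresholds are undefined for constant channels and can sit at
  the intensity maximum for independent channels; downstream coefficients
  are then NaN-flagged.
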