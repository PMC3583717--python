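# Methods

This note documents the models and procedures `gastroquant` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinate and unit conventions

Pixel coordinates are 0-based and pixel-centered, x right, y down. Embryo
coordinates are A-P / D-V / L-R with anterior = +x; distances in µm, times in
seconds from the start of the recording. Lineage names follow the binary
a/p/l/r (and d/v) suffix nomenclature rooted at founders (AB, MS, E, C, D,
P-lineage); sisters differ in the final letter, left/right homologues by an
l↔r swap anywhere in the name.

## Line profiles and kymographs

Profiles sample the image by bilinear interpolation at exactly 1 px steps
along the line. With `n_lines` parallel lines offset perpendicular to the
requested line: even counts start one-sided at offset 0 (so the default two
lines are the requested line and one line one pixel away, the two-line
convention of the original measurement), odd counts are symmetric about it.
The reported SD is the sample standard deviation across lines (n − 1
denominator; for two lines |a − b|/√2). A kymograph row is the single-line
profile at one frame — the same sampler, so the two operations agree exactly.
Neither background subtraction nor bleach correction is applied; which z
planes constitute "cortical" signal is the caller's choice.

## Focus detection, tracking and contraction events

Foci are local maxima above a configurable intensity threshold with
non-maximum suppression inside `min_sep` px; a focus's intensity is the
integrated signal in a fixed-radius disk (default 3 px). No threshold or
radius is calibrated against published values — the source measurements were
visual — so both are exposed configuration with working defaults.

Tracking links consecutive-frame detections greedily in order of increasing
distance (ties broken by coordinates), capped at `max_link_dist`; unlinked
detections open new tracks. Greedy nearest-neighbour rather than global
assignment is deliberate: cortical focus densities are low and the simple
linker is order-independent and transparent.

A contraction event is a rise-then-fall pulse of the summed intensity of a
group of tracks whose paths converge (final positions within
`cluster_radius`), matching the visual definition of contractions as
converging focus streams. `min_gain` suppresses noise-level pulses; a default
of about twice the per-frame noise SD is recommended.

## Blebs

Given an outline time series and a baseline shape, a bleb is a contiguous run
of frames where area(outline \ baseline) exceeds `min_area`, ending when the
excess regresses; the event records its maximal excess area, onset and
retraction times, and the anterior displacement of the outline centroid from
the last bleb-free frame before onset to the frame after retraction. With
`align="posterior"` the baseline is translated along the anterior axis to
match each frame's posterior extent first — the right choice when the cell
body itself translocates between blebs, since anterior protrusions leave the
posterior edge untouched. The area→translocation relationship is quantified
by unweighted OLS (slope, intercept, r², n, slope CI).

## Contraction–extension coupling

The lag scan regresses extension **position** at time t against intensity at
t − τ for each τ on a grid (default 0–60 s in sampling-interval steps,
negative lags behind a flag for falsification checks), reporting r² of the
simple linear fit (squared Pearson r) over the per-lag overlap window; ties
break toward smaller τ. Position rather than velocity is regressed because
the source measurement plots normalised position; a velocity mode exists.
Traces are normalised by convention: intensity by its maximum, extension by
its final tip position. Off-grid lags are handled by linear interpolation of
the intensity trace.

## Coplanar-division spread model

The measured spread of a tissue at one timepoint is the summed angular extent
of its intervals around the embryo-midpoint circumference (both lateral
halves), as % of 360°; overlapping same-tissue intervals are merged with a
warning, and multiple embryos aggregate as mean ± SD.

The theoretical model assumes perfectly symmetric divisions with measured
timing. The published description states these assumptions but no formula,
so the closed form here is this package's reconstruction and is flagged as
such: a dividing cell's footprint stretches ×2 along the spindle (in-plane
perpendicular ×1, thickness ×½, conserving volume — the cuboidal → columnar
→ cuboidal cycle seen in surface cells), so its circumferential extent
multiplies by the circumferential semi-axis of the stretched unit footprint,

    g(θ) = sqrt(4 sin²θ + cos²θ),   g(0°) = 1, g(36°) ≈ 1.427, g(90°) = 2,

monotone on [0°, 90°]. Per division round the tissue spread multiplies by
the arithmetic mean of g over that round's events (equal-width cells tile,
so the tissue scales by the mean factor; a single event reduces to ×g(θ)),
capped at 100%. Both a per-event-angle mode and a fixed-mean-angle mode
(θ = 36°) are provided because the original calculation does not state which
was used. The measured/theoretical comparison reports residuals and RMS
only — no hypothesis test, matching the purely descriptive original overlay.
An independent polygon-stretching oracle validates g in the test suite.

## Track analysis

Migration paths are smoothed by a centered moving average of width 5
(shrinking windows at the ends). Pairwise movement correlation along the L/R
axis is the Pearson correlation of per-step displacement increments over the
pair's shared timepoints (≥ 3 required, else undefined/NaN): increment
correlation is chosen over raw positions because position correlation is
dominated by shared drift; a positions mode is available, and whether
smoothing precedes correlation is the caller's choice — both orders are
supported. Matrices store raw coefficients; the ±0.8 clip applies only to
rendering. Sister paths can optionally be combined by averaging positions
over shared times. Displacement metrics project net displacement onto an
axis and normalise by embryo length (default: the A-P extent of all tracks'
bounding box). The midline is the total-least-squares line through midpoints
of name-mirrored left/right pairs in the A-P × L-R plane; its angle to the
A-P axis is positive when the midline tilts toward +z (left) with increasing
anterior position, and decreases toward 0° as the embryo symmetrises.

## Morphometrics

Axis extents are vertex-projection extents along the apical direction and its
in-section perpendicular. Flatness is defined as 1 − (min extent / max
extent) ∈ [0, 1]; the original formula is cited to an inaccessible reference,
so this definition is printed in every output header to keep any divergence
auditable. Covering fractions use exact polygon clipping
(intersection-over-target-area with the union of covering outlines); a
Monte-Carlo point-in-polygon oracle exists in the tests only. Ratio
timecourses are fitted by least-squares polynomials (default cubic) on the
per-time mean.

## Synthetic generator

Each generator consumes a single `numpy.random.Generator` seeded from
`SynthConfig.seed` in a documented order, so outputs are bit-reproducible
and the stream can be replayed by independent test oracles. Defaults encode
the study conditions: 2 s movie frame interval, 20 s coupling delay, spindle
angles Normal(36°, 10°), bleb retraction uniform in 30–60 s, and a linear
bleb area→translocation law (default slope 0.02 µm/µm²).

**Cortex movies.** Foci are isotropic Gaussians (σ 1.5 px) born at the cell
periphery at a Poisson rate, drifting centripetally at `flow_speed`, with a
triangular brighten-then-dissolve intensity profile; birth angles are nudged
apart so concurrent foci stay resolvable. Scripted convergence pulses spawn
deterministic focus rings that collapse onto the apical center, giving a
known number of contraction events. The original recordings show but do not
parameterise flows; any smooth inward motion suffices to exercise the
tracker, and no microscope PSF or camera-noise model is attempted.

**Coupled traces.** Integrated intensity is a sum of smooth accumulation
steps (Gaussian-CDF kernels, rise time 2 s, Poisson pulse times in the first
70% of the recording, lognormal amplitudes): myosin recruited in a pulse
persists, so the trace is monotone and maximal at the end, which is what
makes normalisation-to-maximum well defined. The extension tip position is
`coupling_gain ×` the smoothed intensity evaluated `coupling_delay` seconds
earlier, rescaled to end at `extension_plateau`; smoothing is a zero-phase
Gaussian (σ 2 s) standing in for cortex viscoelasticity. A causal
first-order filter would add its own phase lag on top of the transport
delay; the zero-phase choice keeps `coupling_delay` identical to the
recoverable peak-r² lag, which is the property the generator exists to
encode. Trace noise is white, with SD `noise_sd` × the trace maximum
(default 0.03, a free parameter chosen so that single replicates carry
visible noise while the 20 s delay remains identifiable on the 2 s grid; the
same `noise_sd` field is an absolute AU level when applied to movies).
At zero noise the delayed affine relationship is exact. Because the lag
scan's overlap window depends on the lag, single replicates can peak one
grid step from the truth; the median over replicates is unbiased at 20 s.

**Lineage.** Cells live on an ellipsoid (semi-axes 25 × 15 × 15 µm)
parameterised by A-P position u and circumferential angle φ. At each
division time every live cell splits into 'a'/'p' daughters displaced ±2 µm
along a spindle at angle θ ~ Normal(36°, 10°) to the A-P axis (folded to
[0°, 90°]). Cells random-walk slowly in (u, φ); the two lateral sides share
an antisymmetric coherent L/R drift, producing within-side correlation and
cross-side anti-correlation of movement — the bilateral structure the
correlation matrix is designed to reveal. Optional scripts impose a decaying
right-side shear (midline symmetrisation) or a ramped anterior displacement
of a named cell (for displacement-metric checks). Cross-sections consistent
with the division model are rendered by laying each side's cell intervals
out contiguously (left centred at 90°, right at 270°) with widths that
multiply by g(θ) at each recorded division.

**Blebs.** Event counts are Poisson (`bleb_rate` × duration), areas
lognormal around 4 µm², translocation = slope × area + optional noise,
retraction durations uniform in 30–60 s. A renderer realises scripted events
as outline series (circular body, anterior bump of exactly the scripted
excess area, body jump at retraction) for exercising the outline-based
detector.

What the generator does **not** emulate: realistic PSF/noise statistics,
mechanical force balance (no vertex or finite-element model), cell-cell
exclusion, z-resolution anisotropy, or segmentation error in outlines.
Passing tests therefore demonstrate correctness of the measurement code and
internal consistency of the models, not performance on real micrographs.

## Problem sizes and determinism

Default synthetic sizes — 150-frame 64 × 64 movies, 150-sample traces, a
four-founder/three-round lineage (60 tracks), and 100-replicate recovery
studies — were chosen as the smallest instances that exercise every code
path with stable statistics; all tests and the acceptance script run in well
under a minute on one CPU. Pipeline runs with the same config and seed are
byte-identical (no timestamps are written in reproducible mode).

## Known limitations

- g(θ) is a reconstruction of an unpublished calculation; the fixed-mean vs
  per-event-angle ambiguity is preserved as two modes rather than resolved.
- The flatness formula is a stated stand-in for an inaccessible original.
- The lag-scan estimator computes r² over each lag's own overlap window;
  near-flat trace segments at the window edges can bias a single replicate's
  peak by one grid step (see above).
- The outline-based bleb detector assumes non-overlapping events and a rigid
  body between blebs; deforming cells need the event-table route instead.
- AceTree-style input is a simplified single-file nuclei listing, not the
  full directory format.
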