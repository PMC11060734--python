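# Methods

## Scope and design

The package covers the numeric machinery of an ex vivo / in vivo bowel
motility study: motility video → kymograph → contraction-event detection
and CMC scoring; FITC-dextran transit summarisation; neuron-count
statistics; and the three standard single-cell rules (cell filter, PC
selection, marker gate). Published-tool stages that sit around these
rules in practice — normalisation, SCTransform-style regression, dataset
integration, clustering, UMAP, RNA velocity, enrichment — are deliberately
out of scope: they belong to the established toolkits, and re-implementing
them would add nothing testable here.

Detection-, filter- and selection-shaped steps are exposed as
scikit-learn-style estimators (`BowelSegmenter`, `CmcDetector`,
`CellQCFilter`, `PCSelector`, `MarkerFinder`) with `get_params`/
`set_params` and fitted attributes, so they compose with sklearn
pipelines and grid search; module functions wrap them for one-off use.

## Synthetic recordings

The generator renders the bowel as a horizontal bright band (foreground
200, background 30 by default) on a dark field, vertically centred, with
per-column height `round(w(p, t))`. The width function is multiplicative
over programmed waves,

    w(p, t) = baseline · Π_k (1 − A_k · g_k(p, t)) · ripple(t),

where each `g_k` is a separable Gaussian: spatial kernel (σ = the wave's
`spatial_halfwidth_px`) centred on a peak moving at `velocity_px_per_s`
from its origin, and temporal envelope (σ = `temporal_halfwidth_s`)
centred on the onset. "Halfwidth" throughout means the Gaussian σ. An
optional spatially uniform sinusoidal ripple stands in for myogenic
high-frequency activity. Width is clipped below at 20% of baseline so the
silhouette never vanishes (segmentation ground truth stays occlusion
free). Pixel noise is additive Gaussian, clipped to [0, 255]; there is no
motion blur, optics model, curvature, or illumination drift — the
simulator exercises thresholding and geometry, not camera physics, so
passing tests demonstrate algorithmic correctness on clean-contrast
recordings rather than robustness to poor imaging.

Protocol defaults (15 fps, 1920 × 1080, 20-minute duration) mirror the
standard organ-bath recording setup; tests and benchmarks pass smaller
explicit frame sizes and durations, which are their stated problem sizes.
In "TTX mode" (`neurogenic_enabled=False`) neurogenic waves are removed
from both the rendering and the ground-truth event list, emulating
pharmacological blockade; waves flagged myogenic survive. Waves whose
±3σ temporal window misses the recording entirely are excluded from the
ground truth and logged.

Transit profiles are mixtures of Gaussian bolus components over segment
indices 1–19 (σ = 0 gives a point mass), scaled to a fixed total
intensity, with optional additive noise truncated at zero; the true
geometric center is computed from the noiseless profile. QC tables draw
UMIs from a lognormal matched to a typical healthy 10x neuron dataset
(mean 9,128, SD 6,059), genes as a Beta-distributed fraction of UMIs
(mean 0.34, concentration 80 — this construction guarantees
n_genes ≤ n_umis), and percent-mito from a Gamma (mean 5%, SD 2.5%).

All generators take one explicit seed and use a private
`numpy.random.Generator`; identical inputs give byte-identical outputs.

## Segmentation and kymographs

Width is the count of foreground pixels per column, not a
centerline-normal distance; this is exact for a horizontally mounted,
roughly straight specimen and is a documented limitation for curved ones.
Otsu (256-bin) is the default threshold; a fixed threshold is available
for reproducibility. Components use 8-connectivity; equal-size ties go to
the component containing the lexicographically smallest (row, column)
pixel. Columns within `margin_px` (default 10) of either frame edge are
invalid (cannula/pin exclusion). Frames that fail segmentation become
all-invalid kymograph rows — retained to preserve time alignment — and a
recording with more than 10% failed frames is rejected outright.

The per-position baseline is the temporal median, robust to contractions
occupying less than half the recording. The pre/post-TTX comparison is
the per-position ratio of post to pre baselines over jointly valid
positions (zero pre-baseline positions are excluded and logged), with the
mean and n−1 SD as summary.

## Event detection and CMC scoring

Numerical choices, with rationale:

- **Smoothing: 0.2 s × 5 px moving average.** A wave travelling at speed
  v dwells only ~σ_p/|v| seconds at any one position (~0.1 s at
  200 px/s); a temporal window much longer than that attenuates the
  apparent amplitude below threshold, so the window is kept at 3 frames
  at 15 fps. Spatial smoothing (5 px) suppresses column-level
  quantisation.
- **Threshold: 10% width reduction relative to the temporal-median
  baseline**; configurable, as are all criteria, because the manual
  scoring rules this detector operationalises are not numerically
  enumerable.
- **Minimum duration 0.5 s**: long enough to reject flicker, short
  enough that the fastest waves (which cross a short test frame in
  ~1.3 s) are never discarded.
- **Peak trajectory and the "defined peak" rule.** Pixel-count widths are
  quantised, so the minimum at a position is often a flat plateau of
  exactly equal smoothed values; a contiguous plateau is one defined peak
  and its centre is used as the peak time, while disconnected minima at
  ≥10% of spanned positions mark the peak as undefined. Velocity is
  1/slope of the OLS fit of peak time on position (a slope of exactly
  zero maps to +inf); robust regression is deferred.
- **Direction dead-band 5 px/s**: |velocity| below it is "localized".
- **CMC criteria**: antegrade, extent ≥ 50% of the valid length, defined
  peak, neurogenic-capable recording. Neurogenicity is a recording-level
  flag (pre- vs post-TTX), never inferred per event, because neural
  origin is established pharmacologically, not morphologically.
  Frequencies are normalised per 20 minutes.

The recovery benchmark (`enskit.recovery`) programs 1–3 waves per run
with amplitudes uniform on 0.15–0.4 and speeds uniform on 20–200 px/s
with random sign, on a 48 s, 100 × 256 px, 15 fps recording with noise
SD 5 and a 3% myogenic ripple. The wave kernels (σ_p = 15 px, σ_t = 3 s)
come from resolvability arithmetic: successive waves spaced
duration/(n+1) apart must not merge even at amplitude 0.4 (temporal
threshold-crossing radius ≈ 1.5 σ_t per side), and the fastest waves must
stay above the 10% threshold after smoothing (attenuation factor ≈ 0.77
at 200 px/s). For a separable-Gaussian wave the estimated speed is biased
upward by σ_p²/(v σ_t²) — ~6% at 20 px/s with these kernels, negligible
at high speed — which is why measured velocity errors sit in the few
percent range, well inside the 20% check used by the benchmark.

## Transit, counts, and the binomial test

The 19-segment layout (stomach + 12 small intestine + cecum + 5 colon) is
fixed; profiles of any other length are rejected rather than silently
accepted. GC = Σ i·x_i/100 with x the percent distribution; group tables
report per-segment means with SEM (n−1 SD; undefined for single-animal
groups). No exclusion rule is applied for animals with fluorescence
retained in the stomach. Densities are reported per mm² with raw counts
retained; proportions round half-away-from-zero to one decimal, matching
how such percentages are conventionally printed. The two-sided binomial
test uses the small-probability (minimum-likelihood) method with a 1e−7
relative guard against floating-point ties; the double-the-smaller-tail
("central") variant is available as an option. Group-comparison omnibus
tests (Welch ANOVA, Kruskal–Wallis, etc.) are delegated to standard
statistics libraries.

One figure input used in tests deserves a flag: the 30.4% proportion is
reproduced from a reconstructed 7-of-23 cohort; the 23 denominator is
inferred, not printed in the source data, whereas 8 of 9 (88.9%) is
explicit.

## Single-cell rules

Inequality strictness follows the printed cutoffs literally: keep iff
n_genes > 1,500 **and** n_umis < 50,000 **and** pct_mito ≤ 10 ("remove
cells with more than 10%" ⇒ 10.0 itself is kept). Every rejected cell
carries all violated criteria, not just the first.

The PC rule's two clauses are joined as a minimum — whichever fires at
the earlier component wins — because the prose formulation ("…or at
which…") is ambiguous; "contributed <5% of standard deviation" is read as
percent of the total SD sum. The rule is scale-invariant by construction
and never returns more components than supplied.

Marker fold changes are computed on the supplied matrix as given
(assumed normalised upstream), with a pseudocount of 1 in both numerator
and denominator — the convention of the major single-cell frameworks —
exposed as a parameter. "Expressed" means count > 0. Swapping the in- and
out-groups negates ln FC exactly, which the tests assert.

## Verification strategy

Every operation with a tractable alternative implementation is checked
against an independent oracle in the test suite: per-column width counts
against a Python loop; spatiotemporal labeling against a brute-force
flood fill; binomial p-values against exact rational enumeration (and
scipy's implementation); the marker table against a from-scratch
recomputation; detection against the generator's programmed ground truth
across a 20-run seeded sweep of amplitudes and speeds. Closed-form limits
(uniform-profile GC = 10, static videos, unit TTX ratios) are asserted
exactly. `scripts/acceptance.py` re-runs the same computations from
scratch under a caller-supplied seed.

## Known limitations

- Width measurement assumes a horizontally mounted, uncurved specimen.
- The simulator's noise model is additive Gaussian on a two-level image;
  real recordings have shading, drift, and debris the segmenter has not
  been stress-tested against.
- Velocity estimation uses plain OLS on the peak trajectory; outliers
  from partially occluded positions would benefit from a robust fit.
- Overlapping contraction waves that merge into one spatiotemporal
  component are counted as one event by construction.
- The binomial test is exact but the minlike tie guard is a floating-point
  heuristic; for n beyond a few thousand the central method is cheaper
  and more stable.
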