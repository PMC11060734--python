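# enskit

Quantitative toolkit for studies of bowel motility and the enteric nervous
system (ENS): it turns organ-bath video of an ex vivo bowel into
spatiotemporal diameter maps (kymographs), detects propagating contraction
events and scores colonic motor complexes (CMCs), computes the
geometric-center statistic for FITC-dextran intestinal transit, summarises
neuron-count data into densities and proportions with an exact two-sided
binomial test, and implements the standard single-cell RNA-seq QC,
principal-component-selection and marker-gene rules. A seeded
synthetic-data module generates all of these inputs with known ground
truth, so every stage of the pipeline is testable end to end.

Intended users: labs quantifying gut motility phenotypes (e.g. in mouse
models of enteric neuropathy or pseudo-obstruction) who want the analysis
chain between raw recordings and figure statistics to be scripted,
parameterised, and verifiable.

## What it computes

**Kymographs and CMCs.** Each video frame is thresholded (Otsu by
default), the bowel is isolated as the largest 8-connected component, and
bowel width w(p, t) is measured per column p along the proximal–distal
axis. Stacking rows over time gives the diameter matrix. A (t, p) cell is
*contracted* when its smoothed width drops below (1 − a) · baseline(p),
with baseline the temporal median and a = 0.10 by default; 8-connected
spatiotemporal components of this mask are contraction events. The peak
trajectory is the per-position time of minimum width, the propagation
velocity is 1/slope of the least-squares fit of peak time on position, and
an event is scored as a CMC when it is antegrade, spans ≥ 50% of the
bowel, has a defined peak, and was recorded without tetrodotoxin (TTX),
i.e. under neurogenic-capable conditions.

**Transit.** With the bowel cut into 19 ordered segments (stomach, 12
small-intestine, cecum, 5 colon) and x_i the percent of total fluorescence
in segment i, the geometric center is GC = Σ_i i·x_i / 100 ∈ [1, 19].

**Counting statistics.** Density = count / field area (per mm²; standard
field areas 180,625 µm² and 90,312.5 µm² are provided as constants),
proportions are one-decimal percentages, and categorical phenotypes use
the exact small-probability two-sided binomial test
p = Σ { P(X = j) : P(X = j) ≤ P(X = k) }.

**Single-cell rules.** Keep a cell iff n_genes > 1,500, n_UMIs < 50,000
and percent-mito ≤ 10; select principal components by the earlier of the
<5%-contribution-with-90%-cumulative clause and the <0.1-point flatness
clause; call a gene a cluster marker only if expressed in >10% of the
cluster's cells and ln fold-change of mean expression exceeds 0.25.

## Worked example

Simulate a 24 s organ-bath recording (80 × 200 px, 15 fps) containing one
programmed antegrade wave (80 px/s, 30% amplitude), rebuild the kymograph
from the rendered frames, and detect events:

```python
import numpy as np
from enskit import (MotilitySpec, WaveSpec, generate_motility_video,
                    build_kymograph, CmcDetector)
from enskit.segmentation import BowelSegmenter

wave = WaveSpec(onset_s=12.0, origin_fraction=0.5, velocity_px_per_s=80.0,
                amplitude_fraction=0.3, spatial_halfwidth_px=15.0,
                temporal_halfwidth_s=3.0)
spec = MotilitySpec(duration_s=24.0, frame_height_px=80, frame_width_px=200,
                    baseline_width_px=40.0, wave_list=(wave,), noise_sd=5.0,
                    seed=7)
frames, truth = generate_motility_video(spec)
dm = build_kymograph(frames, BowelSegmenter(), frame_rate_fps=15.0)
det = CmcDetector().fit(dm)
summary = det.summarize(neurogenic=True)
ev = det.events_[0]
print(f"events detected: {det.n_events_}")
print(f"velocity: {ev.velocity_px_per_s:.1f} px/s ({ev.direction}), "
      f"extent {ev.extent_fraction:.2f}")
print(f"CMC count: {summary.cmc_count}, "
      f"frequency {summary.frequency_per_20min:.1f} per 20 min")
```

prints

```
events detected: 1
velocity: 80.4 px/s (antegrade), extent 1.00
CMC count: 1, frequency 50.0 per 20 min
```

The single programmed wave is recovered as one full-length antegrade
event; its estimated speed (80.4 px/s) is within 0.5% of the programmed
80 px/s, and it satisfies all CMC criteria — one event in 24 s normalises
to 50 per 20 minutes. The transit and counting statistics are one-liners:

```python
from enskit import geometric_center, proportion, binomial_two_sided
raw = np.array([120, 300, 900, 2400, 3000, 1800, 700, 300, 180, 120,
                80, 40, 20, 10, 10, 5, 5, 3, 2], float)
geometric_center(raw)        # 5.11  (marker still in proximal small bowel)
proportion(8, 9)             # 88.9  (% affected, one-decimal rounding)
binomial_two_sided(8, 9, .5) # 0.0391
```

The same operations are available from the shell via the `enskit` CLI
(`enskit simulate video|transit|qc`, `enskit segment`, `enskit kymograph`,
`enskit detect`, `enskit ttx-compare`, `enskit transit`, `enskit
ensquant`, `enskit sc-filter`, `enskit sc-pcs`, `enskit sc-markers`); run
any subcommand with `--help`.

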