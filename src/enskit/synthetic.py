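"""Seeded synthetic inputs with known ground truth.

The generators here emulate the raw data of an ex vivo bowel-motility study:

* organ-bath video of a cannulated bowel, rendered as a bright horizontal
  band on a dark background whose per-column height follows a programmed
  width function w(position, time) driven by propagating contraction waves;
* FITC-dextran transit fluorescence over the 19-segment bowel partition
  (stomach, 12 small-intestine segments, cecum, 5 colon segments);
* per-cell single-cell QC tables (genes, UMIs, percent-mitochondrial reads);
* tiny labeled gene x cell expression matrices for marker-rule tests.

Every generator takes an explicit seed and uses a single private
``numpy.random.Generator``; no global random state is touched.  Identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fractional width floor: the silhouette never narrows below this fraction
#: of the resting width, so the bowel band never vanishes from a frame.
MIN_WIDTH_FRACTION = 0.20


@dataclass(frozen=True)
class WaveSpec:
    """One programmed contraction wave.

    The wave is a separable Gaussian disturbance: a spatial kernel (sigma
    ``spatial_halfwidth_px``) centred on a peak that travels at
    ``velocity_px_per_s`` from ``origin_fraction`` of the bowel length, and
    a temporal envelope (sigma ``temporal_halfwidth_s``) centred on
    ``onset_s``, the moment of maximal contraction strength.  Positive
    velocity propagates proximal-to-distal (antegrade).
    """

    onset_s: float
    origin_fraction: float
    velocity_px_per_s: float
    amplitude_fraction: float
    spatial_halfwidth_px: float = 20.0
    temporal_halfwidth_s: float = 4.0
    neurogenic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.amplitude_fraction < 1.0:
            raise ValueError(
                f"amplitude_fraction must be in (0, 1), got {self.amplitude_fraction}"
            )
        if not 0.0 <= self.origin_fraction <= 1.0:
            raise ValueError(
                f"origin_fraction must be in [0, 1], got {self.origin_fraction}"
            )
        if self.spatial_halfwidth_px <= 0 or self.temporal_halfwidth_s <= 0:
            raise ValueError("halfwidths must be positive")


@dataclass(frozen=True)
class MotilitySpec:
    """Parameters for one simulated organ-bath recording.

    Defaults mirror the recording protocol the pipeline is designed for:
    a 20-minute video at 15 frames per second, 1920 x 1080 pixels.  Tests
    and benchmarks pass smaller explicit sizes.
    """

    duration_s: float = 1200.0
    frame_rate_fps: float = 15.0
    frame_height_px: int = 1080
    frame_width_px: int = 1920
    baseline_width_px: float = 400.0
    wave_list: tuple[WaveSpec, ...] = ()
    myogenic_ripple_amplitude: float = 0.0
    myogenic_ripple_hz: float = 0.5
    neurogenic_enabled: bool = True
    noise_sd: float = 5.0
    foreground_intensity: float = 200.0
    background_intensity: float = 30.0
    pixel_size_mm_per_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be positive")
        if not 0.0 <= self.myogenic_ripple_amplitude < 1.0:
            raise ValueError("myogenic ripple amplitude must be in [0, 1)")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground_intensity must exceed background_intensity")
        if self.baseline_width_px >= self.frame_height_px:
            raise ValueError("baseline_width_px must be smaller than frame height")
        object.__setattr__(self, "wave_list", tuple(self.wave_list))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_fps))


@dataclass(frozen=True)
class MotilityGroundTruth:
    """Programmed events plus the evaluable true width function.

    ``events`` lists the waves actually rendered (neurogenic waves are
    dropped entirely in TTX mode, i.e. when ``neurogenic_enabled`` is
    false); ``width_function`` maps (position_px, time_s) -> true width in
    pixels, before rounding and camera noise.
    """

    events: tuple[WaveSpec, ...]
    width_function: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(
        repr=False, compare=False, default=None
    )
    baseline_width_px: float = 0.0

    @property
    def n_events(self) -> int:
        return len(self.events)


def _active_waves(spec: MotilitySpec) -> tuple[WaveSpec, ...]:
    """Waves that are rendered: neurogenic-gated and overlapping the video."""
    active = []
    for w in spec.wave_list:
        if w.neurogenic and not spec.neurogenic_enabled:
            continue
        lo = w.onset_s - 3.0 * w.temporal_halfwidth_s
        hi = w.onset_s + 3.0 * w.temporal_halfwidth_s
        if hi < 0.0 or lo > spec.duration_s:
            logger.info("wave at onset %.2f s lies outside the recording; skipped", w.onset_s)
            continue
        active.append(w)
    return tuple(active)


def make_width_function(spec: MotilitySpec) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Return the noiseless true width function w(position_px, time_s).

    Width is multiplicative over active waves,
    ``w = baseline * prod_k (1 - A_k * g_k(p, t)) * ripple(t)``,
    with each ``g_k`` a separable Gaussian in position (around the moving
    peak) and time (around the onset), and is clipped below at
    ``MIN_WIDTH_FRACTION`` of baseline.
    """
    waves = _active_waves(spec)
    base = spec.baseline_width_px
    width_px = spec.frame_width_px
    ra = spec.myogenic_ripple_amplitude
    rf = spec.myogenic_ripple_hz

    def w(p: np.ndarray, t: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        t = np.asarray(t, dtype=float)
        out = np.ones(np.broadcast(p, t).shape, dtype=float)
        for wv in waves:
            center = wv.origin_fraction * (width_px - 1) + wv.velocity_px_per_s * (
                t - wv.onset_s
            )
            g = np.exp(
                -((p - center) ** 2) / (2.0 * wv.spatial_halfwidth_px**2)
                - ((t - wv.onset_s) ** 2) / (2.0 * wv.temporal_halfwidth_s**2)
            )
            out = out * (1.0 - wv.amplitude_fraction * g)
        if ra > 0:
            out = out * (1.0 - ra * 0.5 * (1.0 + np.sin(2.0 * np.pi * rf * t)))
        return np.clip(base * out, MIN_WIDTH_FRACTION * base, None)

    return w


def generate_motility_video(spec: MotilitySpec) -> tuple[np.ndarray, MotilityGroundTruth]:
    """Render a synthetic organ-bath video.

    Returns ``(frames, truth)`` where ``frames`` is a ``(T, H, W)`` uint8
    stack.  Each frame shows a horizontal bright band, vertically centred,
    whose height in column p at frame time t equals ``round(w(p, t))``;
    Gaussian pixel noise of sd ``spec.noise_sd`` is added and the result is
    clipped to [0, 255].
    """
    waves = _active_waves(spec)
    wfun = make_width_function(spec)
    T, H, W = spec.n_frames, spec.frame_height_px, spec.frame_width_px
    times = np.arange(T) / spec.frame_rate_fps
    cols = np.arange(W, dtype=float)
    widths = wfun(cols[None, :], times[:, None])  # (T, W)
    heights = np.round(widths).astype(np.int64)

    center = H / 2.0
    top = np.round(center - heights / 2.0).astype(np.int64)  # (T, W)
    bottom = top + heights
    rows = np.arange(H, dtype=np.int64)
    band = (rows[None, :, None] >= top[:, None, :]) & (rows[None, :, None] < bottom[:, None, :])

    frames = np.where(band, spec.foreground_intensity, spec.background_intensity).astype(
        np.float32
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape).astype(np.float32)
    frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)

    truth = MotilityGroundTruth(
        events=waves, width_function=wfun, baseline_width_px=spec.baseline_width_px
    )
    return frames, truth


# ---------------------------------------------------------------------------
# FITC-dextran transit profiles


def generate_transit_profile(
    components: Sequence[tuple[float, float, float]] = ((9.0, 2.0, 1.0),),
    n_segments: int = 19,
    noise_sd: float = 0.0,
    total_intensity: float = 10_000.0,
    seed: int | None = None,
) -> tuple[np.ndarray, float]:
    """Simulate one animal's segment fluorescence readings.

    ``components`` is a sequence of ``(center, sigma, weight)`` Gaussian
    bolus components over segment indices 1..n_segments; ``sigma == 0``
    places the whole component on the nearest integer segment.  Returns
    ``(raw, true_gc)`` where ``raw`` are nonnegative intensities and
    ``true_gc`` is the geometric centre of the noiseless profile,
    ``sum_i i * x_i / 100`` with ``x`` the percent-of-total distribution.
    """
    idx = np.arange(1, n_segments + 1, dtype=float)
    weights = np.zeros(n_segments)
    for center, sigma, weight in components:
        if weight < 0:
            raise ValueError("component weights must be nonnegative")
        if sigma < 0:
            raise ValueError("component sigma must be nonnegative")
        if sigma == 0:
            k = int(round(center))
            if not 1 <= k <= n_segments:
                raise ValueError(f"delta component centre {center} outside segments")
            weights[k - 1] += weight
        else:
            weights += weight * np.exp(-((idx - center) ** 2) / (2.0 * sigma**2))
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate transit profile: all component weights are zero")

    clean = total_intensity * weights / total
    percent = 100.0 * clean / clean.sum()
    true_gc = float(np.sum(idx * percent) / 100.0)

    raw = clean
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = np.clip(clean + rng.normal(0.0, noise_sd, size=n_segments), 0.0, None)
        if raw.sum() <= 0:  # pragma: no cover - absurd noise levels only
            raise ValueError("noise drove the whole profile to zero")
    return raw, true_gc


# ---------------------------------------------------------------------------
# Single-cell QC tables and toy expression matrices


def generate_qc_table(
    n_cells: int,
    umi_mean: float = 9128.41,
    umi_sd: float = 6058.95,
    gene_fraction_mean: float = 0.34,
    gene_fraction_concentration: float = 80.0,
    mito_mean_pct: float = 5.0,
    mito_sd_pct: float = 2.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a per-cell QC table (n_genes, n_umis, pct_mito).

    UMI counts are lognormal with the given mean/sd (defaults match a
    typical healthy 10x neuron dataset: 9,128 +/- 6,059 UMIs and roughly
    3,106 genes per cell); the detected-gene count is a Beta-distributed
    fraction of each cell's UMIs, which guarantees ``n_genes <= n_umis``;
    percent-mitochondrial reads are Gamma distributed, clipped to [0, 100].
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0.0 < gene_fraction_mean < 1.0:
        raise ValueError(
            "gene_fraction_mean must lie strictly in (0, 1): values >= 1 would "
            "imply n_genes > n_umis"
        )
    if umi_mean <= 0 or umi_sd <= 0 or mito_mean_pct < 0:
        raise ValueError("distribution parameters must be positive")

    rng = np.random.default_rng(seed)
    cv2 = (umi_sd / umi_mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(umi_mean) - sigma2 / 2.0
    n_umis = np.maximum(1, np.round(rng.lognormal(mu, np.sqrt(sigma2), n_cells))).astype(int)

    a = gene_fraction_mean * gene_fraction_concentration
    b = (1.0 - gene_fraction_mean) * gene_fraction_concentration
    frac = rng.beta(a, b, n_cells)
    n_genes = np.maximum(1, np.round(frac * n_umis)).astype(int)
    n_genes = np.minimum(n_genes, n_umis)

    if mito_sd_pct > 0:
        shape = (mito_mean_pct / mito_sd_pct) ** 2
        scale = mito_sd_pct**2 / mito_mean_pct
        pct_mito = np.clip(rng.gamma(shape, scale, n_cells), 0.0, 100.0)
    else:
        pct_mito = np.full(n_cells, float(mito_mean_pct))

    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(n_cells)],
            "n_genes": n_genes,
            "n_umis": n_umis,
            "pct_mito": pct_mito,
        }
    )


def generate_labeled_expression(
    n_genes: int = 20,
    cells_per_cluster: Sequence[int] = (30, 30),
    marker_genes_per_cluster: int = 3,
    marker_fold: float = 8.0,
    base_rate: float = 0.5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a tiny gene x cell count matrix with planted cluster markers.

    Each cluster gets ``marker_genes_per_cluster`` genes whose Poisson rate
    is ``marker_fold`` times the background ``base_rate`` inside the
    cluster.  Returns ``(expr, labels)`` with genes as rows.
    """
    rng = np.random.default_rng(seed)
    n_clusters = len(cells_per_cluster)
    if n_genes < n_clusters * marker_genes_per_cluster:
        raise ValueError("not enough genes for the requested planted markers")
    labels = np.repeat([f"c{k}" for k in range(n_clusters)], cells_per_cluster)
    n_cells = len(labels)
    rates = np.full((n_genes, n_cells), base_rate)
    for k in range(n_clusters):
        genes = slice(k * marker_genes_per_cluster, (k + 1) * marker_genes_per_cluster)
        rates[genes, labels == f"c{k}"] = base_rate * marker_fold
    counts = rng.poisson(rates)
    expr = pd.DataFrame(
        counts,
        index=[f"gene_{g:03d}" for g in range(n_genes)],
        columns=[f"cell_{c:03d}" for c in range(n_cells)],
    )
    return expr, pd.Series(labels, index=expr.columns, name="cluster")
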