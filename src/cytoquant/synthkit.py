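"""Synthetic trace ensembles, two-plane image sequences, and knockdown
datasets with full ground truth.

Everything downstream of acquisition can be exercised against these
generators: traces carry injected release events (instant step, exponential
decay, photobleaching, Gaussian noise), image sequences render cells,
nuclei, vignetting and in/out-of-focus lipoplexes in two z-planes, and
knockdown datasets are drawn from a known kinetic model.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knockdown import KineticModel

__all__ = [
    "SyntheticTraceSpec",
    "SyntheticSceneSpec",
    "GroundTruth",
    "gen_trace_ensemble",
    "gen_image_sequence",
    "gen_reference_stack",
    "gen_knockdown_dataset",
    "vignette_field",
]


@dataclass
class SyntheticTraceSpec:
    n_cells: int = 100
    n_frames: int = 120
    frame_interval: float = 5.0          # minutes
    event_rate: float = 0.1              # events / cell / hour
    magnitude_bounds: tuple = (1.0, 40.0)  # nM, log-uniform
    decay_rate_k: float = 0.05           # per frame
    noise_sd: float = 0.15               # nM-equivalents
    bleach_rate: float = 0.0             # fraction lost per frame
    baseline: float = 0.0                # nM-equivalents
    calib_error_rel: float = 0.08
    seed: int = 0
    events_per_cell: int | None = None   # exact count overrides event_rate
    min_event_frame: int = 12
    event_margin: int = 20               # frames kept after the last event slot

    def __post_init__(self) -> None:
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        lo, hi = self.magnitude_bounds
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("magnitude bounds must be positive and ordered")
        if not (0 <= self.bleach_rate < 1):
            raise ValueError("bleach_rate must be in [0, 1)")
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")


@dataclass
class SyntheticSceneSpec:
    image_shape: tuple = (256, 256)
    pixel_size: float = 0.35             # µm
    z_spacing: float = 4.0               # µm
    cell_radius_um: float = 12.0
    nucleus_radius_um: float = 5.0
    n_lipoplexes: int = 10
    lipoplex_intensity: tuple = (500.0, 2000.0)  # uniform bounds
    vignette_min: float = 0.8            # corner / center intensity ratio
    psf_sigma_infocus: float = 1.0       # px
    psf_sigma_outfocus: float = 4.0      # px
    reference_level: float = 1000.0      # intensity of 1 µM at field center
    egfp_level: float = 500.0
    nuclear_level: float = 800.0
    background: float = 10.0
    noise_scale: float = 0.0             # 0 disables Poisson-Gaussian noise
    read_noise_sd: float = 2.0
    cell_drift_px_per_frame: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0 < self.vignette_min <= 1):
            raise ValueError("vignette_min must be in (0, 1]")
        if self.psf_sigma_outfocus <= self.psf_sigma_infocus:
            raise ValueError("psf_sigma_outfocus must exceed psf_sigma_infocus")
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus radius must be smaller than cell radius")


@dataclass
class GroundTruth:
    """Oracle for all downstream stages."""

    events: pd.DataFrame                   # track_id, frame, magnitude_nM
    traces_clean: np.ndarray | None = None  # (n_cells, n_frames) noiseless nM
    bleach_curve: np.ndarray | None = None
    cell_masks: np.ndarray | None = None    # (t, y, x) labels
    nucleus_masks: np.ndarray | None = None
    lipoplex_masks: np.ndarray | None = None  # (t, z, y, x) labels
    vignette: np.ndarray | None = None
    centroids: np.ndarray | None = None     # (t, n_cells, 2) row/col
    doses: np.ndarray | None = None
    knockdown_curves: np.ndarray | None = None
    times_h: np.ndarray | None = None
    mitosis: dict = field(default_factory=dict)
    apoptosis: dict = field(default_factory=dict)

    def validate(self, n_frames: int | None = None) -> None:
        if (self.events["magnitude_nM"] <= 0).any():
            raise ValueError("ground-truth magnitudes must be strictly positive")
        if n_frames is not None and (self.events["frame"] >= n_frames).any():
            raise ValueError("event frame beyond trace length")


# ---------------------------------------------------------------------------
# trace ensembles


def gen_trace_ensemble(spec: SyntheticTraceSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-cell concentration traces with injected release events.

    trace = (baseline + sum of decaying event steps) * cumulative bleaching
            + Gaussian noise

    Returns a long TraceTable (track_id, frame, time_min, conc_nM) and the
    :class:`GroundTruth` listing every injected event.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_cells, spec.n_frames
    lo, hi = spec.magnitude_bounds

    ev_rows = []
    clean = np.full((n, T), spec.baseline, dtype=float)
    t = np.arange(T)
    for c in range(n):
        frames = _draw_event_frames(spec, rng)
        for fr in frames:
            mag = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            ev_rows.append((c, int(fr), mag))
            m = t >= fr
            clean[c, m] += mag * np.exp(-spec.decay_rate_k * (t[m] - fr))

    bleach = (1.0 - spec.bleach_rate) ** t
    noisy = clean * bleach + rng.normal(0.0, spec.noise_sd, size=(n, T))

    table = pd.DataFrame({
        "track_id": np.repeat(np.arange(n), T),
        "frame": np.tile(t, n),
        "time_min": np.tile(t * spec.frame_interval, n),
        "conc_nM": noisy.ravel(),
    })
    truth = GroundTruth(
        events=pd.DataFrame(ev_rows, columns=["track_id", "frame", "magnitude_nM"]),
        traces_clean=clean,
        bleach_curve=bleach,
    )
    truth.validate(T)
    return table, truth


def _draw_event_frames(spec: SyntheticTraceSpec, rng: np.random.Generator) -> np.ndarray:
    first, last = spec.min_event_frame, spec.n_frames - spec.event_margin
    if last <= first:
        first, last = spec.min_event_frame, spec.n_frames - 1
    if spec.events_per_cell is not None:
        k = spec.events_per_cell
        return np.sort(rng.choice(np.arange(first, last), size=k, replace=False)) if k else np.array([], int)
    p = spec.event_rate * spec.frame_interval / 60.0
    hits = rng.random(spec.n_frames) < p
    hits[:first] = False
    hits[last:] = False
    return np.flatnonzero(hits)


# ---------------------------------------------------------------------------
# image sequences


def vignette_field(shape, vignette_min: float) -> np.ndarray:
    """Radial multiplicative field: 1 at center, ``vignette_min`` at corners."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy ** 2 + cx ** 2)
    return 1.0 - (1.0 - vignette_min) * r2


def to_intensity(conc_nm: float, position, scene: SyntheticSceneSpec) -> float:
    """Noiseless rendered intensity of a cytosolic concentration at a
    position — the synthetic inverse of ``calibration.to_concentration``."""
    vig = vignette_field(scene.image_shape, scene.vignette_min)
    r, c = int(round(position[0])), int(round(position[1]))
    return conc_nm / 1000.0 * scene.reference_level * vig[r, c]


def _gaussian_blob(shape, center, sigma, amplitude):
    h, w = shape
    cy, cx = center
    y0, y1 = max(0, int(cy - 4 * sigma)), min(h, int(cy + 4 * sigma) + 1)
    x0, x1 = max(0, int(cx - 4 * sigma)), min(w, int(cx + 4 * sigma) + 1)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    patch = amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return (slice(y0, y1), slice(x0, x1)), patch


def gen_image_sequence(
    scene: SyntheticSceneSpec,
    trace_truth: GroundTruth,
    seed: int = 0,
) -> tuple[dict, GroundTruth]:
    """Render a two-plane multichannel sequence from a trace ground truth.

    Returns ``images`` (dict with keys ``siRNA`` (t, 2, y, x), ``eGFP`` and
    ``nuclear`` (t, y, x)) and a new :class:`GroundTruth` carrying per-frame
    label masks, centroids and the true vignette field.
    """
    if trace_truth.traces_clean is None:
        raise ValueError("trace ground truth must carry noiseless traces")
    rng = np.random.default_rng(seed)
    n_cells, T = trace_truth.traces_clean.shape
    h, w = scene.image_shape
    px = scene.pixel_size
    r_cell = scene.cell_radius_um / px
    r_nuc = scene.nucleus_radius_um / px

    centers0 = _place_cells(n_cells, (h, w), r_cell, rng)
    if centers0.shape[0] < n_cells:
        raise ValueError(
            f"scene too small for {n_cells} cells of radius {r_cell:.0f} px")
    vig = vignette_field((h, w), scene.vignette_min)
    drift = np.asarray(scene.cell_drift_px_per_frame, dtype=float)

    # lipoplexes: fixed positions, random plane, lognormal-ish intensity
    lip_pos = rng.uniform(0, [h, w], size=(scene.n_lipoplexes, 2))
    lip_plane = rng.integers(0, 2, size=scene.n_lipoplexes)
    lip_int = rng.uniform(*scene.lipoplex_intensity, size=scene.n_lipoplexes)

    bleach = trace_truth.bleach_curve if trace_truth.bleach_curve is not None else np.ones(T)

    sirna = np.zeros((T, 2, h, w), dtype=float)
    egfp = np.zeros((T, h, w), dtype=float)
    nuclear = np.zeros((T, h, w), dtype=float)
    cell_masks = np.zeros((T, h, w), dtype=np.int32)
    nuc_masks = np.zeros((T, h, w), dtype=np.int32)
    lip_masks = np.zeros((T, 2, h, w), dtype=np.int32)
    centroids = np.zeros((T, n_cells, 2), dtype=float)

    yy, xx = np.mgrid[0:h, 0:w]
    for fr in range(T):
        centers = centers0 + drift * fr
        centroids[fr] = centers
        for ci, (cy, cx) in enumerate(centers, start=1):
            cell = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_cell ** 2
            nuc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_nuc ** 2
            if not cell.any():
                continue
            cell_masks[fr][cell] = ci
            nuc_masks[fr][nuc] = ci
            conc = trace_truth.traces_clean[ci - 1, fr] * bleach[fr]
            level = conc / 1000.0 * scene.reference_level
            cyto = cell & ~nuc
            sirna[fr, 0][cyto] += level
            egfp[fr][cell] += scene.egfp_level
            nuclear[fr][nuc] += scene.nuclear_level
        for li in range(scene.n_lipoplexes):
            zin = lip_plane[li]
            zout = 1 - zin
            blob = _gaussian_blob((h, w), lip_pos[li], scene.psf_sigma_infocus, lip_int[li])
            if blob is not None:
                sl, patch = blob
                sirna[fr, zin][sl] += patch
                lip_masks[fr, zin][sl][patch > 0.2 * lip_int[li]] = li + 1
            blob = _gaussian_blob((h, w), lip_pos[li], scene.psf_sigma_outfocus, lip_int[li] * 0.15)
            if blob is not None:
                sl, patch = blob
                sirna[fr, zout][sl] += patch

        for z in range(2):
            sirna[fr, z] = sirna[fr, z] * vig + scene.background
        egfp[fr] = egfp[fr] * vig + scene.background
        nuclear[fr] = nuclear[fr] * vig + scene.background

    if scene.noise_scale > 0:
        for arr in (sirna, egfp, nuclear):
            arr += rng.normal(0.0, scene.read_noise_sd, size=arr.shape)
            arr += rng.normal(0.0, np.sqrt(np.maximum(arr, 0) * scene.noise_scale))

    images = {"siRNA": sirna, "eGFP": egfp, "nuclear": nuclear}
    truth = GroundTruth(
        events=trace_truth.events.copy(),
        traces_clean=trace_truth.traces_clean,
        bleach_curve=bleach,
        cell_masks=cell_masks,
        nucleus_masks=nuc_masks,
        lipoplex_masks=lip_masks,
        vignette=vig,
        centroids=centroids,
    )
    return images, truth


def _place_cells(n, shape, radius, rng):
    """Jittered grid placement with no overlap."""
    h, w = shape
    pitch = 2.4 * radius
    rows = int((h - 2 * radius) // pitch) + 1
    cols = int((w - 2 * radius) // pitch) + 1
    pts = []
    for i in range(rows):
        for j in range(cols):
            cy = radius + 4 + i * pitch + rng.uniform(-0.1, 0.1) * radius
            cx = radius + 4 + j * pitch + rng.uniform(-0.1, 0.1) * radius
            if cy + radius < h and cx + radius < w:
                pts.append((cy, cx))
    return np.asarray(pts[:n], dtype=float)


def gen_reference_stack(
    scene: SyntheticSceneSpec,
    n_planes: int = 30,
    peak_plane: float | None = None,
    column_halfwidth_planes: int = 8,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic 1 µM reference and blank z-stacks matching the scene optics.

    The axial profile is flat-topped (a uniform fluid column much thicker
    than the focal depth) with sub-half-maximum tails, so the FWHM interval
    selects exactly the full-intensity planes and the projection equals
    ``reference_level`` times the vignette field.  The blank stack is
    background only.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.image_shape
    vig = vignette_field((h, w), scene.vignette_min)
    z = np.arange(n_planes, dtype=float)
    mu = (n_planes - 1) / 2.0 if peak_plane is None else peak_plane
    dist = np.maximum(np.abs(z - mu) - column_halfwidth_planes, 0.0)
    profile = np.where(dist == 0, 1.0, 0.4 * np.exp(-dist))
    ref = profile[:, None, None] * scene.reference_level * vig[None] + scene.background
    blank = np.full((n_planes, h, w), scene.background, dtype=float)
    if noise_sd > 0:
        ref = ref + rng.normal(0, noise_sd, ref.shape)
        blank = blank + rng.normal(0, noise_sd, blank.shape)
    return ref, blank


# ---------------------------------------------------------------------------
# knockdown datasets


def gen_knockdown_dataset(
    kinetic: KineticModel,
    magnitudes,
    times_h=None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell relative expression curves drawn from a known kinetic model.

    Each cell's noiseless curve is the ODE solution at its dose, multiplied
    by i.i.d. lognormal noise per timepoint (the t = 0 point is exact so the
    normalization convention is preserved).
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    if (magnitudes < 0).any():
        raise ValueError("doses must be non-negative")
    times_h = np.asarray(times_h if times_h is not None else np.arange(0, 20.01, 0.5), dtype=float)
    rng = np.random.default_rng(seed)

    curves = np.vstack([kinetic.relative_expression(d, times_h) for d in magnitudes])
    # mean-one lognormal noise so noisy curves are unbiased in expectation
    noise = np.exp(rng.normal(-0.5 * noise_sd ** 2, noise_sd, size=curves.shape))
    noise[:, times_h == 0] = 1.0
    noisy = curves * noise

    n, T = curves.shape
    table = pd.DataFrame({
        "track_id": np.repeat(np.arange(n), T),
        "time_h": np.tile(times_h, n),
        "time_min": np.tile(times_h * 60.0, n),
        "rel_frame": np.tile(np.round(times_h * 12).astype(int), n),
        "rel_expression": noisy.ravel(),
        "dose_nM": np.repeat(magnitudes, T),
    })
    truth = GroundTruth(
        events=pd.DataFrame({"track_id": np.arange(n), "frame": 0, "magnitude_nM": magnitudes}),
        doses=magnitudes,
        knockdown_curves=curves,
        times_h=times_h,
    )
    return table, truth
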