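"""Segmentation, tracking, lipoplex masking, and per-cell median-intensity
measurement for two-plane time-lapse stacks, plus geometric utilities.

Measurements are always taken on raw intensities; denoising is applied only
to the channels used for segmentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "FramePair",
    "SegmentationConfig",
    "segment_and_track",
    "mask_lipoplexes",
    "measure_traces",
    "measure_stack",
    "lipoplex_diameters",
    "cytosol_volume",
]


@dataclass
class FramePair:
    z1: np.ndarray
    z2: np.ndarray
    frame_index: int = 0
    pixel_size: float = 1.0  # µm
    timestamp: float = 0.0   # minutes

    def __post_init__(self) -> None:
        if self.z1.shape != self.z2.shape:
            raise ValueError("z1 and z2 must have identical shape")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


@dataclass
class SegmentationConfig:
    nuclear_sigma: float = 2.0        # denoise sigma for the nuclear channel
    cell_sigma: float = 2.0           # denoise sigma for the eGFP channel
    min_nucleus_px: int = 40
    declump_min_distance: int = 10    # px between watershed seeds
    max_displacement: float | None = None  # px/frame; default 2x median nucleus radius
    lipoplex_threshold: float | None = None  # default: 99.9th pct of first frame
    lipoplex_margin_px: int = 3


# ---------------------------------------------------------------------------
# segmentation + tracking


def _segment_nuclei(img: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    sm = gaussian(img.astype(float), cfg.nuclear_sigma, preserve_range=True)
    if sm.max() <= sm.min():
        return np.zeros(img.shape, dtype=np.int32)
    binary = sm > threshold_otsu(sm)
    binary = remove_small_objects(binary, max_size=cfg.min_nucleus_px)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(dist, min_distance=cfg.declump_min_distance, labels=binary)
    seeds = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        lab, _ = ndi.label(binary)
        return lab.astype(np.int32)
    return watershed(-dist, seeds, mask=binary).astype(np.int32)


def _grow_cells(egfp: np.ndarray, nuclei: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    sm = gaussian(egfp.astype(float), cfg.cell_sigma, preserve_range=True)
    if nuclei.max() == 0 or sm.max() <= sm.min():
        return np.zeros(egfp.shape, dtype=np.int32)
    fg = sm > threshold_otsu(sm)
    fg |= nuclei > 0
    return watershed(-sm, nuclei, mask=fg).astype(np.int32)


def segment_and_track(images: dict, config: SegmentationConfig | None = None):
    """Segment nuclei and cells per frame and link nuclei across frames.

    ``images`` needs keys ``nuclear`` and ``eGFP``, each (t, y, x).  Returns
    ``(cell_masks, nucleus_masks, tracks)`` where masks are label stacks
    relabelled to stable track ids and ``tracks`` is a DataFrame
    (track_id, frame, row, col).  Tracks are greedy nearest-centroid links
    within a maximum displacement; an ambiguous merge ends the track.
    """
    cfg = config or SegmentationConfig()
    nuclear, egfp = images["nuclear"], images["eGFP"]
    T = nuclear.shape[0]

    raw_nuc, raw_cell, frame_props = [], [], []
    for fr in range(T):
        nuc = _segment_nuclei(nuclear[fr], cfg)
        cell = _grow_cells(egfp[fr], nuc, cfg)
        raw_nuc.append(nuc)
        raw_cell.append(cell)
        frame_props.append({p.label: p for p in regionprops(nuc)})

    if cfg.max_displacement is None:
        radii = [math.sqrt(p.area / math.pi) for props in frame_props for p in props.values()]
        max_disp = 2.0 * float(np.median(radii)) if radii else 10.0
    else:
        max_disp = cfg.max_displacement

    next_track = 1
    active: dict[int, tuple] = {}  # track_id -> (row, col)
    label_to_track = [dict() for _ in range(T)]
    rows = []
    for fr in range(T):
        cents = {lab: p.centroid for lab, p in frame_props[fr].items()}
        assigned_labels, assigned_tracks = set(), set()
        pairs = sorted(
            ((np.hypot(c[0] - a[0], c[1] - a[1]), lab, tid)
             for lab, c in cents.items() for tid, a in active.items()),
            key=lambda x: x[0],
        )
        links = {}
        for d, lab, tid in pairs:
            if d > max_disp:
                break
            if lab in assigned_labels or tid in assigned_tracks:
                continue
            links[lab] = tid
            assigned_labels.add(lab)
            assigned_tracks.add(tid)
        new_active = {}
        for lab, c in cents.items():
            tid = links.get(lab)
            if tid is None:
                tid = next_track
                next_track += 1
            label_to_track[fr][lab] = tid
            new_active[tid] = c
            rows.append((tid, fr, c[0], c[1]))
        active = new_active

    cell_masks = np.zeros_like(np.asarray(raw_cell), dtype=np.int32)
    nucleus_masks = np.zeros_like(cell_masks)
    for fr in range(T):
        for lab, tid in label_to_track[fr].items():
            nucleus_masks[fr][raw_nuc[fr] == lab] = tid
            cell_masks[fr][raw_cell[fr] == lab] = tid

    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "row", "col"])
    return cell_masks, nucleus_masks, tracks


# ---------------------------------------------------------------------------
# lipoplex masking


def mask_lipoplexes(
    z1: np.ndarray,
    z2: np.ndarray,
    intensity_threshold: float,
    margin_px: int = 3,
) -> np.ndarray:
    """Exclusion mask for bright particles visible in either z-plane.

    Pixels above the threshold in z1 OR z2 are labelled as particles and the
    union is dilated by ``margin_px`` so that out-of-focus halos around
    particles in the other plane are also excluded from z1 measurements.
    """
    bright = (np.asarray(z1) > intensity_threshold) | (np.asarray(z2) > intensity_threshold)
    if not bright.any():
        return np.zeros(z1.shape, dtype=np.int32)
    lab, _ = ndi.label(bright)
    if margin_px > 0:
        dil = dilation(bright, disk(margin_px))
        # nearest-particle label for dilated pixels
        _, (ri, ci) = ndi.distance_transform_edt(~bright, return_indices=True)
        out = np.where(dil, lab[ri, ci], 0).astype(np.int32)
        return out
    return lab.astype(np.int32)


# ---------------------------------------------------------------------------
# measurement


def _masked_median(img, mask):
    vals = img[mask]
    return (float(np.median(vals)), vals.size) if vals.size else (float("nan"), 0)


def measure_traces(
    images: dict,
    cell_masks: np.ndarray,
    nucleus_masks: np.ndarray,
    lipoplex_masks: np.ndarray,
    tracks: pd.DataFrame | None = None,
    frame_interval: float = 5.0,
) -> pd.DataFrame:
    """Background-corrected per-cell median intensities per frame.

    siRNA (z1) is measured in the full cell mask and in the cytosol mask
    (nucleus and lipoplexes removed); eGFP in the nucleus mask.  The per-frame
    background is the median of pixels free of every identified object.  A
    cell whose measurement mask is empty after exclusions gets NaN and a flag.
    """
    sirna = images["siRNA"]
    egfp = images["eGFP"]
    T = sirna.shape[0]
    lip = lipoplex_masks
    if lip.ndim == 4:  # (t, z, y, x) -> union over z
        lip = (lip > 0).any(axis=1)
    else:
        lip = lip > 0

    rows = []
    for fr in range(T):
        z1 = sirna[fr, 0] if sirna.ndim == 4 else sirna[fr]
        cells = cell_masks[fr]
        nucs = nucleus_masks[fr]
        lips = lip[fr]
        free = (cells == 0) & (nucs == 0) & ~lips
        bg_sirna = float(np.median(z1[free])) if free.any() else 0.0
        bg_egfp = float(np.median(egfp[fr][free])) if free.any() else 0.0
        for tid in np.unique(cells):
            if tid == 0:
                continue
            cmask = cells == tid
            nmask = nucs == tid
            cell_meas = cmask & ~lips
            cyto_meas = cmask & ~nmask & ~lips
            med_cell, n_cell = _masked_median(z1, cell_meas)
            med_cyto, n_cyto = _masked_median(z1, cyto_meas)
            med_nuc, n_nuc = _masked_median(egfp[fr], nmask)
            flags = []
            if n_cell == 0:
                flags.append("empty_cell_mask")
            if n_cyto == 0:
                flags.append("empty_cytosol_mask")
            if n_nuc == 0:
                flags.append("empty_nucleus_mask")
            cy, cx = ndi.center_of_mass(cmask) if cmask.any() else (np.nan, np.nan)
            rows.append({
                "track_id": int(tid),
                "frame": fr,
                "time_min": fr * frame_interval,
                "median_siRNA_cellmask": med_cell - bg_sirna if n_cell else np.nan,
                "median_siRNA_cytosolmask": med_cyto - bg_sirna if n_cyto else np.nan,
                "median_eGFP_nucleusmask": med_nuc - bg_egfp if n_nuc else np.nan,
                "background_siRNA": bg_sirna,
                "background_eGFP": bg_egfp,
                "centroid_row": cy,
                "centroid_col": cx,
                "flags": ";".join(flags),
            })
    table = pd.DataFrame(rows)
    if not table.empty:
        first_seen = table.groupby("track_id")["frame"].transform("min")
        table["entered_after_frame3"] = first_seen > 3
    return table


def measure_stack(images: dict, config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Full measurement pipeline: segment, track, mask lipoplexes, measure."""
    cfg = config or SegmentationConfig()
    cell_masks, nucleus_masks, tracks = segment_and_track(images, cfg)
    sirna = images["siRNA"]
    T = sirna.shape[0]
    thr = cfg.lipoplex_threshold
    if thr is None:
        first = sirna[0, 0] if sirna.ndim == 4 else sirna[0]
        thr = float(np.percentile(first, 99.9))
    lip = np.zeros((T,) + sirna.shape[-2:], dtype=np.int32)
    for fr in range(T):
        z1 = sirna[fr, 0] if sirna.ndim == 4 else sirna[fr]
        z2 = sirna[fr, 1] if sirna.ndim == 4 else sirna[fr]
        lip[fr] = mask_lipoplexes(z1, z2, thr, cfg.lipoplex_margin_px)
    return measure_traces(images, cell_masks, nucleus_masks, lip, tracks)


# ---------------------------------------------------------------------------
# geometric utilities


def lipoplex_diameters(image: np.ndarray, threshold: float, pixel_size: float) -> np.ndarray:
    """Equivalent-circle diameters (µm) of above-threshold particles."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    bright = np.asarray(image) > threshold
    if not bright.any():
        return np.array([])
    lab, n = ndi.label(bright)
    areas = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    areas_um2 = areas * pixel_size ** 2
    return 2.0 * np.sqrt(areas_um2 / math.pi)


def cytosol_volume(cell_areas_um2, nucleus_areas_um2, dz_um: float) -> float:
    """Cytosol volume in fL: dz * (sum of cell areas - sum of nucleus areas).

    1 µm³ = 1 fL; the plane lists may have different lengths (the nucleus
    typically spans fewer planes).
    """
    if dz_um <= 0:
        raise ValueError("dz must be positive")
    v_cell = dz_um * float(np.sum(cell_areas_um2))
    v_nuc = dz_um * float(np.sum(nucleus_areas_um2))
    if v_nuc > v_cell:
        raise ValueError("nucleus volume exceeds cell volume")
    return v_cell - v_nuc
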