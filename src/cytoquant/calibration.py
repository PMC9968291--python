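"""Conversion of background-corrected intensities to absolute siRNA concentrations.

A reference z-stack of a 1 µM dye solution is reduced to a single per-pixel
reference image (mean projection over the FWHM plane interval, blank
subtracted).  Dividing a corrected intensity by the reference pixel value at
the cell centroid simultaneously corrects vignetting and converts to
concentration.  Molecule counts follow from N = C * V * N_A.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AVOGADRO = 6.022e23

__all__ = [
    "AVOGADRO",
    "CalibrationModel",
    "StandardCurve",
    "build_reference",
    "fit_standard_curve",
    "fwhm_plane_indices",
    "round_sig",
    "to_concentration",
    "to_molecules",
]


class CalibrationError(ValueError):
    """Raised when a calibration cannot be built or applied."""


@dataclass
class CalibrationModel:
    """Per-pixel 1 µM reference with vignetting baked in.

    Attributes
    ----------
    reference_image:
        Blank-subtracted mean FWHM projection of the reference stack(s);
        intensity corresponding to ``reference_conc`` at every pixel.
    reference_conc:
        Concentration of the reference solution in nM (default 1000).
    fwhm_plane_indices:
        Indices of the z-planes included in the projection, per replicate.
    calib_error_rel:
        Relative systematic uncertainty of the calibration, propagated into
        per-event error estimates downstream.
    """

    reference_image: np.ndarray
    reference_conc: float = 1000.0
    fwhm_plane_indices: list = field(default_factory=list)
    calib_error_rel: float = 0.08

    def __post_init__(self) -> None:
        self.reference_image = np.asarray(self.reference_image, dtype=float)
        if self.reference_conc <= 0:
            raise CalibrationError("reference_conc must be positive")

    def save(self, outdir: str | Path) -> None:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(outdir / "reference.tif", self.reference_image.astype(np.float32))
        meta = {
            "reference_conc": self.reference_conc,
            "fwhm_plane_indices": [list(map(int, ix)) for ix in self.fwhm_plane_indices],
            "calib_error_rel": self.calib_error_rel,
        }
        (outdir / "calibration.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, indir: str | Path) -> "CalibrationModel":
        import tifffile

        indir = Path(indir)
        ref = tifffile.imread(indir / "reference.tif")
        meta = json.loads((indir / "calibration.json").read_text())
        return cls(
            reference_image=ref,
            reference_conc=meta["reference_conc"],
            fwhm_plane_indices=meta["fwhm_plane_indices"],
            calib_error_rel=meta["calib_error_rel"],
        )


@dataclass
class StandardCurve:
    """Fitted dilution-series response: ``linear`` or ``loglog_origin``."""

    mode: str
    coefficient: float  # slope (linear) or exponent (loglog_origin)
    r_squared: float


def fwhm_plane_indices(zstack: np.ndarray) -> np.ndarray:
    """Indices of z-planes whose mean pixel intensity is >= half the maximum
    plane mean."""
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim != 3:
        raise CalibrationError("z-stack must be 3-D (z, y, x)")
    profile = zstack.mean(axis=(1, 2))
    peak = profile.max()
    if peak <= 0:
        raise CalibrationError("z-stack has no signal (all-zero profile)")
    return np.flatnonzero(profile >= peak / 2.0)


def _fwhm_projection(zstack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = fwhm_plane_indices(zstack)
    return np.asarray(zstack, dtype=float)[idx].mean(axis=0), idx


def build_reference(
    ref_zstacks,
    blank_zstacks,
    reference_conc: float = 1000.0,
    calib_error_rel: float = 0.08,
) -> CalibrationModel:
    """Build a :class:`CalibrationModel` from reference and blank z-stacks.

    Each reference stack is reduced to the mean projection over its FWHM
    plane interval; replicate projections are averaged.  Blank stacks are
    processed identically and subtracted.

    Parameters
    ----------
    ref_zstacks, blank_zstacks:
        A single ``(z, y, x)`` array or a sequence of replicate arrays.
    """
    refs = _as_stack_list(ref_zstacks)
    blanks = _as_stack_list(blank_zstacks)
    for s in refs + blanks:
        if s.shape[0] < 3:
            raise CalibrationError("need at least 3 z-planes per stack")
    if refs[0].shape[1:] != blanks[0].shape[1:]:
        raise CalibrationError("blank stack geometry does not match reference")

    projections, indices = [], []
    for s in refs:
        proj, idx = _fwhm_projection(s)
        projections.append(proj)
        indices.append(idx)
    ref_mean = np.mean(projections, axis=0)

    blank_projections = []
    for s in blanks:
        try:
            blank_projections.append(_fwhm_projection(s)[0])
        except CalibrationError:  # signal-free blank: plain mean projection
            blank_projections.append(s.mean(axis=0))
    blank_mean = np.mean(blank_projections, axis=0)

    return CalibrationModel(
        reference_image=ref_mean - blank_mean,
        reference_conc=reference_conc,
        fwhm_plane_indices=indices,
        calib_error_rel=calib_error_rel,
    )


def _as_stack_list(stacks) -> list[np.ndarray]:
    if isinstance(stacks, np.ndarray) and stacks.ndim == 3:
        return [np.asarray(stacks, dtype=float)]
    return [np.asarray(s, dtype=float) for s in stacks]


def fit_standard_curve(concentrations, intensities, mode: str = "linear") -> StandardCurve:
    """Least-squares standard curve over a dilution series.

    ``linear``: straight line through the origin is *not* forced; the slope of
    an ordinary y = a*x + b fit is reported together with its R².
    ``loglog_origin``: log y = a * log x with the intercept fixed at zero.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size < 3:
        raise CalibrationError("need at least 3 points for a standard curve")
    if np.any(x <= 0):
        raise CalibrationError("concentrations must be positive")

    if mode == "linear":
        coeffs = np.polyfit(x, y, 1)
        fit = np.polyval(coeffs, x)
        coef = float(coeffs[0])
    elif mode == "loglog_origin":
        if np.any(y <= 0):
            raise CalibrationError("loglog_origin mode requires positive intensities")
        lx, ly = np.log(x), np.log(y)
        # intercept constrained to 0: a = <lx, ly> / <lx, lx>
        a = float(lx @ ly / (lx @ lx))
        fit = a * lx
        y = ly
        coef = a
    else:
        raise CalibrationError(f"unknown standard-curve mode: {mode!r}")

    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(mode=mode, coefficient=coef, r_squared=r2)


def to_concentration(corrected_intensity, position, model: CalibrationModel) -> float:
    """Convert a background-corrected intensity to nM at an image position.

    ``position`` is the (row, col) centroid of the evaluated cell; the
    reference pixel there supplies the local 1 µM response (vignetting
    included), so the conversion is position dependent.
    """
    row, col = int(round(position[0])), int(round(position[1]))
    ref = model.reference_image
    if not (0 <= row < ref.shape[0] and 0 <= col < ref.shape[1]):
        raise CalibrationError(f"position {position} outside reference image")
    ref_val = ref[row, col]
    if ref_val <= 0:
        raise CalibrationError(f"non-positive reference value at {position}")
    return float(corrected_intensity) / float(ref_val) * model.reference_conc


def to_molecules(conc_nm: float, volume_fl: float) -> float:
    """Molecule count N = C * V * N_A for C in nM and V in fL."""
    if conc_nm < 0:
        raise ValueError("concentration must be non-negative")
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    return conc_nm * 1e-9 * volume_fl * 1e-15 * AVOGADRO


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
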