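"""Planar time-activity curves and mono-exponential half-life fitting.

Workflow: an oversized ROI drawn on the first whole-body scan is shrunk to
the pixels at or above 50% of its maximum (ROI50), the ROI50 is propagated
through the scan series by translation-only normalized cross-correlation,
counts are corrected with an adjacent-background subtraction, and the
resulting curve is fit with a single exponential on log-counts.  The
biological half-life follows from 1/T_bio = 1/T_eff - 1/T_phys; values of
T_eff above the physical half-life give a negative T_bio (net accumulation
over the observation window) and are reported as such with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, zoom

from .core import PlanarImage
from .nuclide import LN2, NuclideData


@dataclass
class ROI2D:
    label: str
    mask: np.ndarray  # bool, planar grid
    background: np.ndarray | None = None
    source: str = "threshold50"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=bool)
            if (self.mask & self.background).any():
                raise ValueError(f"ROI {self.label}: ROI and background masks overlap")

    def shifted(self, shift: tuple[int, int]) -> "ROI2D":
        return ROI2D(self.label, np.roll(self.mask, shift, axis=(0, 1)),
                     None if self.background is None else np.roll(self.background, shift, axis=(0, 1)),
                     self.source)


@dataclass
class TimeActivityCurve:
    label: str
    times_h: np.ndarray
    counts: np.ndarray          # background-corrected
    counts_raw: np.ndarray
    background_per_px: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("TAC times must be strictly increasing")
        if len(self.times_h) < 2:
            raise ValueError("at least two time points are required")


@dataclass
class KineticFit:
    label: str
    A0: float                  # extrapolated counts at t=0
    T_eff_h: float
    T_bio_h: float             # may be negative (accumulation) or inf
    rss: float
    flags: list[str] = field(default_factory=list)

    @property
    def lambda_eff(self) -> float:
        return LN2 / self.T_eff_h


def biological_half_life(T_eff_h: float, T_phys_h: float) -> float:
    """T_bio = T_eff*T_phys/(T_phys - T_eff); +inf when T_eff == T_phys."""
    denom = T_phys_h - T_eff_h
    if abs(denom) < 1e-12 * T_phys_h:
        return math.inf
    return T_eff_h * T_phys_h / denom


def make_roi50(planar: PlanarImage, oversized_mask: np.ndarray, label: str = "",
               background: np.ndarray | None = None) -> ROI2D:
    """Pixels of the oversized ROI at or above half of its maximum count."""
    mask = np.asarray(oversized_mask, dtype=bool)
    if not mask.any():
        raise ValueError("oversized ROI is empty")
    vals = planar.data[mask]
    vmax = vals.max()
    if vmax <= 0:
        raise ValueError(f"ROI {label or '?'}: no signal in oversized ROI")
    roi = mask & (planar.data >= 0.5 * vmax)
    return ROI2D(label, roi, background, source="threshold50")


def make_background_rind(mask: np.ndarray, exclude: np.ndarray | None = None,
                         gap_px: int = 2, width_px: int = 3) -> np.ndarray:
    """Background ROI adjacent to a mask: a rind at gap_px distance."""
    inner = binary_dilation(mask, iterations=gap_px)
    outer = binary_dilation(inner, iterations=width_px)
    bg = outer & ~inner
    if exclude is not None:
        bg &= ~np.asarray(exclude, dtype=bool)
    if not bg.any():
        raise ValueError("background rind is empty")
    return bg


def register_translation(reference: np.ndarray, target: np.ndarray,
                         window: np.ndarray, max_shift: int = 8):
    """Integer shift maximizing zero-mean NCC of target vs reference over a
    pixel window.  Returns (shift, at_edge_flag)."""
    ref = reference[window]
    ref = ref - ref.mean()
    nref = np.linalg.norm(ref)
    best, best_val = (0, 0), -np.inf
    for dx in range(-max_shift, max_shift + 1):
        for dy in range(-max_shift, max_shift + 1):
            cand = np.roll(target, (-dx, -dy), axis=(0, 1))[window]
            cand = cand - cand.mean()
            denom = nref * np.linalg.norm(cand)
            val = float(ref @ cand) / max(denom, 1e-300)
            if val > best_val + 1e-12:
                best_val, best = val, (dx, dy)
    at_edge = max(abs(best[0]), abs(best[1])) >= max_shift
    return best, at_edge


def propagate_roi(roi: ROI2D, reference: PlanarImage, series: list[PlanarImage],
                  max_shift: int = 8) -> list[tuple[ROI2D, bool]]:
    """Translate the ROI to each image of the series by NCC registration.

    All images must share the reference pixel grid (resample dialects with
    :func:`resample_planar` first).  Returns (shifted ROI, edge-warning) per
    time point.
    """
    window = binary_dilation(roi.mask, iterations=max_shift + 2)
    out = []
    for img in series:
        if img.shape != reference.shape:
            raise ValueError("series images must share the reference grid")
        shift, at_edge = register_translation(reference.data, img.data, window, max_shift)
        out.append((roi.shifted(shift), at_edge))
    return out


def resample_planar(img: PlanarImage, pixel_mm: float) -> PlanarImage:
    """Resample a planar dialect (2.21 / 2.88 mm) to a common pixel size,
    conserving total counts."""
    if abs(img.pixel_mm[0] - pixel_mm) < 1e-9:
        return img
    f = img.pixel_mm[0] / pixel_mm
    data = zoom(img.data.astype(float), f, order=1)
    data *= img.data.sum() / max(data.sum(), 1e-300)
    return PlanarImage(data, (pixel_mm, pixel_mm), unit=img.unit, meta=dict(img.meta))


def background_corrected_counts(img: PlanarImage, roi: ROI2D):
    """ROI total minus (mean background per pixel) x (ROI pixel count).

    Returns (corrected, raw, bg_mean_per_px, clipped_flag); negative results
    are floored at zero with the flag set.
    """
    if roi.background is None or not roi.background.any():
        raise ValueError(f"ROI {roi.label}: background mask empty")
    raw = float(img.data[roi.mask].sum())
    bg_mean = float(img.data[roi.background].mean())
    corrected = raw - bg_mean * int(roi.mask.sum())
    clipped = corrected < 0
    return (max(corrected, 0.0), raw, bg_mean, clipped)


def build_tac(label: str, times_h, images: list[PlanarImage],
              rois: list[ROI2D], flags_per_point=None) -> TimeActivityCurve:
    corrected, raw, bg = [], [], []
    flags = []
    for i, (img, roi) in enumerate(zip(images, rois)):
        c, r, b, clipped = background_corrected_counts(img, roi)
        corrected.append(c)
        raw.append(r)
        bg.append(b)
        if clipped:
            flags.append(f"negative_corrected_counts_at_t{i}")
        if flags_per_point and flags_per_point[i]:
            flags.append(f"registration_edge_at_t{i}")
    return TimeActivityCurve(label, np.asarray(times_h), np.asarray(corrected),
                             np.asarray(raw), np.asarray(bg), flags)


def fit_monoexponential(tac: TimeActivityCurve, nuclide: NuclideData) -> KineticFit:
    """Unweighted least squares on log-counts; exact for two points."""
    t, c = tac.times_h, tac.counts
    usable = c > 0
    flags = list(tac.flags)
    if not usable.all():
        flags.append("nonpositive_points_excluded")
    t, c = t[usable], c[usable]
    if len(t) < 2:
        raise ValueError(f"{tac.label}: fewer than 2 usable points for fitting")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        raise ValueError(f"{tac.label}: counts do not decay; no positive T_eff")
    T_eff = LN2 / (-slope)
    A0 = float(np.exp(intercept))
    rss = float(np.sum((np.log(c) - (slope * t + intercept)) ** 2))
    T_bio = biological_half_life(T_eff, nuclide.half_life_h)
    if T_eff > nuclide.half_life_h:
        flags.append("accumulation")  # T_bio < 0: uptake still rising
    return KineticFit(tac.label, A0, float(T_eff), float(T_bio), rss, flags)
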