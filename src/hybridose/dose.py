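"""Voxel-level dose maps, self/cross decomposition, and DVHs.

Dose maps are the convolution of the cumulated-activity map (MBq h per
voxel) with the voxel S-value kernel, done by zero-padded FFT.  The organ
decomposition convolves each region's cumulated activity separately: the
self dose of a region is the mean dose it receives from its own activity,
the cross dose is everything else; the two add exactly to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft

from .core import ImageVolume
from .kernel import DoseKernel

_NEG_TOL = 1e-12


@dataclass
class DVH:
    """Cumulative dose-volume histogram: fraction of volume >= dose."""

    dose_edges_mGy: np.ndarray
    fraction_ge: np.ndarray

    def mean_dose(self) -> float:
        """Mean dose recovered from the DVH by the Riemann sum
        integral of the survival curve."""
        widths = np.diff(self.dose_edges_mGy)
        return float(np.sum(self.fraction_ge[1:] * widths))


@dataclass
class DoseResult:
    dose_map: ImageVolume                      # mGy per MBq injected
    per_roi: pd.DataFrame                      # mean/self/cross dose + cross fraction
    dvhs: dict[str, DVH] = field(default_factory=dict)


class _FFTConvolver:
    """Zero-padded FFT convolution with a fixed centered kernel."""

    def __init__(self, kernel: np.ndarray, shape: tuple[int, int, int]):
        self.shape = shape
        kshape = kernel.shape
        full = [shape[a] + kshape[a] - 1 for a in range(3)]
        self.fshape = [scipy.fft.next_fast_len(n, real=True) for n in full]
        self.kf = scipy.fft.rfftn(kernel, self.fshape)
        # 'same' slice: kernel is centered, so offset by its half extent
        self.sl = tuple(
            slice(kshape[a] // 2, kshape[a] // 2 + shape[a]) for a in range(3)
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        xf = scipy.fft.rfftn(x, self.fshape)
        y = scipy.fft.irfftn(xf * self.kf, self.fshape)[self.sl]
        neg = y.min()
        if neg < -_NEG_TOL * max(y.max(), 1.0):
            raise FloatingPointError(f"convolution produced large negative residue {neg:g}")
        return np.maximum(y, 0.0)


def dose_map(cumulated: ImageVolume, kernel: DoseKernel) -> ImageVolume:
    """Convolve cumulated activity (MBq h) with the voxel S kernel -> mGy."""
    if abs(cumulated.spacing[0] - kernel.voxel_mm) > 1e-6 or len(set(cumulated.spacing)) != 1:
        raise ValueError(
            f"voxel size mismatch: map {cumulated.spacing} vs kernel {kernel.voxel_mm} mm"
        )
    conv = _FFTConvolver(kernel.k, cumulated.shape)
    return cumulated.with_data(conv(cumulated.data), unit="mGy")


def dose_map_bruteforce(cumulated: ImageVolume, kernel: DoseKernel) -> ImageVolume:
    """O(N^2) double-sum reference implementation (tiny grids only)."""
    act = cumulated.data
    h = kernel.center
    out = np.zeros_like(act, dtype=float)
    nz = np.argwhere(act != 0)
    idx = np.indices(act.shape)
    for (i, j, k) in nz:
        di = idx[0] - i + h[0]
        dj = idx[1] - j + h[1]
        dk = idx[2] - k + h[2]
        valid = (
            (di >= 0) & (di < kernel.k.shape[0])
            & (dj >= 0) & (dj < kernel.k.shape[1])
            & (dk >= 0) & (dk < kernel.k.shape[2])
        )
        contrib = np.zeros_like(out)
        contrib[valid] = kernel.k[di[valid], dj[valid], dk[valid]]
        out += act[i, j, k] * contrib
    return cumulated.with_data(out, unit="mGy")


def dvh(dose: ImageVolume | np.ndarray, roi_mask: np.ndarray, n_bins: int = 100) -> DVH:
    """Cumulative DVH over a region; bin 0 is always 1.0."""
    data = dose.data if isinstance(dose, ImageVolume) else np.asarray(dose)
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI for DVH")
    d = data[mask]
    dmax = float(d.max())
    edges = np.linspace(0.0, dmax * (1 + 1e-9), n_bins + 1)
    frac = np.array([(d >= e).mean() for e in edges])
    frac[0] = 1.0
    return DVH(edges, frac)


def organ_dose_decomposition(
    source_maps: dict[str, ImageVolume],
    kernel: DoseKernel,
    roi_masks: dict[str, np.ndarray],
    injected_MBq: float = 1.0,
    n_dvh_bins: int = 100,
) -> DoseResult:
    """Self/cross decomposition by per-source convolution.

    ``source_maps`` gives cumulated activity (MBq h) per source region;
    ``roi_masks`` the target regions to report (usually a subset of the
    sources).  Doses are normalized per MBq injected.
    """
    labels = list(source_maps)
    first = source_maps[labels[0]]
    for lab, m in source_maps.items():
        if not m.same_grid(first):
            raise ValueError(f"source map {lab} grid mismatch")
    for lab, mask in roi_masks.items():
        if not np.asarray(mask).any():
            raise ValueError(f"empty ROI {lab}")

    conv = _FFTConvolver(kernel.k, first.shape)
    per_source = {lab: conv(m.data) for lab, m in source_maps.items()}
    total = np.zeros(first.shape)
    for arr in per_source.values():
        total += arr

    rows = []
    dvhs = {}
    for lab, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        mean_total = float(total[mask].mean()) / injected_MBq
        mean_self = (
            float(per_source[lab][mask].mean()) / injected_MBq if lab in per_source else 0.0
        )
        cross = mean_total - mean_self
        rows.append(
            dict(
                label=lab,
                mean_dose_mGy_per_MBq=mean_total,
                self_dose_mGy_per_MBq=mean_self,
                cross_dose_mGy_per_MBq=cross,
                cross_fraction_pct=100.0 * cross / mean_total if mean_total > 0 else 0.0,
            )
        )
        dvhs[lab] = dvh(total / injected_MBq, mask, n_dvh_bins)
    dm = first.with_data(total / injected_MBq, unit="mGy/MBq")
    return DoseResult(dm, pd.DataFrame(rows), dvhs)
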