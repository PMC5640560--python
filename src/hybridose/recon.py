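"""OSEM reconstruction and absolute-activity calibration.

Reconstruction follows the clinical recipe: ordered-subsets EM with 2
iterations and 10 subsets, CT-based attenuation correction with the mu-map
rescaled toward broad-beam values (indirect scatter compensation), and a
post-reconstruction smoothing filter.

Quantification contract: the forward model inside OSEM divides by the
number of views, so a voxel of the reconstructed image carries the counts
the whole acquisition would have collected from it.  Dividing by
(sensitivity x total acquisition time) then yields activity, which is what
:func:`counts_to_activity` does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import ImageVolume, centered_grid
from .projector import FWHM_TO_SIGMA, ProjectionSet, RotationProjector

_EPS = 1e-12


@dataclass
class CalibrationFactor:
    """Planar sensitivity of the camera, cps/MBq, averaged over both heads."""

    sensitivity_cps_per_MBq: float
    source_activity_MBq: float
    per_head: tuple[float, float]


def calibrate(counts_det1: float, counts_det2: float, duration_s: float,
              activity_MBq: float) -> CalibrationFactor:
    """Point-source calibration: per-head sensitivity counts/(duration x activity),
    overall factor the arithmetic mean of the two heads."""
    if min(counts_det1, counts_det2) <= 0:
        raise ValueError("nonpositive calibration counts: acquisition failed")
    if duration_s <= 0 or activity_MBq <= 0:
        raise ValueError("duration and activity must be positive")
    s1 = counts_det1 / (duration_s * activity_MBq)
    s2 = counts_det2 / (duration_s * activity_MBq)
    return CalibrationFactor((s1 + s2) / 2.0, activity_MBq, (s1, s2))


@dataclass
class ReconConfig:
    n_iterations: int = 2
    n_subsets: int = 10
    post_filter: tuple[str, float] | None = ("gaussian", 8.0)  # (type, FWHM mm)
    broad_beam_scale: float = 0.75

    def validate(self, n_projections: int) -> None:
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("iterations and subsets must be >= 1")
        if n_projections % self.n_subsets != 0:
            raise ValueError(
                f"{n_projections} projections not divisible into {self.n_subsets} subsets"
            )
        if not (0 < self.broad_beam_scale <= 1):
            raise ValueError("broad_beam_scale must be in (0, 1]")
        if self.post_filter is not None and self.post_filter[0] not in ("gaussian",):
            raise ValueError(f"unknown post filter {self.post_filter[0]!r}")


def osem_reconstruct(projections: ProjectionSet, mu: ImageVolume | None,
                     cfg: ReconConfig | None = None) -> ImageVolume:
    """Attenuation-corrected OSEM reconstruction, output in counts."""
    cfg = cfg or ReconConfig()
    n_views, nx, nz = projections.counts.shape
    cfg.validate(n_views)
    spacing, origin = centered_grid((nx, nx, nz), projections.pixel_mm)
    if mu is not None:
        if mu.shape != (nx, nx, nz):
            raise ValueError(f"attenuation grid {mu.shape} does not match recon grid {(nx, nx, nz)}")
        mu_arr = mu.data * cfg.broad_beam_scale
    else:
        mu_arr = None
    proj_op = RotationProjector((nx, nx, nz), spacing, projections.angles_deg, mu=mu_arr)

    # interleaved angular subsets
    subsets = [list(range(s, n_views, cfg.n_subsets)) for s in range(cfg.n_subsets)]
    g = np.maximum(projections.counts.astype(float), 0.0)

    x = np.ones((nx, nx, nz))
    sens = {tuple(s): proj_op.adjoint(np.ones((len(s), nx, nz)), views=s) for s in map(tuple, subsets)}
    for _ in range(cfg.n_iterations):
        for s in subsets:
            fwd = proj_op.forward(x, views=s) / n_views
            ratio = g[s] / np.maximum(fwd, _EPS)
            x = x * proj_op.adjoint(ratio, views=s) / np.maximum(sens[tuple(s)], _EPS)
    if cfg.post_filter is not None:
        sigma = cfg.post_filter[1] * FWHM_TO_SIGMA / projections.pixel_mm
        x = gaussian_filter(x, sigma, mode="constant")
    return ImageVolume(np.maximum(x, 0.0), spacing, origin, unit="counts")


def poisson_loglik(projections: ProjectionSet, volume: ImageVolume,
                   mu: ImageVolume | None = None, broad_beam_scale: float = 1.0) -> float:
    """Poisson log-likelihood of a volume under the OSEM forward model
    (constant terms dropped); used to monitor EM monotonicity."""
    n_views, nx, nz = projections.counts.shape
    mu_arr = mu.data * broad_beam_scale if mu is not None else None
    op = RotationProjector(volume.shape, volume.spacing, projections.angles_deg, mu=mu_arr)
    lam = np.maximum(op.forward(volume.data) / n_views, _EPS)
    g = projections.counts
    return float(np.sum(g * np.log(lam) - lam))


def counts_to_activity(recon: ImageVolume, cf: CalibrationFactor,
                       total_acq_time_s: float) -> ImageVolume:
    """Convert reconstructed counts to MBq per voxel.

    No decay correction is applied here; time referencing happens when the
    TIACs are assembled.
    """
    if total_acq_time_s <= 0:
        raise ValueError("total acquisition time must be positive")
    if cf.sensitivity_cps_per_MBq <= 0:
        raise ValueError("invalid calibration factor")
    data = recon.data / (cf.sensitivity_cps_per_MBq * total_acq_time_s)
    return recon.with_data(data, unit="MBq")
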