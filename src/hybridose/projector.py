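"""Forward models for planar and SPECT acquisitions.

A rotation-based parallel-ray projector: the volume is resampled into the
detector frame by bilinear in-plane rotation (explicit gather weights), an
attenuation weight per voxel is applied (line integral of mu from the voxel
to the detector), and the result is summed along the anteroposterior axis.
The adjoint scatters through the *same* interpolation weights, so
``<P x, y> == <x, P^T y>`` holds to floating-point accuracy — the property
OSEM relies on.

The detector point-spread function is a distance-independent Gaussian
applied to the projection (self-adjoint).  Counts are Poisson-sampled from
the expected projections with a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .core import ImageVolume, PlanarImage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AcquisitionSpec:
    """Camera geometry, timing and statistics of one simulated study."""

    planar_times_h: tuple[float, ...] = (2.0, 5.0, 22.0)
    spect_time_h: float = 3.0
    n_projections: int = 60
    seconds_per_projection: float = 20.0
    spect_pixel_mm: float = 4.418
    planar_pixel_mm: float | None = None  # None -> SPECT pixel; 2.21 / 2.88 dialects supported
    planar_duration_s: float = 300.0
    sensitivity_cps_per_MBq: float = 90.0
    psf_fwhm_mm: float = 10.0
    attenuation: bool = True
    poisson: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        times = tuple(self.planar_times_h)
        if len(times) < 2 or len(times) > 3:
            raise ValueError("2-3 planar time points are required")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("planar times must be strictly increasing")
        if times[0] <= 0 or times[-1] > 24:
            raise ValueError("planar times must lie within (0, 24] h")
        if self.n_projections <= 0 or self.seconds_per_projection <= 0:
            raise ValueError("projection count and duration must be positive")
        if self.sensitivity_cps_per_MBq <= 0:
            raise ValueError("sensitivity must be positive")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory for reproducibility")

    @property
    def total_acq_time_s(self) -> float:
        return self.n_projections * self.seconds_per_projection

    def view_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * 360.0 / self.n_projections

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.rng_seed), salt]))


@dataclass
class ProjectionSet:
    """SPECT projection stack (view, x, z) with angle metadata."""

    counts: np.ndarray
    angles_deg: np.ndarray
    pixel_mm: float
    seconds_per_projection: float
    time_h: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_views(self) -> int:
        return self.counts.shape[0]


class RotationProjector:
    """Matched projector/backprojector for a cubic-in-plane grid.

    Parameters
    ----------
    shape, spacing_mm : grid of the activity volume (nx, ny, nz), in-plane
        voxels must be square.
    angles_deg : detector angles; 0 deg is the anterior view (detector on
        the -y side), rotation about the z axis.
    mu : optional attenuation volume (1/cm) on the same grid.
    psf_fwhm_mm : Gaussian detector blur applied in projection space.
    """

    def __init__(self, shape, spacing_mm, angles_deg, mu: np.ndarray | None = None,
                 psf_fwhm_mm: float = 0.0):
        self.shape = tuple(shape)
        nx, ny, nz = self.shape
        if abs(spacing_mm[0] - spacing_mm[1]) > 1e-9:
            raise ValueError("in-plane voxels must be square for the rotating projector")
        self.spacing = tuple(spacing_mm)
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self.psf_sigma_px = (psf_fwhm_mm * FWHM_TO_SIGMA) / spacing_mm[0] if psf_fwhm_mm else 0.0

        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        # Forward rotation is the mass-conserving "push": each source voxel
        # deposits its content at its rotated position with bilinear weights
        # (sum to 1 for in-grid points, so activity totals are preserved even
        # for point sources).  The adjoint is the matching gather.
        self._weights = []
        for ang in self.angles_deg:
            th = -np.deg2rad(ang)
            c, s = np.cos(th), np.sin(th)
            # source position for each detector-frame voxel
            fx = c * (ix - cx) - s * (iy - cy) + cx
            fy = s * (ix - cx) + c * (iy - cy) + cy
            x0 = np.floor(fx).astype(np.int64)
            y0 = np.floor(fy).astype(np.int64)
            wx = fx - x0
            wy = fy - y0
            idx, wts = [], []
            for dx, dy, w in (
                (0, 0, (1 - wx) * (1 - wy)),
                (1, 0, wx * (1 - wy)),
                (0, 1, (1 - wx) * wy),
                (1, 1, wx * wy),
            ):
                xs, ys = x0 + dx, y0 + dy
                valid = (xs >= 0) & (xs < nx) & (ys >= 0) & (ys < ny)
                flat = np.where(valid, xs * ny + ys, 0)
                idx.append(flat.ravel())
                wts.append(np.where(valid, w, 0.0).ravel())
            self._weights.append((np.stack(idx), np.stack(wts)))

        self.mu = mu
        self._att = None
        if mu is not None:
            dy_cm = self.spacing[1] / 10.0
            self._att = []
            for v in range(len(self.angles_deg)):
                mur = self._rotate(mu, v)
                # path toward the detector on the -y side of the rotated frame
                c = np.cumsum(mur, axis=1) - mur / 2.0
                self._att.append(np.exp(-c * dy_cm).astype(np.float32))

    def _rotate(self, vol: np.ndarray, view: int) -> np.ndarray:
        """Push rotation into the detector frame (mass-conserving)."""
        nx, ny, nz = self.shape
        idx, wts = self._weights[view]
        flat = vol.reshape(nx * ny, nz)
        out = np.zeros((nx * ny, nz))
        for k in range(4):
            np.add.at(out, idx[k], wts[k][:, None] * flat)
        return out.reshape(nx, ny, nz)

    def _rotate_adjoint(self, vol: np.ndarray, view: int) -> np.ndarray:
        nx, ny, nz = self.shape
        idx, wts = self._weights[view]
        flat = vol.reshape(nx * ny, nz)
        out = np.zeros((nx * ny, nz))
        for k in range(4):
            out += wts[k][:, None] * flat[idx[k]]
        return out.reshape(nx, ny, nz)

    def _blur(self, proj: np.ndarray) -> np.ndarray:
        if self.psf_sigma_px > 0:
            return gaussian_filter(proj, self.psf_sigma_px, mode="constant")
        return proj

    def forward(self, x: np.ndarray, views=None) -> np.ndarray:
        """Project to (n_views, nx, nz)."""
        views = range(len(self.angles_deg)) if views is None else views
        out = []
        for v in views:
            xr = self._rotate(x, v)
            if self._att is not None:
                xr = xr * self._att[v]
            out.append(self._blur(xr.sum(axis=1)))
        return np.stack(out)

    def adjoint(self, proj: np.ndarray, views=None) -> np.ndarray:
        views = range(len(self.angles_deg)) if views is None else views
        out = np.zeros(self.shape)
        for p, v in zip(proj, views):
            g = np.broadcast_to(self._blur(p)[:, None, :], self.shape).copy()
            if self._att is not None:
                g *= self._att[v]
            out += self._rotate_adjoint(g, v)
        return out


def _planar_attenuation(mu: np.ndarray | None, dy_cm: float, posterior: bool) -> np.ndarray | None:
    if mu is None:
        return None
    m = mu[:, ::-1, :] if posterior else mu
    c = np.cumsum(m, axis=1) - m / 2.0
    att = np.exp(-c * dy_cm)
    return att[:, ::-1, :] if posterior else att


def _resample_planar(proj: np.ndarray, voxel_mm: float, pixel_mm: float) -> np.ndarray:
    if abs(voxel_mm - pixel_mm) < 1e-9:
        return proj
    f = voxel_mm / pixel_mm
    out = zoom(proj, f, order=1)
    return out * proj.sum() / max(out.sum(), 1e-300)  # conserve total counts


def simulate_planar(activity: ImageVolume, mu: ImageVolume | None, acq: AcquisitionSpec,
                    time_h: float | None = None):
    """Anterior/posterior whole-body planar pair (Poisson counts)."""
    acq.validate()
    if mu is not None and not activity.same_grid(mu):
        raise ValueError("activity and attenuation grids do not match")
    mu_arr = mu.data if (mu is not None and acq.attenuation) else None
    dy_cm = activity.spacing[1] / 10.0
    scale = acq.sensitivity_cps_per_MBq * acq.planar_duration_s
    sigma = acq.psf_fwhm_mm * FWHM_TO_SIGMA / activity.spacing[0] if acq.psf_fwhm_mm else 0.0
    pixel = acq.planar_pixel_mm or acq.spect_pixel_mm

    images = []
    for i, posterior in enumerate((False, True)):
        att = _planar_attenuation(mu_arr, dy_cm, posterior)
        a = activity.data * att if att is not None else activity.data
        # both views kept in patient (x, z) coordinates for conjugate-view math
        proj = a.sum(axis=1)
        if sigma > 0:
            proj = gaussian_filter(proj, sigma, mode="constant")
        expected = scale * proj
        expected = _resample_planar(expected, activity.spacing[0], pixel)
        if acq.poisson:
            t_salt = 0 if time_h is None else int(round(time_h * 3600))
            counts = acq.rng(salt=1000 + 2 * t_salt + i).poisson(np.maximum(expected, 0.0))
            counts = counts.astype(np.int64)
        else:
            counts = expected
        images.append(PlanarImage(counts, (pixel, pixel),
                                  meta={"view": "posterior" if posterior else "anterior",
                                        "time_h": time_h, "duration_s": acq.planar_duration_s}))
    return images[0], images[1]


def simulate_spect(activity: ImageVolume, mu: ImageVolume | None, acq: AcquisitionSpec,
                   time_h: float | None = None) -> ProjectionSet:
    """60-view (default) circular-orbit projection set with Poisson noise."""
    acq.validate()
    if mu is not None and not activity.same_grid(mu):
        raise ValueError("activity and attenuation grids do not match")
    proj = RotationProjector(
        activity.shape,
        activity.spacing,
        acq.view_angles_deg(),
        mu=mu.data if (mu is not None and acq.attenuation) else None,
        psf_fwhm_mm=acq.psf_fwhm_mm,
    )
    expected = acq.sensitivity_cps_per_MBq * acq.seconds_per_projection * proj.forward(activity.data)
    if acq.poisson:
        counts = acq.rng(salt=2).poisson(np.maximum(expected, 0.0)).astype(np.int64)
    else:
        counts = expected
    return ProjectionSet(
        counts=counts,
        angles_deg=acq.view_angles_deg(),
        pixel_mm=activity.spacing[0],
        seconds_per_projection=acq.seconds_per_projection,
        time_h=acq.spect_time_h if time_h is None else time_h,
        meta={"sensitivity_cps_per_MBq": acq.sensitivity_cps_per_MBq},
    )


def simulate_calibration(activity_MBq: float, duration_s: float, acq: AcquisitionSpec):
    """Point-source-in-air planar acquisition on both detector heads.

    Returns total counts per head.  In air there is no attenuation and the
    source sits centrally, so both heads share the same expectation
    sensitivity x duration x activity.
    """
    if activity_MBq <= 0:
        raise ValueError("calibration source activity must be positive")
    if duration_s <= 0:
        raise ValueError("calibration duration must be positive")
    expected = acq.sensitivity_cps_per_MBq * duration_s * activity_MBq
    if acq.poisson:
        rng = acq.rng(salt=3)
        return int(rng.poisson(expected)), int(rng.poisson(expected))
    return expected, expected
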