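"""Voxel S-value kernels for Tc-99m in water.

The kernel k[di, dj, dk] is the absorbed dose (mGy) in a target voxel per
unit cumulated activity (MBq h) in a source voxel.  It combines

* a non-penetrating component: conversion/Auger electrons (mean energy per
  decay) deposited entirely in the source voxel, and
* a photon point-kernel component evaluated at the center-to-center
  distance r:

      Phi(r) = sum_lines  y E (mu_en/rho) B(mu r) exp(-mu r) / (4 pi r^2)

  with a linear buildup factor B(mu r) = 1 + a mu r approximating scattered
  dose in water.  The self-voxel photon term averages Phi over the distance
  distribution of two uniform points in the equal-volume sphere.

Attenuation/absorption coefficients and the buildup coefficient come from
the packaged physics data file.  A one-dimensional radial quadrature of the
same Phi serves as an independent energy-bookkeeping oracle for the 3-D
kernel (see :func:`radial_absorbed_energy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nuclide import DECAYS_PER_MBQ_H, J_PER_KEV, NuclideData, WATER


@dataclass
class DoseKernel:
    """Voxel S-value array with odd, centered dimensions."""

    k: np.ndarray                     # mGy per MBq.h, total
    k_electron: np.ndarray            # non-penetrating part (only center nonzero)
    voxel_mm: float
    medium: str = "water"
    density_g_per_ml: float = 1.0
    provenance: dict = field(default_factory=dict)

    @property
    def k_photon(self) -> np.ndarray:
        return self.k - self.k_electron

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple(s // 2 for s in self.k.shape)

    @property
    def voxel_mass_g(self) -> float:
        return (self.voxel_mm / 10.0) ** 3 * self.density_g_per_ml


def photon_point_dose(r_cm: np.ndarray, nuclide: NuclideData,
                      density: float = 1.0) -> np.ndarray:
    """Photon absorbed dose in water at distance r from a point source,
    mGy per MBq.h of cumulated activity.  Vectorized over r (r > 0)."""
    r = np.asarray(r_cm, dtype=float)
    dose_J_per_g = np.zeros_like(r)
    for line in nuclide.photon_lines:
        mu = WATER.mu_over_rho(line.energy_keV) * density       # 1/cm
        muen_rho = WATER.mu_en_over_rho(line.energy_keV)        # cm^2/g
        a = WATER.buildup_a(line.energy_keV)                    # energy-conserving
        mur = mu * r
        dose_J_per_g += (
            line.yield_per_decay * line.energy_keV * J_PER_KEV
            * muen_rho * (1.0 + a * mur) * np.exp(-mur) / (4.0 * np.pi * r**2)
        )
    # J/g per decay -> mGy per MBq.h :  * decays * (1000 g/kg) * (1000 mGy/Gy)
    return dose_J_per_g * DECAYS_PER_MBQ_H * 1e6


def sphere_self_dose(radius_cm: float, nuclide: NuclideData,
                     density: float = 1.0, n_quad: int = 2000) -> float:
    """Mean photon self-dose of a uniform unit-density sphere per unit
    cumulated activity (mGy per MBq.h), via the pair-distance distribution
    p(r) = (3 r^2/R^3)(1 - 3r/(4R) + r^3/(16 R^3)) on [0, 2R]."""
    R = float(radius_cm)
    r = np.linspace(1e-6 * R, 2 * R, n_quad)
    p = (3 * r**2 / R**3) * (1 - 3 * r / (4 * R) + r**3 / (16 * R**3))
    return float(np.trapezoid(photon_point_dose(r, nuclide, density) * p, r))


def electron_self_value(nuclide: NuclideData, voxel_mm: float,
                        density: float = 1.0) -> float:
    """Non-penetrating S value of the source voxel, mGy per MBq.h."""
    mass_kg = (voxel_mm / 10.0) ** 3 * density / 1000.0
    return nuclide.electron_energy_J_per_MBqh / mass_kg * 1000.0  # Gy -> mGy


def build_kernel(nuclide: NuclideData, voxel_mm: float = 4.418,
                 grid_half_extent: int = 47) -> DoseKernel:
    """Build a (2h+1)^3 voxel S-value kernel.

    ``grid_half_extent`` is the maximum voxel offset along each axis; the
    clinical configuration uses 107 (a 215^3 grid at 4.418 mm).
    """
    if voxel_mm <= 0:
        raise ValueError("voxel size must be positive")
    if not nuclide.emissions:
        raise ValueError("emission table is empty")
    if grid_half_extent < 1:
        raise ValueError("kernel half-extent must be at least one voxel")
    h = int(grid_half_extent)
    ax = np.arange(-h, h + 1) * (voxel_mm / 10.0)  # cm
    DX, DY, DZ = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(DX**2 + DY**2 + DZ**2)

    k = np.zeros_like(r)
    nz = r > 0
    k[nz] = photon_point_dose(r[nz], nuclide)

    c = (h, h, h)
    r_eq = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) * (voxel_mm / 10.0)  # equal-volume sphere
    k[c] = sphere_self_dose(r_eq, nuclide)

    k_e = np.zeros_like(k)
    k_e[c] = electron_self_value(nuclide, voxel_mm)
    k = k + k_e
    prov = dict(
        nuclide=nuclide.name,
        buildup="energy-conserving linear 1 + a_E*mu*r, a_E = mu/mu_en - 1",
        medium="water",
        voxel_mm=voxel_mm,
        half_extent=h,
    )
    return DoseKernel(k=k, k_electron=k_e, voxel_mm=voxel_mm, provenance=prov)


# ---------------------------------------------------------------------------
# independent energy bookkeeping


def radial_absorbed_energy(nuclide: NuclideData, r_max_cm: float,
                           density: float = 1.0, n_quad: int = 20000) -> float:
    """Photon energy absorbed within radius r_max of a point source, J per
    MBq.h, by 1-D radial quadrature of Phi: integral of Phi * rho * 4 pi r^2 dr.

    Independent of the 3-D kernel path; used as its oracle.
    """
    r = np.linspace(1e-6, r_max_cm, n_quad)
    phi_mGy = photon_point_dose(r, nuclide, density)
    # mGy per MBq.h -> J/g : /1e6 ; shell mass rho*4 pi r^2 dr in g
    integrand = phi_mGy / 1e6 * density * 4.0 * np.pi * r**2
    return float(np.trapezoid(integrand, r))


def infinite_medium_photon_energy(nuclide: NuclideData, density: float = 1.0) -> float:
    """Closed-form infinite-medium photon energy integral of the kernel,
    J per MBq.h: sum_lines y E (mu_en/mu)(1 + a_E).  With the
    energy-conserving buildup this equals the emitted photon energy."""
    total = 0.0
    for line in nuclide.photon_lines:
        mu_rho = WATER.mu_over_rho(line.energy_keV)
        muen_rho = WATER.mu_en_over_rho(line.energy_keV)
        a = WATER.buildup_a(line.energy_keV)
        total += line.yield_per_decay * line.energy_keV * J_PER_KEV * (muen_rho / mu_rho) * (1 + a)
    return total * DECAYS_PER_MBQ_H


def kernel_total_absorbed_energy(kernel: DoseKernel, photon_only: bool = True) -> float:
    """Sum of k * voxel mass over the kernel grid, J per MBq.h."""
    k = kernel.k_photon if photon_only else kernel.k
    return float(k.sum()) / 1e6 * kernel.voxel_mass_g
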