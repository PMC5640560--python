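"""Organ-level MIRD dosimetry with phantom-derived S factors.

Dose to a target is  D_t = sum_s a~_s S(t <- s).  The S-factor table is
derived from the same voxel kernel and phantom used by the voxel-level arm
(uniform unit cumulated activity in each source, mean dose per target), so
the two arms are comparable by construction.  Mass adaptation rescales the
self-dose components to the patient's organ masses: the non-penetrating
(electron) part as m_ref/m, the photon self-absorption part as
(m_ref/m)^(2/3) — the standard absorbed-fraction scaling of organ-level
codes.  Tumors use a unit-density sphere model (self dose only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageVolume
from .dose import _FFTConvolver
from .kernel import DoseKernel, sphere_self_dose
from .nuclide import NuclideData
from .tiac import TIACTable


@dataclass
class SFactorTable:
    """S[target][source] in mGy/(MBq h), split into electron and photon parts."""

    electron: pd.DataFrame   # rows: targets, cols: sources
    photon: pd.DataFrame
    reference_masses_g: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> pd.DataFrame:
        return self.electron + self.photon

    def copy(self) -> "SFactorTable":
        return SFactorTable(self.electron.copy(), self.photon.copy(),
                            dict(self.reference_masses_g))


def derive_sfactors(
    masks: dict[str, np.ndarray],
    masses_g: dict[str, float],
    kernel: DoseKernel,
    spacing_mm: tuple[float, float, float],
) -> SFactorTable:
    """Mean dose per target region from unit cumulated activity uniformly
    distributed in each source region, using the voxel kernel."""
    labels = list(masks)
    if not labels:
        raise ValueError("no organs given")
    shape = np.asarray(masks[labels[0]]).shape
    conv_e = _FFTConvolver(kernel.k_electron, shape)
    conv_p = _FFTConvolver(kernel.k_photon, shape)

    S_e = pd.DataFrame(0.0, index=labels, columns=labels)
    S_p = pd.DataFrame(0.0, index=labels, columns=labels)
    for src in labels:
        m = np.asarray(masks[src], dtype=bool)
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"organ {src} has no voxels")
        unit = m / n  # 1 MBq.h spread uniformly
        d_e = conv_e(unit)
        d_p = conv_p(unit)
        for tgt in labels:
            tm = np.asarray(masks[tgt], dtype=bool)
            S_e.loc[tgt, src] = float(d_e[tm].mean())
            S_p.loc[tgt, src] = float(d_p[tm].mean())
    return SFactorTable(S_e, S_p, dict(masses_g))


def adapt_masses(table: SFactorTable, patient_masses_g: dict[str, float]) -> SFactorTable:
    """Rescale self-dose entries to patient organ masses.

    electron self S  *= m_ref/m ; photon self S *= (m_ref/m)^(2/3);
    cross terms are left unchanged.
    """
    out = table.copy()
    for organ, m in patient_masses_g.items():
        if m <= 0:
            raise ValueError(f"nonpositive mass for {organ}")
        if organ not in table.reference_masses_g:
            continue
        m_ref = table.reference_masses_g[organ]
        if organ in out.electron.index:
            out.electron.loc[organ, organ] *= m_ref / m
            out.photon.loc[organ, organ] *= (m_ref / m) ** (2.0 / 3.0)
    out.reference_masses_g = dict(table.reference_masses_g)
    return out


@dataclass
class OrganDoseReport:
    doses: pd.DataFrame          # per-organ dose mGy/MBq
    tiacs: pd.DataFrame
    patient_masses_g: dict[str, float] = field(default_factory=dict)


def organ_doses(tiacs: TIACTable, table: SFactorTable) -> OrganDoseReport:
    """MIRD sum D_t = sum_s a~_s S[t][s], per MBq injected."""
    sources = [lab for lab in tiacs.entries
               if lab not in ("whole_body",) and tiacs[lab] > 0]
    missing = [s for s in sources if s not in table.total.columns]
    if missing:
        raise ValueError(f"TIAC sources without an S-factor column: {missing}")
    S = table.total
    rows = []
    for tgt in S.index:
        d = sum(tiacs[s] * float(S.loc[tgt, s]) for s in sources)
        d_self = tiacs[tgt] * float(S.loc[tgt, tgt]) if tgt in tiacs.entries else 0.0
        rows.append(dict(label=tgt, dose_mGy_per_MBq=d,
                         self_dose_mGy_per_MBq=d_self,
                         cross_dose_mGy_per_MBq=d - d_self))
    return OrganDoseReport(pd.DataFrame(rows), tiacs.to_frame(),
                           dict(table.reference_masses_g))


def sphere_dose(tumor_mass_g: float, tiac_h: float, nuclide: NuclideData,
                density_g_per_ml: float = 1.0) -> float:
    """Self dose (mGy/MBq) of a unit-density sphere with uniform cumulated
    activity: local electron deposition plus photon self-absorption
    integrated over the sphere.  Cross dose is excluded by construction."""
    if not 1.0 <= tumor_mass_g <= 1000.0:
        raise ValueError(f"tumor mass {tumor_mass_g} g outside the tabulated 1-1000 g range")
    if tiac_h < 0:
        raise ValueError("TIAC must be nonnegative")
    volume_ml = tumor_mass_g / density_g_per_ml
    radius_cm = (3.0 * volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)
    electron = nuclide.electron_energy_J_per_MBqh / (tumor_mass_g / 1000.0) * 1000.0  # mGy/MBq.h
    photon = sphere_self_dose(radius_cm, nuclide, density_g_per_ml)
    return tiac_h * (electron + photon)


def uniform_source_maps(
    tiacs: TIACTable,
    masks: dict[str, np.ndarray],
    grid: ImageVolume,
) -> dict[str, ImageVolume]:
    """Cumulated-activity maps (MBq h per voxel, per MBq injected) spreading
    each region's TIAC uniformly over its mask — the input of the
    voxel-level arm when only organ TIACs are known."""
    out = {}
    for lab, mask in masks.items():
        if lab not in tiacs.entries:
            continue
        mask = np.asarray(mask, dtype=bool)
        arr = np.zeros(grid.shape)
        arr[mask] = tiacs[lab] / mask.sum()
        out[lab] = grid.with_data(arr, unit="MBq.h")
    return out
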