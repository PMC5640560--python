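"""Time-integrated activity coefficients from the hybrid planar/SPECT data.

The planar series supplies the shape of each organ's washout (its
effective half-life); the single quantitative SPECT supplies one absolute
activity sample.  Rescaling the mono-exponential through that sample and
integrating from zero to infinity gives the TIAC:

    a~ = (A_spect / A_inj) * 2^(t_spect / T_eff) * T_eff / ln 2    [hours]

The urinary bladder contents use a voiding-bladder model, and the
remainder of body is the whole-body TIAC minus all explicit regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuclide import LN2, NuclideData
from .planar_kinetics import KineticFit


@dataclass
class BladderModelParams:
    f_u: float = 0.5              # fraction of injected activity excreted to urine
    T_u_h: float = 2.0            # urinary biologic half-life
    voiding_interval_h: float = 3.5

    def validate(self) -> None:
        if not 0 <= self.f_u <= 1:
            raise ValueError("f_u must be in [0, 1]")
        if self.T_u_h <= 0 or self.voiding_interval_h <= 0:
            raise ValueError("T_u and voiding interval must be positive")


@dataclass
class TIACEntry:
    label: str
    tiac_h: float
    T_eff_h: float | None = None
    spect_activity_MBq: float | None = None
    spect_time_h: float | None = None
    method: str = "hybrid"


@dataclass
class TIACTable:
    entries: dict[str, TIACEntry] = field(default_factory=dict)
    injected_MBq: float = 1.0

    def add(self, entry: TIACEntry) -> None:
        if entry.tiac_h < 0:
            raise ValueError(f"negative TIAC for {entry.label}")
        self.entries[entry.label] = entry

    def __getitem__(self, label: str) -> float:
        return self.entries[label].tiac_h

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def organ_labels(self) -> list[str]:
        skip = {"whole_body", "remainder", "bladder"}
        return [k for k in self.entries if k not in skip]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    label=e.label,
                    tiac_h=e.tiac_h,
                    T_eff_h=e.T_eff_h,
                    spect_activity_MBq=e.spect_activity_MBq,
                    spect_time_h=e.spect_time_h,
                    method=e.method,
                )
                for e in self.entries.values()
            ]
        )


def tiac_from_hybrid(fit: KineticFit, spect_activity_MBq: float, t_spect_h: float,
                     injected_MBq: float) -> float:
    """Rescale a planar washout fit through the absolute SPECT sample and
    integrate (instant-uptake assumption).  Result in hours (Bq h / Bq)."""
    if fit.T_eff_h <= 0:
        raise ValueError("T_eff must be positive")
    if not 0 < spect_activity_MBq <= injected_MBq:
        raise ValueError("SPECT activity must be positive and not exceed injected activity")
    frac0 = spect_activity_MBq * 2.0 ** (t_spect_h / fit.T_eff_h) / injected_MBq
    if frac0 > 1 + 1e-9:
        raise ValueError(
            f"extrapolated t=0 fraction {frac0:.3f} exceeds 1: inconsistent inputs"
        )
    return frac0 * fit.T_eff_h / LN2


def bladder_tiac(params: BladderModelParams, nuclide: NuclideData,
                 dt_h: float = 0.005, n_half_lives: float = 10.0) -> float:
    """Numerical integral of the voiding-bladder content over [0, 10 T_phys].

    Between voids the bladder accumulates the physically decaying urinary
    inflow  f_u * lambda_u * exp(-(lambda_u) s) (biologic), and is emptied
    at every multiple of the voiding interval.
    """
    params.validate()
    if params.f_u == 0:
        return 0.0
    lam_u = LN2 / params.T_u_h
    lam_p = nuclide.lambda_phys
    t = np.arange(0.0, n_half_lives * nuclide.half_life_h + dt_h, dt_h)
    t_void = np.floor(t / params.voiding_interval_h) * params.voiding_interval_h
    content = params.f_u * np.exp(-lam_p * t) * (np.exp(-lam_u * t_void) - np.exp(-lam_u * t))
    return float(np.trapezoid(content, t))


def whole_body_tiac(fit: KineticFit) -> float:
    """Whole-body TIAC with the t=0 fraction fixed at 1 (everything
    injected is in the body at injection time)."""
    return fit.T_eff_h / LN2


def remainder_tiac(table: TIACTable) -> float:
    """Whole-body TIAC minus all explicit organ/tumor/bladder TIACs."""
    if "whole_body" not in table:
        raise ValueError("whole-body TIAC entry missing")
    total = table["whole_body"]
    subtracted = sum(table[k] for k in table.organ_labels())
    if "bladder" in table:
        subtracted += table["bladder"]
    rem = total - subtracted
    if rem < 0:
        raise ValueError(
            f"remainder TIAC negative ({rem:.3f} h): organ TIACs exceed whole body"
        )
    return rem
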