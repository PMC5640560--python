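"""Nuclear decay data and photon interaction coefficients for water.

Emission tables and water attenuation data are loaded from a packaged data
file (``data/physics.json``); nothing physical is hard-coded here beyond
unit conversions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

J_PER_KEV = 1.602176634e-16
DECAYS_PER_MBQ_H = 3.6e9
TC99M_HALF_LIFE_H = 6.0067
LN2 = float(np.log(2.0))


def _load_physics() -> dict:
    with resources.files("hybridose.data").joinpath("physics.json").open() as fh:
        return json.load(fh)


_PHYSICS = _load_physics()


@dataclass(frozen=True)
class Emission:
    kind: str  # "photon" | "electron"
    energy_keV: float
    yield_per_decay: float


@dataclass(frozen=True)
class NuclideData:
    """Half-life and per-decay emission table of a radionuclide."""

    name: str
    half_life_h: float
    emissions: tuple[Emission, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ValueError("physical half-life must be positive")
        if any(e.yield_per_decay < 0 for e in self.emissions):
            raise ValueError("emission yields must be nonnegative")

    @property
    def lambda_phys(self) -> float:
        return LN2 / self.half_life_h

    @property
    def photon_lines(self) -> list[Emission]:
        return [e for e in self.emissions if e.kind == "photon"]

    @property
    def electron_energy_keV_per_decay(self) -> float:
        return sum(e.energy_keV * e.yield_per_decay for e in self.emissions if e.kind == "electron")

    @property
    def photon_energy_keV_per_decay(self) -> float:
        return sum(e.energy_keV * e.yield_per_decay for e in self.photon_lines)

    @property
    def electron_energy_J_per_MBqh(self) -> float:
        """Locally deposited (non-penetrating) energy per unit cumulated activity."""
        return self.electron_energy_keV_per_decay * J_PER_KEV * DECAYS_PER_MBQ_H


def load_nuclide(name: str = "Tc-99m") -> NuclideData:
    try:
        entry = _PHYSICS["nuclides"][name]
    except KeyError:
        raise KeyError(f"no packaged decay data for nuclide {name!r}") from None
    emissions = tuple(
        Emission(e["type"], float(e["energy_keV"]), float(e["yield"])) for e in entry["emissions"]
    )
    return NuclideData(name, float(entry["half_life_h"]), emissions)


class WaterAttenuation:
    """Log-log interpolation of water mu/rho and mu_en/rho (cm^2/g)."""

    def __init__(self) -> None:
        w = _PHYSICS["water"]
        self._logE = np.log(np.asarray(w["energy_keV"], dtype=float))
        self._log_mu = np.log(np.asarray(w["mu_over_rho"], dtype=float))
        self._log_muen = np.log(np.asarray(w["mu_en_over_rho"], dtype=float))
        self.density = float(w["density_g_per_ml"])
        self.buildup_model = w.get("buildup_model", "energy-conserving-linear")

    def buildup_a(self, energy_keV: float) -> float:
        """Linear buildup coefficient a_E = mu/mu_en - 1.

        With B = 1 + a_E mu r the point kernel's infinite-medium energy
        integral equals the emitted photon energy exactly — the standard
        normalization of analytic dose point kernels.
        """
        return self.mu_over_rho(energy_keV) / self.mu_en_over_rho(energy_keV) - 1.0

    def mu_over_rho(self, energy_keV: float) -> float:
        return float(np.exp(np.interp(np.log(energy_keV), self._logE, self._log_mu)))

    def mu_en_over_rho(self, energy_keV: float) -> float:
        return float(np.exp(np.interp(np.log(energy_keV), self._logE, self._log_muen)))

    def mu_linear(self, energy_keV: float) -> float:
        """Linear (narrow-beam) attenuation coefficient in 1/cm."""
        return self.mu_over_rho(energy_keV) * self.density


WATER = WaterAttenuation()
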