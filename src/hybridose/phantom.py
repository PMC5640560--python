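"""Synthetic digital phantoms and time-resolved activity maps.

The phantom is a torso-like elliptical cylinder containing ellipsoidal
organs (kidneys, liver, spleen), an optional spherical tumor and bladder,
and a "remainder of body" region (body minus organs).  All linear
dimensions scale with ``age_scale``, so the same geometry serves adult
(``age_scale=1``) and pediatric studies.

Organ kinetics follow the mono-exponential washout model
``A_r(t) = f0 * A_inj * 2^(-t/T_eff)``, optionally multiplied by an uptake
term ``1 - 2^(-t/T_up)``.  A urinary pathway routes a fraction ``f_u`` of
the injected activity into the bladder with biologic half-life ``T_u`` and
periodic voiding; the remainder region carries the leftover whole-body
activity spread uniformly over the anatomical body volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .core import ImageVolume, centered_grid
from .nuclide import LN2, NuclideData, WATER, load_nuclide

#: broad-beam-free linear attenuation of water at 140 keV, 1/cm
MU_WATER_140KEV = WATER.mu_linear(140.511)

ORGAN_LABELS = ("left_kidney", "right_kidney", "liver", "spleen")


class PhantomValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    half_axes_mm: tuple[float, float, float]

    def volume_ml(self) -> float:
        a, b, c = self.half_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0

    def scaled(self, s: float) -> "Ellipsoid":
        return Ellipsoid(tuple(c * s for c in self.center_mm), tuple(a * s for a in self.half_axes_mm))


@dataclass(frozen=True)
class Region:
    label: str
    shapes: tuple[Ellipsoid, ...]
    density_g_per_ml: float = 1.0

    def volume_ml(self) -> float:
        # shapes of one region are assumed disjoint (validated on the grid)
        return sum(s.volume_ml() for s in self.shapes)

    def scaled(self, s: float) -> "Region":
        return Region(self.label, tuple(e.scaled(s) for e in self.shapes), self.density_g_per_ml)


@dataclass
class GridSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_mm: float = 4.418


@dataclass
class PhantomSpec:
    """Geometry of body, organs and voxel grid.

    ``body`` is (half_axis_x_mm, half_axis_y_mm, full_length_mm) of an
    elliptical cylinder along z.  The cylinder may be longer than the grid;
    the full analytic volume defines the remainder-of-body mass while only
    the in-grid part is voxelized.
    """

    body: tuple[float, float, float] = (180.0, 110.0, 1170.0)
    regions: list[Region] = field(default_factory=list)
    grid: GridSpec = field(default_factory=GridSpec)
    age_scale: float = 1.0
    body_density_g_per_ml: float = 1.0

    MIN_TUMOR_ML = 12.0  # below this, adaptive-threshold segmentation is not validated

    def scaled_body(self) -> tuple[float, float, float]:
        return tuple(b * self.age_scale for b in self.body)

    def scaled_regions(self) -> list[Region]:
        return [r.scaled(self.age_scale) for r in self.regions]

    def body_volume_ml(self) -> float:
        a, b, L = self.scaled_body()
        return np.pi * a * b * L / 1000.0

    def body_mass_g(self) -> float:
        return self.body_volume_ml() * self.body_density_g_per_ml

    def validate(self) -> None:
        a, b, L = self.body
        if min(a, b, L) <= 0 or self.age_scale <= 0:
            raise PhantomValidationError("body half-axes, length and age_scale must be positive")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise PhantomValidationError("duplicate region labels")
        for r in self.regions:
            if r.density_g_per_ml <= 0:
                raise PhantomValidationError(f"region {r.label}: nonpositive density")
            if r.label.startswith("tumor") and r.volume_ml() * self.age_scale**3 < self.MIN_TUMOR_ML:
                raise PhantomValidationError(
                    f"region {r.label}: tumor volume "
                    f"{r.volume_ml() * self.age_scale**3:.1f} mL below the {self.MIN_TUMOR_ML} mL "
                    "segmentation validity bound"
                )


def _ellipsoid_mask(vol_shape, spacing, origin, ell: Ellipsoid) -> np.ndarray:
    axes = [origin[a] + (np.arange(vol_shape[a]) + 0.5) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    cx, cy, cz = ell.center_mm
    ax, ay, az = ell.half_axes_mm
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec):
    """Voxelize a phantom.

    Returns ``(label_volume, attenuation_map, mass_table)``.  The label
    volume is 0 outside the body, 1 in the remainder region, and 2.. for the
    listed regions (mapping in ``label_volume.unit`` metadata is returned in
    the mass table).  The attenuation map is the narrow-beam mu of water at
    140 keV (1/cm) inside the body, 0 outside.  The mass table has one row
    per region plus ``remainder`` and ``body_total`` (analytic, includes any
    off-grid body volume).
    """
    spec.validate()
    shape = tuple(spec.grid.shape)
    spacing, origin = centered_grid(shape, spec.grid.voxel_mm)
    voxel_ml = float(np.prod(spacing)) / 1000.0

    a, b, L = spec.scaled_body()
    axes = [origin[d] + (np.arange(shape[d]) + 0.5) * spacing[d] for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    body = (((X / a) ** 2 + (Y / b) ** 2) <= 1.0) & (np.abs(Z) <= L / 2.0)

    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = 1
    index = {"remainder": 1}
    rows = []
    masks = {}
    for k, region in enumerate(spec.scaled_regions(), start=2):
        mask = np.zeros(shape, dtype=bool)
        for ell in region.shapes:
            mask |= _ellipsoid_mask(shape, spacing, origin, ell)
        if not mask.any():
            raise PhantomValidationError(f"region {region.label} has no voxels on the grid")
        outside = mask & ~body
        if outside.any():
            raise PhantomValidationError(f"region {region.label} extends outside the body")
        for other_label, other_mask in masks.items():
            if (mask & other_mask).any():
                raise PhantomValidationError(
                    f"regions overlap: {region.label} and {other_label}"
                )
        masks[region.label] = mask
        labels[mask] = k
        index[region.label] = k
        n = int(mask.sum())
        rows.append(
            dict(
                label=region.label,
                index=k,
                n_voxels=n,
                volume_ml=n * voxel_ml,
                mass_g=n * voxel_ml * region.density_g_per_ml,
            )
        )

    n_rem = int((labels == 1).sum())
    organ_mass = sum(r["mass_g"] for r in rows)
    rows.append(
        dict(
            label="remainder",
            index=1,
            n_voxels=n_rem,
            volume_ml=n_rem * voxel_ml,
            mass_g=max(spec.body_mass_g() - organ_mass, n_rem * voxel_ml),
        )
    )
    rows.append(
        dict(
            label="body_total",
            index=-1,
            n_voxels=int(body.sum()),
            volume_ml=spec.body_volume_ml(),
            mass_g=spec.body_mass_g(),
        )
    )
    mass_table = pd.DataFrame(rows)

    label_vol = ImageVolume(labels, spacing, origin, unit="label")
    mu = np.where(body, MU_WATER_140KEV, 0.0)
    mu_vol = ImageVolume(mu, spacing, origin, unit="1/cm")
    return label_vol, mu_vol, mass_table


def region_masks(label_vol: ImageVolume, mass_table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean mask per region label (including 'remainder')."""
    out = {}
    for _, row in mass_table.iterrows():
        if row["label"] == "body_total":
            continue
        out[row["label"]] = label_vol.data == row["index"]
    return out


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class RegionKinetics:
    f0: float  # fraction of injected activity at t=0+ (after any uptake phase)
    T_eff_h: float
    T_up_h: float | None = None  # optional uptake half-time


@dataclass
class KineticsSpec:
    injected_MBq: float = 500.0
    regions: dict[str, RegionKinetics] = field(default_factory=dict)
    remainder_T_eff_h: float = 5.189  # gives remainder TIAC 5.01 h at default f0/f_u
    f_u: float = 0.15
    T_u_h: float = 1.5
    voiding_interval_h: float = 3.5
    nuclide: NuclideData = field(default_factory=load_nuclide)

    def validate(self) -> None:
        if self.injected_MBq <= 0:
            raise ValueError("injected activity must be positive")
        if not 0 <= self.f_u <= 1:
            raise ValueError("f_u must be within [0, 1]")
        if self.T_u_h <= 0 or self.voiding_interval_h <= 0:
            raise ValueError("urinary half-life and voiding interval must be positive")
        total_f0 = sum(r.f0 for r in self.regions.values())
        if total_f0 + self.f_u > 1 + 1e-12:
            raise ValueError(f"sum of f0 ({total_f0:.3f}) + f_u ({self.f_u}) exceeds 1")
        for label, r in self.regions.items():
            if r.T_eff_h <= 0:
                raise ValueError(f"{label}: T_eff must be positive")
        if self.remainder_T_eff_h <= 0:
            raise ValueError("remainder T_eff must be positive")
        # whole-body retention may never exceed pure physical decay
        t = np.linspace(0.0, 4 * self.nuclide.half_life_h, 200)
        wb = self.whole_body_fraction(t)
        phys = 2.0 ** (-t / self.nuclide.half_life_h)
        if np.any(wb > phys * (1 + 1e-9)):
            raise ValueError("whole-body retention exceeds physical decay")

    @property
    def remainder_f0(self) -> float:
        return 1.0 - sum(r.f0 for r in self.regions.values()) - self.f_u

    def region_activity_MBq(self, label: str, t: float | np.ndarray) -> float | np.ndarray:
        """Activity of one named region at time t (hours post-injection)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        if label == "remainder":
            a = self.remainder_f0 * 2.0 ** (-t / self.remainder_T_eff_h)
        elif label == "bladder":
            a = self.bladder_fraction(t)
        else:
            r = self.regions[label]
            a = r.f0 * 2.0 ** (-t / r.T_eff_h)
            if r.T_up_h is not None:
                a = a * (1.0 - 2.0 ** (-t / r.T_up_h))
        return self.injected_MBq * a

    def bladder_fraction(self, t: float | np.ndarray) -> np.ndarray:
        """Bladder-content activity as a fraction of injected.

        Between voids the content is the physically decayed integral of the
        urinary inflow; it resets to zero at every multiple of the voiding
        interval (closed-form piecewise solution of the voiding model).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lam_u = LN2 / self.T_u_h
        lam_p = self.nuclide.lambda_phys
        t_void = np.floor(t / self.voiding_interval_h) * self.voiding_interval_h
        return self.f_u * np.exp(-lam_p * t) * (np.exp(-lam_u * t_void) - np.exp(-lam_u * t))

    def whole_body_fraction(self, t: np.ndarray) -> np.ndarray:
        """In-body activity (organs + remainder + bladder) / injected."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        total = np.zeros_like(t)
        for label in self.regions:
            total += np.asarray(self.region_activity_MBq(label, t)) / self.injected_MBq
        total += self.remainder_f0 * 2.0 ** (-t / self.remainder_T_eff_h)
        total += self.bladder_fraction(t)
        return total

    def true_tiac_h(self, label: str) -> float:
        """Analytic time-integrated activity coefficient of a region (hours)."""
        if label == "remainder":
            return self.remainder_f0 * self.remainder_T_eff_h / LN2
        if label == "bladder":
            t = np.arange(0.0, 10 * self.nuclide.half_life_h, 0.005)
            return float(np.trapezoid(self.bladder_fraction(t), t))
        r = self.regions[label]
        tiac = r.f0 * r.T_eff_h / LN2
        if r.T_up_h is not None:
            # integral of f0*(1-2^(-t/Tup))*2^(-t/Teff) over [0, inf)
            tiac -= r.f0 / (LN2 / r.T_eff_h + LN2 / r.T_up_h)
        return tiac


def activity_map(
    label_vol: ImageVolume,
    mass_table: pd.DataFrame,
    kinetics: KineticsSpec,
    t_h: float,
    body_volume_ml: float | None = None,
) -> ImageVolume:
    """Voxelized activity distribution (MBq per voxel) at time ``t_h``.

    Each region is uniform at ``A_r(t)/V_r``.  The remainder concentration
    uses the full anatomical body volume (off-grid limbs included), so only
    the in-grid share of the remainder activity lands on the grid.
    """
    if t_h < 0:
        raise ValueError("time must be nonnegative")
    kinetics.validate()
    voxel_ml = label_vol.voxel_volume_ml
    act = np.zeros(label_vol.shape, dtype=float)
    organ_volume = 0.0
    for _, row in mass_table.iterrows():
        label = row["label"]
        if label in ("remainder", "body_total"):
            continue
        mask = label_vol.data == row["index"]
        if label in kinetics.regions or label == "bladder":
            A = float(np.asarray(kinetics.region_activity_MBq(label, t_h)))
        else:
            A = 0.0
        act[mask] = A / row["n_voxels"]
        organ_volume += row["volume_ml"]
    if body_volume_ml is None:
        row = mass_table.loc[mass_table["label"] == "body_total"].iloc[0]
        body_volume_ml = float(row["volume_ml"])
    A_rem = float(np.asarray(kinetics.region_activity_MBq("remainder", t_h)))
    conc = A_rem / max(body_volume_ml - organ_volume, voxel_ml)  # MBq/mL
    act[label_vol.data == 1] = conc * voxel_ml
    return ImageVolume(act, label_vol.spacing, label_vol.origin, unit="MBq")


# ---------------------------------------------------------------------------
# reference phantoms and kinetics

#: linear scale whose cube maps the 73 kg adult body to a ~40 kg 12-year-old
PEDIATRIC_AGE_SCALE = 0.818


def reference_phantom(
    age_scale: float = 1.0,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    voxel_mm: float = 4.418,
    include_tumor: bool = False,
    include_bladder: bool = True,
) -> PhantomSpec:
    """Torso phantom with ICRP-like adult organ masses, scaled by age_scale.

    At ``age_scale=1``: kidneys 2 x 154 g, liver 1790 g, spleen 182 g,
    body 73 kg.  ``PEDIATRIC_AGE_SCALE`` gives a ~40 kg pediatric phantom.
    """
    regions = [
        Region("left_kidney", (Ellipsoid((-60, -45, -65), (35, 25, 42)),)),
        Region("right_kidney", (Ellipsoid((60, -45, -65), (35, 25, 42)),)),
        Region("liver", (Ellipsoid((60, 20, 45), (95, 75, 60)),)),
        Region("spleen", (Ellipsoid((-100, 5, 20), (55, 33, 24)),)),
    ]
    grid_half_z = grid_shape[2] * voxel_mm / 2.0
    if include_bladder and (180.0 + 25.0) * age_scale <= grid_half_z:
        # bladder sits caudally; only included when the axial FOV reaches it
        regions.append(Region("bladder", (Ellipsoid((0, -30, -180), (25, 25, 25)),)))
    if include_tumor:
        regions.append(Region("tumor_1", (Ellipsoid((0, -40, 150), (20, 20, 20)),)))
    return PhantomSpec(
        body=(180.0, 110.0, 1170.0),
        regions=regions,
        grid=GridSpec(tuple(grid_shape), voxel_mm),
        age_scale=age_scale,
    )


def reference_kinetics(injected_MBq: float = 500.0, tumor: bool = False) -> KineticsSpec:
    """Default kinetics reproducing the study-mean pediatric organ TIACs.

    f0 values are set so that f0 * T_eff / ln2 equals the mean TIACs
    (kidneys 0.37 h split equally, liver 0.56 h, spleen 0.43 h) at the mean
    effective half-lives (kidneys ~4.83 h, liver 5.07 h, spleen 5.83 h).
    """
    regions = {
        "left_kidney": RegionKinetics(f0=0.185 * LN2 / 4.83, T_eff_h=4.83),
        "right_kidney": RegionKinetics(f0=0.185 * LN2 / 4.83, T_eff_h=4.83),
        "liver": RegionKinetics(f0=0.56 * LN2 / 5.07, T_eff_h=5.07),
        "spleen": RegionKinetics(f0=0.43 * LN2 / 5.83, T_eff_h=5.83),
    }
    if tumor:
        regions["tumor_1"] = RegionKinetics(f0=0.07 * LN2 / 4.18, T_eff_h=4.18)
    spec = KineticsSpec(injected_MBq=injected_MBq, regions=regions)
    spec.validate()
    return spec


def pediatric_mass_ranges() -> dict[str, tuple[float, float]]:
    with resources.files("hybridose.data").joinpath("reference_anatomy.json").open() as fh:
        data = json.load(fh)
    return {k: tuple(v) for k, v in data["pediatric_mass_ranges_g"].items()}


def age_model_masses(model: str) -> dict[str, float]:
    """Reference organ masses (g) of a named age model ('1','5','10','15','adult')."""
    with resources.files("hybridose.data").joinpath("reference_anatomy.json").open() as fh:
        data = json.load(fh)
    return dict(data["age_models"][model])


# ---------------------------------------------------------------------------
# YAML round-trip for specs


def phantom_to_yaml(spec: PhantomSpec, path: str) -> None:
    doc = dict(
        body=list(spec.body),
        age_scale=spec.age_scale,
        body_density_g_per_ml=spec.body_density_g_per_ml,
        grid=dict(shape=list(spec.grid.shape), voxel_mm=spec.grid.voxel_mm),
        regions=[
            dict(
                label=r.label,
                density_g_per_ml=r.density_g_per_ml,
                shapes=[
                    dict(center_mm=list(e.center_mm), half_axes_mm=list(e.half_axes_mm))
                    for e in r.shapes
                ],
            )
            for r in spec.regions
        ],
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def phantom_from_yaml(path: str) -> PhantomSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    known = {"body", "age_scale", "body_density_g_per_ml", "grid", "regions"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown keys in phantom spec: {sorted(unknown)}")
    regions = [
        Region(
            r["label"],
            tuple(Ellipsoid(tuple(s["center_mm"]), tuple(s["half_axes_mm"])) for s in r["shapes"]),
            r.get("density_g_per_ml", 1.0),
        )
        for r in doc["regions"]
    ]
    return PhantomSpec(
        body=tuple(doc["body"]),
        regions=regions,
        grid=GridSpec(tuple(doc["grid"]["shape"]), doc["grid"]["voxel_mm"]),
        age_scale=doc.get("age_scale", 1.0),
        body_density_g_per_ml=doc.get("body_density_g_per_ml", 1.0),
    )
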