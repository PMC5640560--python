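"""End-to-end study orchestration.

``run_study`` chains the full hybrid dosimetry analysis on one synthetic
(or ingested) study: simulate the acquisitions, calibrate and reconstruct
the SPECT, extract planar time-activity curves and fit half-lives, segment
the quantitative SPECT, assemble TIACs (organs, voiding bladder, remainder
of body), and run both dosimetry arms — voxel-kernel convolution with
self/cross decomposition and DVHs, and the organ-level MIRD engine with
mass-adapted and default-mass variants plus a sphere model for tumors.

All outputs are plain CSV/JSON; a manifest records the seed, parameters
and a config hash so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.stats import pearsonr

from . import __version__
from .core import ImageVolume
from .kernel import DoseKernel, build_kernel
from .nuclide import LN2, NuclideData, load_nuclide
from .phantom import (
    KineticsSpec,
    PhantomSpec,
    activity_map,
    age_model_masses,
    build_phantom,
    region_masks,
)
from .planar_kinetics import (
    KineticFit,
    TimeActivityCurve,
    build_tac,
    fit_monoexponential,
    make_background_rind,
    make_roi50,
    propagate_roi,
)
from .projector import AcquisitionSpec, simulate_calibration, simulate_planar, simulate_spect
from .recon import ReconConfig, calibrate, counts_to_activity, osem_reconstruct
from .dose import DoseResult, organ_dose_decomposition
from .organ_dose import (
    adapt_masses,
    derive_sfactors,
    organ_doses,
    sphere_dose,
    uniform_source_maps,
)
from .segmentation import CalibrationCurve, segment_region
from .tiac import (
    BladderModelParams,
    TIACEntry,
    TIACTable,
    bladder_tiac,
    remainder_tiac,
    tiac_from_hybrid,
    whole_body_tiac,
)

log = logging.getLogger("hybridose")

CALIBRATION_SOURCE_MBQ = 4.82   # 3 mL point-source vial
CALIBRATION_DURATION_S = 300.0


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class StudyConfig:
    phantom: PhantomSpec
    kinetics: KineticsSpec
    acquisition: AcquisitionSpec
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(broad_beam_scale=1.0))
    curves: tuple[CalibrationCurve, CalibrationCurve] | None = None
    age_years: float | None = None
    age_model: str = "adult"          # reference model for the default-mass arm
    output_dir: str | None = None
    seed: int = 0
    image_weighted_sources: bool = True
    stages: str = "full"              # "full" | "tiac" (stop after TIAC assembly)
    nuclide: NuclideData = field(default_factory=load_nuclide)

    def config_hash(self) -> str:
        blob = json.dumps(
            dict(
                grid=list(self.phantom.grid.shape),
                voxel=self.phantom.grid.voxel_mm,
                age_scale=self.phantom.age_scale,
                regions=sorted(r.label for r in self.phantom.regions),
                injected=self.kinetics.injected_MBq,
                planar_times=list(self.acquisition.planar_times_h),
                spect_time=self.acquisition.spect_time_h,
                seed=self.seed,
                recon=[self.recon.n_iterations, self.recon.n_subsets, self.recon.broad_beam_scale],
            ),
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    half_lives: pd.DataFrame
    tiacs: TIACTable
    doses: pd.DataFrame               # three arms side by side
    voxel_result: DoseResult | None
    segmentations: dict
    fits: dict[str, KineticFit]
    tacs: dict[str, TimeActivityCurve]
    manifest: dict
    age_years: float | None = None


def _organ_labels(cfg: StudyConfig) -> list[str]:
    phantom_labels = {r.label for r in cfg.phantom.regions}
    return [lab for lab in cfg.kinetics.regions if lab in phantom_labels]


def _seed_box(mask: np.ndarray, margin: int = 3):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def run_study(cfg: StudyConfig) -> StudyReport:
    t_start = time.time()
    cfg.acquisition.rng_seed = cfg.seed
    organs = _organ_labels(cfg)
    nuclide = cfg.nuclide

    def stage(name):
        log.info("stage %-14s t=%.1fs", name, time.time() - t_start)

    try:
        stage("phantom")
        labels, mu, mass_table = build_phantom(cfg.phantom)
        masks = region_masks(labels, mass_table)
    except Exception as e:  # noqa: BLE001
        raise StageError("phantom", e) from e

    try:
        stage("simulate")
        c1, c2 = simulate_calibration(CALIBRATION_SOURCE_MBQ, CALIBRATION_DURATION_S,
                                      cfg.acquisition)
        planars = []
        for t in cfg.acquisition.planar_times_h:
            act = activity_map(labels, mass_table, cfg.kinetics, t)
            planars.append(simulate_planar(act, mu, cfg.acquisition, time_h=t))
        act_spect = activity_map(labels, mass_table, cfg.kinetics, cfg.acquisition.spect_time_h)
        projections = simulate_spect(act_spect, mu, cfg.acquisition)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    try:
        stage("recon")
        cf = calibrate(c1, c2, CALIBRATION_DURATION_S, CALIBRATION_SOURCE_MBQ)
        recon = osem_reconstruct(projections, mu, cfg.recon)
        quant = counts_to_activity(recon, cf, cfg.acquisition.total_acq_time_s)
    except Exception as e:  # noqa: BLE001
        raise StageError("recon", e) from e

    try:
        stage("kinetics")
        anteriors = [p[0] for p in planars]
        all_organ_proj = np.zeros(anteriors[0].shape, dtype=bool)
        for lab in masks:
            if lab in ("remainder",):
                continue
            all_organ_proj |= masks[lab].any(axis=1)
        fits: dict[str, KineticFit] = {}
        tacs: dict[str, TimeActivityCurve] = {}
        for lab in organs:
            proj_mask = masks[lab].any(axis=1)
            oversized = binary_dilation(proj_mask, iterations=3)
            bg = make_background_rind(oversized, exclude=all_organ_proj)
            roi = make_roi50(anteriors[0], oversized, label=lab, background=bg)
            tracked = propagate_roi(roi, anteriors[0], anteriors)
            tac = build_tac(lab, cfg.acquisition.planar_times_h, anteriors,
                            [r for r, _ in tracked], [f for _, f in tracked])
            tacs[lab] = tac
            fits[lab] = fit_monoexponential(tac, nuclide)
        # whole-body curve from total counts of both views
        wb_counts = np.array([a.total() + p.total() for a, p in planars])
        wb_tac = TimeActivityCurve("whole_body", np.asarray(cfg.acquisition.planar_times_h),
                                   wb_counts, wb_counts, np.zeros_like(wb_counts))
        wb_fit = fit_monoexponential(wb_tac, nuclide)
        fits["whole_body"] = wb_fit
        tacs["whole_body"] = wb_tac
    except Exception as e:  # noqa: BLE001
        raise StageError("kinetics", e) from e

    try:
        stage("segment")
        segmentations = {}
        if cfg.curves is None:
            raise ValueError("segmentation calibration curves are required "
                             "(build them once with build_calibration_curves)")
        hot_labels = [lab for lab in masks if lab not in ("remainder",)]
        for lab in organs:
            box = _seed_box(masks[lab])
            # spill from adjacent hot organs is masked out of the seed box
            # and background shell, like ROIs drawn to avoid neighbors
            exclude = np.zeros(labels.shape, dtype=bool)
            for other in hot_labels:
                if other != lab:
                    exclude |= binary_dilation(masks[other], iterations=2)
            segmentations[lab] = segment_region(quant, box, cfg.curves, label=lab,
                                                exclude=exclude)
    except Exception as e:  # noqa: BLE001
        raise StageError("segment", e) from e

    try:
        stage("tiac")
        injected = cfg.kinetics.injected_MBq
        table = TIACTable(injected_MBq=injected)
        for lab in organs:
            a = segmentations[lab].activity_MBq
            tiac = tiac_from_hybrid(fits[lab], a, cfg.acquisition.spect_time_h, injected)
            table.add(TIACEntry(lab, tiac, fits[lab].T_eff_h, a,
                                cfg.acquisition.spect_time_h))
        bladder_params = BladderModelParams(cfg.kinetics.f_u, cfg.kinetics.T_u_h,
                                            cfg.kinetics.voiding_interval_h)
        table.add(TIACEntry("bladder", bladder_tiac(bladder_params, nuclide),
                            method="voiding_bladder_model"))
        table.add(TIACEntry("whole_body", whole_body_tiac(wb_fit), wb_fit.T_eff_h,
                            method="whole_body_planar"))
        table.add(TIACEntry("remainder", remainder_tiac(table), method="subtraction"))
    except Exception as e:  # noqa: BLE001
        raise StageError("tiac", e) from e

    if cfg.stages == "tiac":
        half_lives = pd.DataFrame(
            [dict(label=lab, T_eff_h=f.T_eff_h, T_bio_h=f.T_bio_h, A0=f.A0,
                  flags=";".join(f.flags)) for lab, f in fits.items()]
        )
        manifest = dict(version=__version__, seed=cfg.seed, config_hash=cfg.config_hash(),
                        runtime_s=round(time.time() - t_start, 2))
        return StudyReport(half_lives, table, pd.DataFrame(), None, segmentations,
                           fits, tacs, manifest, age_years=cfg.age_years)

    try:
        stage("voxel_dose")
        half = max(labels.shape) // 2
        kern = build_kernel(nuclide, cfg.phantom.grid.voxel_mm, half)
        source_maps = _cumulated_source_maps(cfg, table, masks, segmentations, quant, labels)
        roi_masks = {lab: segmentations[lab].volume_mask for lab in organs}
        voxel_result = organ_dose_decomposition(source_maps, kern, roi_masks)
    except Exception as e:  # noqa: BLE001
        raise StageError("voxel_dose", e) from e

    try:
        stage("organ_dose")
        organ_table = _organ_level_doses(cfg, table, masks, segmentations, kern, labels, nuclide)
    except Exception as e:  # noqa: BLE001
        raise StageError("organ_dose", e) from e

    half_lives = pd.DataFrame(
        [dict(label=lab, T_eff_h=f.T_eff_h, T_bio_h=f.T_bio_h, A0=f.A0,
              flags=";".join(f.flags)) for lab, f in fits.items()]
    )
    doses = voxel_result.per_roi.merge(organ_table, on="label", how="outer")
    manifest = dict(
        version=__version__,
        seed=cfg.seed,
        config_hash=cfg.config_hash(),
        injected_MBq=cfg.kinetics.injected_MBq,
        grid=list(cfg.phantom.grid.shape),
        voxel_mm=cfg.phantom.grid.voxel_mm,
        age_scale=cfg.phantom.age_scale,
        runtime_s=round(time.time() - t_start, 2),
    )
    report = StudyReport(half_lives, table, doses, voxel_result, segmentations,
                         fits, tacs, manifest, age_years=cfg.age_years)
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def _cumulated_source_maps(cfg, table: TIACTable, masks, segmentations, quant, labels
                           ) -> dict[str, ImageVolume]:
    """Cumulated activity per MBq injected: organs image-weighted inside
    their segmented mask (uniform fallback), remainder uniform over the
    anatomical body, bladder uniform over its region."""
    out: dict[str, ImageVolume] = {}
    grid = quant
    for lab in _organ_labels(cfg):
        mask = segmentations[lab].volume_mask
        arr = np.zeros(grid.shape)
        if cfg.image_weighted_sources:
            w = np.clip(quant.data, 0, None) * mask
            if w.sum() <= 0:
                w = mask.astype(float)
        else:
            w = mask.astype(float)
        arr = w / w.sum() * table[lab]
        out[lab] = grid.with_data(arr, unit="MBq.h")
    if "bladder" in masks and "bladder" in table:
        arr = np.zeros(grid.shape)
        arr[masks["bladder"]] = table["bladder"] / masks["bladder"].sum()
        out["bladder"] = grid.with_data(arr, unit="MBq.h")
    rem_mask = masks["remainder"].copy()
    # remainder concentration over the full anatomical body volume
    body_ml = cfg.phantom.body_volume_ml()
    organ_ml = sum(m.sum() for l, m in masks.items() if l != "remainder") * grid.voxel_volume_ml
    conc = table["remainder"] / max(body_ml - organ_ml, grid.voxel_volume_ml)
    arr = np.zeros(grid.shape)
    arr[rem_mask] = conc * grid.voxel_volume_ml
    out["remainder"] = grid.with_data(arr, unit="MBq.h")
    return out


def _organ_level_doses(cfg, table: TIACTable, masks, segmentations, kern: DoseKernel,
                       labels, nuclide) -> pd.DataFrame:
    organs = _organ_labels(cfg)
    smasks = {lab: segmentations[lab].volume_mask for lab in organs}
    smasks["remainder"] = masks["remainder"]
    if "bladder" in masks:
        smasks["bladder"] = masks["bladder"]
    voxel_ml = labels.voxel_volume_ml
    patient_masses = {lab: segmentations[lab].volume_mask.sum() * voxel_ml for lab in organs}

    sf = derive_sfactors(smasks, patient_masses, kern, labels.spacing)
    # sources outside the axial FOV (e.g. bladder on a short grid) carry no
    # in-grid activity and are excluded from the dose sum
    dose_table = TIACTable(
        {k: v for k, v in table.entries.items() if k in smasks or k == "whole_body"},
        table.injected_MBq,
    )
    adapted = organ_doses(dose_table, sf)  # derived on this patient: already mass-adapted

    # default-mass arm: rescale self terms to the nearest-age reference model
    model = age_model_masses(cfg.age_model)
    default_masses = {}
    for lab in organs:
        if "kidney" in lab:
            default_masses[lab] = model["kidneys"] / 2.0
        elif lab in model:
            default_masses[lab] = model[lab]
    default = organ_doses(dose_table, adapt_masses(sf, default_masses))

    rows = []
    for lab in organs:
        d_ad = float(adapted.doses.set_index("label").loc[lab, "dose_mGy_per_MBq"])
        d_def = float(default.doses.set_index("label").loc[lab, "dose_mGy_per_MBq"])
        row = dict(label=lab, organ_dose_adapted_mGy_per_MBq=d_ad,
                   organ_dose_default_mGy_per_MBq=d_def)
        if lab.startswith("tumor"):
            mass = patient_masses[lab]  # unit density
            row["sphere_dose_mGy_per_MBq"] = sphere_dose(mass, table[lab], nuclide)
        rows.append(row)
    return pd.DataFrame(rows)


_FLOAT_FMT = "%.8g"


def write_report(report: StudyReport, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.half_lives.to_csv(out / "half_lives.csv", index=False, float_format=_FLOAT_FMT)
    report.tiacs.to_frame().to_csv(out / "tiacs.csv", index=False, float_format=_FLOAT_FMT)
    report.doses.to_csv(out / "doses.csv", index=False, float_format=_FLOAT_FMT)
    dvh_rows = []
    for lab, d in report.voxel_result.dvhs.items():
        for e, f in zip(d.dose_edges_mGy, d.fraction_ge):
            dvh_rows.append(dict(label=lab, dose_mGy_per_MBq=e, fraction_ge=f))
    pd.DataFrame(dvh_rows).to_csv(out / "dvh.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=1, sort_keys=True)


def compare_cohorts(reports_a: list[StudyReport], reports_b: list[StudyReport],
                    label_a: str = "children", label_b: str = "adults") -> pd.DataFrame:
    """Per-organ dose ratios between cohorts, cross-fraction summaries, and
    the dose-versus-age Pearson correlation within cohort A."""
    if not reports_a or not reports_b:
        raise ValueError("both cohorts must contain at least one report")

    def organ_frame(reports):
        frames = []
        for i, r in enumerate(reports):
            f = r.voxel_result.per_roi.copy()
            f["study"] = i
            f["age"] = r.age_years
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    fa, fb = organ_frame(reports_a), organ_frame(reports_b)
    rows = []
    for lab in sorted(set(fa["label"]) & set(fb["label"])):
        da = fa.loc[fa.label == lab, "mean_dose_mGy_per_MBq"]
        db = fb.loc[fb.label == lab, "mean_dose_mGy_per_MBq"]
        xa = fa.loc[fa.label == lab, "cross_fraction_pct"]
        xb = fb.loc[fb.label == lab, "cross_fraction_pct"]
        row = dict(
            label=lab,
            dose_ratio=da.mean() / db.mean(),
            cross_fraction_a_pct=xa.mean(),
            cross_fraction_b_pct=xb.mean(),
        )
        ages = fa.loc[fa.label == lab, "age"]
        doses = fa.loc[fa.label == lab, "mean_dose_mGy_per_MBq"]
        ok = ages.notna()
        if ok.sum() >= 3 and doses[ok].std() > 0 and ages[ok].std() > 0:
            r, p = pearsonr(ages[ok], doses[ok])
            row["age_dose_pearson_r"] = r
            row["age_dose_p_value"] = p
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["cohorts"] = (label_a, label_b)
    return out
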