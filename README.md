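# hybridose

Patient-specific internal dosimetry for ⁹⁹ᵐTc somatostatin-receptor imaging
(⁹⁹ᵐTc-HYNIC-TOC), built as a tested, reusable pipeline: hybrid
planar/SPECT estimation of time-integrated activity coefficients (TIACs),
voxel-level absorbed dose by convolution with voxel S-value kernels
(self/cross-organ decomposition and dose-volume histograms), and
organ-level MIRD dosimetry with mass-adapted S-factors. A first-class
synthetic-data module generates digital phantoms and camera acquisitions
with the statistical structure the analysis assumes, so every stage can be
validated end to end.

Intended users: medical-physics researchers studying quantitative SPECT
dosimetry — in particular how pediatric anatomy changes organ doses and the
cross-organ share of the dose — and developers who need a transparent,
fully scriptable alternative to black-box dosimetry tools.

## The method

For each organ region r, planar scans at 2–3 time points give a
time-activity curve whose mono-exponential fit yields the effective
half-life T_eff (1/T_eff = 1/T_phys + 1/T_bio). A single quantitative
SPECT/CT — OSEM (2 it × 10 subsets) with broad-beam attenuation correction,
calibrated with a point source — provides one absolute activity sample
A(t_S), extracted with dual iterative adaptive thresholding whose volume and
activity thresholds are calibrated functions T(SBR) = a + b/SBR of the
signal-to-background ratio. The TIAC is

    ã_r = A(t_S)/A_inj · 2^(t_S/T_eff) · T_eff / ln 2        [Bq·h/Bq]

with a voiding-bladder model for urine and remainder = whole body − organs.
Dose is computed two ways:

* **voxel level** — D = Ã ∗ S_voxel, where S_voxel is an analytic ⁹⁹ᵐTc
  kernel in water (local electron deposition plus a buildup-corrected photon
  point kernel whose energy integral equals the emitted photon energy), with
  per-organ self/cross decomposition and DVHs;
* **organ level** — D_t = Σ_s ã_s S(t←s) with S-factors derived from the
  same phantom and kernel, self terms rescaled to patient organ masses
  (m_ref/m for electrons, (m_ref/m)^(2/3) for photons), and a sphere model
  for tumors.

## Worked example

```python
import hybridose as h

# calibrate the segmentation thresholds once (sphere phantoms)
acq = h.AcquisitionSpec(rng_seed=999)
curves = h.build_calibration_curves([12, 20, 50, 100], [2, 4, 8, 16, 32],
                                    acq, grid_shape=(48, 48, 48))

# a ~12-year-old, 40 kg torso phantom, 500 MBq injected
cfg = h.StudyConfig(
    phantom=h.reference_phantom(age_scale=h.PEDIATRIC_AGE_SCALE,
                                grid_shape=(72, 72, 72)),
    kinetics=h.reference_kinetics(injected_MBq=500.0),
    acquisition=h.AcquisitionSpec(rng_seed=5),
    curves=curves, seed=5, age_model="15",
)
report = h.run_study(cfg)
print(report.tiacs.to_frame()[["label", "tiac_h"]].to_string(index=False))
```

prints (seed 5):

```
       label   tiac_h
 left_kidney 0.183709
right_kidney 0.186179
       liver 0.599069
      spleen 0.438129
     bladder 0.237913
  whole_body 7.507005
   remainder 6.062004
```

The generator's ground truth is 0.185 h per kidney, 0.56 h liver, 0.43 h
spleen: the hybrid chain (simulate → reconstruct → fit → segment → rescale)
recovers the organ TIACs to within ~7% here. `report.doses` adds the three
dose arms per organ (voxel-level mean with self/cross split, organ-level
with adapted and with default masses, in mGy/MBq), and
`report.voxel_result.dvhs` the cumulative DVHs.

The cross-organ question — how much of an organ's dose arrives from outside
it — is answered by the reference studies:

```python
result, mean_cross = h.pediatric_cross_organ_study(grid=96)
print(result.per_roi[["label", "mean_dose_mGy_per_MBq", "cross_fraction_pct"]])
print(f"mean cross-organ fraction: {mean_cross:.1f} %")
```

```
        label  mean_dose_mGy_per_MBq  cross_fraction_pct
  left_kidney               0.042728           17.402521
 right_kidney               0.042010           15.990075
        liver               0.019668           24.576184
       spleen               0.076100            8.120624
mean cross-organ fraction: 16.5 %
```

On the adult phantom with adult TIACs the same quantity is 13.8%: children
receive a visibly larger share of their organ dose from surrounding tissue,
because a similar amount of cumulated activity is packed into roughly half
the body mass at shorter inter-organ distances.

A thin CLI wraps the library: `hybridose simulate|recon|segment|
calibrate-segmentation|dose|run` (see `hybridose --help`).

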