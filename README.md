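# mmtomo

3D Mueller-matrix image reconstruction of tissue optical anisotropy:
differential (logarithmic) decomposition of per-pixel Mueller matrices into
linear and circular birefringence/dichroism maps at selectable phase
planes, statistical-moment texture analysis, and threshold diagnosis of
benign versus malignant tissue cohorts — together with an off-axis
holography simulator and a synthetic tissue-phantom generator that make the
entire chain verifiable without laboratory data.

## The problem

Histopathology of prostate biopsies distinguishes benign adenoma from
carcinoma by visual inspection of stained sections — subjective and
non-quantitative.  Polarimetric imaging offers an objective alternative:
malignant transformation destroys the spatially organized fibrillar
collagen networks, lowering the tissue's linear birefringence and dichroism
and shrinking its domain structure, while optically active molecule
concentrations (circular anisotropy) change little.

A thin section's polarization transfer is a per-pixel 4×4 Mueller matrix
F(a, b).  For a layered medium, F = exp(m), where the first-order
differential generator m carries six anisotropy parameters: linear
birefringence Φ0,90 and Φ45,135, circular birefringence Φ⊗,⊕, and the three
matching dichroism terms Δ0,90, Δ45,135, Δ⊗,⊕ (each accumulated over the
thickness, e.g. Φ0,90 = (2π/λ)·Δn0,90·l).  Reconstruction inverts this: the
principal matrix logarithm of the measured F is split into its
G-antisymmetric part (the six mean parameters) and its G-symmetric part
(depolarization), G = diag(1,−1,−1,−1).  The orientation-invariant
magnitudes ΦL = √(Φ0,90² + Φ45,135²) and ΔL = √(Δ0,90² + Δ45,135²) are
mapped per pixel and characterized by the raw moments

    Z1 = ⟨OA⟩,  Z2 = ⟨OA²⟩,  Z3 = Z2⁻³⟨OA³⟩,  Z4 = Z2⁻⁴⟨OA⁴⟩,

whose higher orders amplify small level differences of weakly anisotropic
media by orders of magnitude.  A scalar threshold on one moment yields
sensitivity, specificity and balanced accuracy Ac = (Se+Sp)/2, graded
Satisfactory (70–80), Good (81–90) or Excellent (91–100).

The measurement side is simulated too: six polarization probes, off-axis
interference of each analyzer projection with a tilted reference wave,
Fourier sideband demodulation back to complex fields, Stokes maps, and
Mueller assembly from half-sum/half-difference probe combinations.

## Worked example

```
$ python examples/phantom_cohort_diagnosis.py
cohort means (adenoma vs carcinoma):
  Z1(phi_l  )      0.5895  vs     0.3299
  Z2(phi_l  )      0.3477  vs     0.1089
  Z3(phi_l  )      4.8804  vs    27.8552
  Z4(phi_l  )      8.2850  vs    84.5919
  Z1(delta_l)      0.1192  vs     0.0927
  ...
leave-one-out threshold diagnosis (carcinoma = positive class):
  Z3(phi_l  )  Se=100.0%  Sp=100.0%  Ac=100.0%  -> Excellent
  Z4(delta_l)  Se=100.0%  Sp=100.0%  Ac=100.0%  -> Excellent
```

The benign cohort's mean linear birefringence map level (Z1 ≈ 0.59 rad)
sits well above the malignant one (≈ 0.33 rad), reflecting the degraded
fibrillar networks; the raw higher-order moments scale like inverse powers
of the level (Z3 ≈ m⁻³), turning a 1.8× level contrast into a 6–10×
marker contrast, so the high-order linear markers classify the phantom
cohorts perfectly.  Other examples: `calibration_check.py` (the air and
quarter-wave calibration matrices), `forward_inverse_roundtrip.py`,
`holography_closure.py` (median per-element closure error ≈ 5·10⁻⁴),
`phase_plane_profile.py` (class separation versus phase plane, peaking
inside 0.3–0.9 rad).

A thin CLI mirrors the pipeline stages:

```
mmtomo phantom --preset adenoma --seed 3 --size 128 --out ph/
mmtomo reconstruct ph/mueller_0p60.tiff --out maps.tiff
mmtomo moments maps.tiff --tissue-class adenoma --out moments.csv
mmtomo report run.yaml
```

## Layout

```
src/mmtomo/
  geometry.py     measurement geometry, optical constants
  core.py         differential model: forward exponential, matrix-log inverse
  _linalg.py      batched 4x4 exp/log via eigendecomposition
  calibration.py  polarimeter calibration matrices (air, quarter-wave)
  holography.py   probes, Jones fields, interferograms, demodulation, Stokes
  maps.py         layered anisotropy observable maps, plane profiles
  stats.py        moments Z1..Z4, threshold diagnosis, grading, stability
  phantom.py      two-class synthetic tissue phantoms (frozen presets)
  pipeline.py     configured end-to-end runs
  io.py           TIFF/NPZ stacks, PNG interferograms, CSV/JSON tables
  cli.py          thin click CLI
docs/methods.md   model, assumptions, presets, numerics, limitations
examples/         one short narrative script per capability
```
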