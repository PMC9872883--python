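# Methods

## Model

A thin anisotropic layer acts on the Stokes vector through the exponential
of a first-order differential generator with six independent entries: the
linear birefringence pair Φ0,90 and Φ45,135, circular birefringence Φ⊗,⊕,
and the three matching dichroism terms Δ0,90, Δ45,135, Δ⊗,⊕.  The layout

```
|    0       Δ0,90    Δ45,135   Δ⊗,⊕   |
|  Δ0,90       0       Φ⊗,⊕   -Φ45,135 |
| Δ45,135   -Φ⊗,⊕       0      Φ0,90   |
|  Δ⊗,⊕    Φ45,135   -Φ0,90      0     |
```

places dichroism in the G-symmetric positions and birefringence in the
G-antisymmetric ones, where G = diag(1, −1, −1, −1).  Generators are stored
*per layer*: each phase term equals (2π/λ)·Δn·l and each amplitude term
(2π/λ)·Δτ·l, with λ the wavelength (default 0.6328 µm) and l the section
thickness (default 40 µm).  Per-unit-length rates are obtained by dividing
by `geometry.thickness`.

### Inverse problem

The default reconstruction takes the principal matrix logarithm of the
f11-normalized Mueller matrix and splits it into its G-antisymmetric part
(the six mean anisotropy parameters) and its G-symmetric part (the
depolarizing component).  Because log∘exp is the identity whenever the
generator's eigenvalue imaginary parts lie in (−π, π), the six mean
parameters are recovered **exactly** — not just to first order — for any
layer generated by this model, including arbitrarily strong G-symmetric
depolarization, as long as the total retardance
sqrt(Φ0,90² + Φ45,135² + Φ⊗,⊕²) stays below π.  Phases are therefore
reported in (−π, π]; thicker stacks that wind past π must be tracked
incrementally layer by layer.

A literal per-element mode (`elementwise`) is retained for comparison with
the published per-element formulas, read as log-ratios 0.5·ln(f_ik/f_ki)
over the element pairing (f24,f42), (f34,f43), (f32,f23), (f12,f21),
(f13,f31), (f14,f41).  This reading is the only one that vanishes at the
identity, but it is structurally degenerate: for a pure retarder the paired
elements have opposite signs (ratio negative → NaN sentinel), and for a
pure diattenuator they are equal (ratio 1 → 0 regardless of the true
diattenuation).  The mode exists to make that failure observable, and the
test suite documents it with a diattenuator counterexample; all quantitative
results use the matrix-logarithm route.

### Derived observables

Generalized linear birefringence and dichroism are the quadrature
magnitudes ΦL = sqrt(Φ0,90² + Φ45,135²), ΔL = sqrt(Δ0,90² + Δ45,135²) —
orientation-invariant and non-negative.  The depolarization degree is the
single-matrix depolarization index expressed in percent,
Λ = (1 − sqrt((Σ f_ik² − f11²)/(3 f11²)))·100, which is 0 for every pure
matrix and 100 for the ideal depolarizer diag(1,0,0,0).

## Holographic measurement chain

The six probe states (0°, 90°, 45°, 135°, right/left circular) are
propagated through the medium; behind an analyzer at Ω = 0°/90° each
projection interferes with a tilted plane reference wave (default carrier
0.25 cycles/pixel per axis).  Demodulation shifts the +1 sideband to DC by
an exact carrier-phase multiply (valid for non-integer carriers), applies a
circular low-pass of radius half the carrier magnitude with a raised-cosine
taper from 0.85·r to r, inverse-transforms, and divides out the reference
amplitude.  The narrow taper favors pass-band fidelity over stop-band
attenuation, which is the right trade-off when the carrier is well
separated; the closure error on 64×64 phantoms is median ≈ 5·10⁻⁴ per
element (outer 5% frame excluded from statistics, as FFT edge effects
concentrate there).

Field synthesis for simulation goes through the per-pixel **Jones** matrix,
obtained in closed form from the same six parameters (the 2×2 generator
½[(Δ0,90−iΦ0,90)σ₃ + (Δ45,135−iΦ45,135)σ₁ − (Δ⊗,⊕−iΦ⊗,⊕)σ₂]).  This is
exact for non-depolarizing media and keeps the fields analytic in the
underlying smooth maps, hence band-limited.  Synthesizing a field from a
Stokes vector alone (`fields_from_stokes`) is also provided but fixes an
arbitrary gauge that introduces square-root kinks where one projection
vanishes; it is not used in the closure chain.  A coherent field pair
cannot carry the unpolarized component at all, so interferometric closure
is only exact for Λ = 0 media; depolarizing maps are validated through the
direct Stokes → half-sum/half-difference assembly, which is exact for any
Mueller map.  How distinct phase planes arise physically from a single thin
section is not modeled; the phase-plane stack is treated as a post-hoc
slicing of the reconstructed relative-phase field (`phase_slice` selects
the nearest plane on the circle).

## Statistical moments and diagnosis

The default moments are the literal raw power statistics
Z1 = mean(OA), Z2 = mean(OA²), Z3 = Z2⁻³·mean(OA³), Z4 = Z2⁻⁴·mean(OA⁴)
over valid pixels.  For a nonnegative map with mean m and modest spread,
Z3 ≈ m⁻³ and Z4 ≈ m⁻⁴: the higher orders amplify level differences of
weakly anisotropic media by orders of magnitude, which is exactly their
diagnostic appeal.  Note the power-mean bound Z3 ≥ (E[OA²])^(−3/2) for any
nonnegative map: raw Z3/Z4 of sub-unity maps are necessarily large.  A
`centered` mode (mean, standard deviation, Pearson skewness and kurtosis)
is available for comparison with classical texture statistics but is never
the default.

Diagnosis is a scalar threshold on one moment of one observable, carcinoma
positive.  The threshold and direction maximize resubstitution balanced
accuracy over midpoints of adjacent pooled values; ties at the threshold
are called carcinoma (deterministic, favors sensitivity; remaining ties are
broken toward the lowest threshold and the ≥ direction).  The default
reporting scheme is leave-one-out: the rule is refit without each sample,
which is then scored out of bag.  Se = a/(a+b)·100, Sp = c/(c+d)·100,
Ac = (Se+Sp)/2 by construction.  The fitted rule is rank-based, so
resubstitution counts are invariant under any strictly monotone transform
of the feature; leave-one-out additionally depends on where the midpoint
threshold falls between training values, which only affine maps preserve.
Balanced accuracy is graded Satisfactory (70–80), Good (81–90), Excellent
(91–100), Unsatisfactory below 70, after rounding to the nearest integer
(which closes the 80–81 and 90–91 gaps).

Cohort stability is assessed by k-fold resampling (default k = 6): the
per-moment sample variance on each training subset must stay below
σ² ≤ 0.025, the level at which a cohort of ~36 sections is considered
statistically reliable.  Under the raw-moment definition this bound is only
meaningful for the primary observable (linear birefringence, whose Z4 is
~9 under the benign preset); for maps with mean ≪ 1 the raw higher orders
are of order 10³–10⁴ and an absolute variance bound of 0.025 cannot be
satisfied by any generator, so the stability check is scoped to Z1..Z4 of
the linear-birefringence map.

## Synthetic tissue phantoms

The generator emulates what the statistical analysis actually consumes:
per-pixel anisotropy fields with class-specific levels and domain scales.

- **Magnitude fields**: log-normal, X = m·exp(cv·G − cv²/2), with G a
  Gaussian-correlated unit field (Gaussian filter of width equal to the
  domain correlation length, periodic boundaries so that simulated
  interferograms are leakage-free).  G is standardized per phantom, which
  also suppresses finite-grid fluctuation of the map mean.
- **Orientation**: a smooth fibril-orientation field θ (random mean
  direction, spread 0.35 rad) splits the linear magnitudes into their
  0/90 and 45/135 components via cos 2θ / sin 2θ; phase and amplitude
  anisotropy share the orientation field, as both arise from the same
  collagen network.  ΦL and ΔL recover the magnitude fields exactly.
- **Depolarization**: an isotropic G-symmetric generator diag(0,−d,−d,−d);
  d is calibrated per phantom by root-finding so the map-mean
  depolarization index hits the class target (46% benign, 45% malignant,
  inside the measured 43–48% band), evaluated on a 32×32 subsample for
  speed.  Unreachable targets raise an error naming the feasible range.
- **Phase planes**: mean levels scale linearly with φ (reference plane
  φ* = 0.6 rad).  The between-sample level dispersion is
  σ(φ) ∝ sqrt((1 + (φ/φ*)⁶)/2): a φ-independent floor plus a steeply
  rising deep-plane term standing in for growing scattering multiplicity.
  Detectability of the class contrast then peaks just below φ*, inside the
  0.3–0.9 rad window.

### Frozen presets

Calibrated once against the published cohort levels and the σ² ≤ 0.025
stability bound, then frozen:

| parameter (at φ* = 0.6) | adenoma | carcinoma |
|---|---|---|
| ΦL mean / pixel cv / cohort jitter | 0.59 / 2% / 0.2% | 0.33 / 3% / 0.2% |
| ΔL mean / pixel cv / cohort jitter | 0.12 / 2% / 1% | 0.093 / 3% / 1% |
| Φ⊗,⊕ mean / jitter | 0.29 / 20% | 0.21 / 20% |
| Δ⊗,⊕ mean / jitter | 0.065 / 20% | 0.072 / 20% |
| correlation length (px) | 4 | 2 |
| depolarization target | 46% | 45% |

The benign class has higher linear anisotropy over larger domains (dense
newly formed fibrillar networks); the malignant class lower levels over
smaller domains (degraded networks); the circular observables overlap
strongly between classes, so they discriminate only moderately.  The small
linear-observable jitters are what the σ² ≤ 0.025 bound forces once the
raw higher-order moments (≈ m⁻³, m⁻⁴) are adopted: a 0.2% relative level
spread already propagates to σ(Z4) ≈ 0.08 on the benign preset.

### What the phantoms do and do not show

They reproduce the *levels*, *domain scales*, *depolarization band* and
*between-class contrast structure* that the analysis assumes — enough to
verify every stage of the computational chain quantitatively.  They do not
simulate radiative transfer, speckle, multiple scattering, instrument
noise, or histological morphology; with the frozen presets the two classes
are cleanly separable, so the reported balanced accuracies on phantom
cohorts sit at the top of the Excellent band rather than at the clinical
values, which include biological overlap the phantoms do not model.
Passing phantom tests validates the pipeline, not clinical performance.

## Problem sizes and numerics

Default study conditions: 26 phantoms per class at 128×128 for cohort
calibration and diagnosis, 36 benign phantoms at 128×128 for the stability
check, 64×64 for interferometric closure, 1000 parameter draws for the
forward–inverse round trip.  Batched 4×4 exponentials/logarithms go through
the eigendecomposition (LAPACK-backed over the pixel axis) with a
scipy.linalg fallback for ill-conditioned pixels (eigenvector condition
number above 1e10 or imaginary residue above 1e-9); pixels whose matrix has
an eigenvalue on the closed negative real axis have no real principal
logarithm and become NaN sentinels, excluded from all downstream statistics
(imputation would bias the higher-order moments).  Maps with more than 50%
sentinels trigger a degraded-quality warning.  All randomness flows through
`numpy.random.default_rng` seeded from the phantom spec; identical
(spec, planes, seed) regenerate phantoms bit-identically.
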