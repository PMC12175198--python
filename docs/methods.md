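# Methods

## Forward model

A thin sample is represented by its complex transmission
`o(r) = exp(iφ(r) − μ(r))` on a square high-resolution (HR) grid. A
capture under LED *m* is

    I_i = γ_i · |F⁻¹[ o(k − k_m) · P(k) · H(k, z) ]|²

with the spectral shift `k_m = (sin θx/λ, sin θy/λ)` computed from the
LED's lateral offset `(dx, dy)` and the array height `h` as
`sin θx = dx / sqrt(dx² + dy² + h²)`.

**Sampling.** The low-resolution (LR) grid has object-plane pixel
`Δx = camera_pixel / magnification` (0.65 μm for the default 10×/6.5 μm
hardware); the HR grid refines it by `hr_upsample` (default 4). Both
grids share the frequency step `dk = 1/(n·Δx)`, so a capture is exactly
an n×n window of the HR spectrum. `k_m` is mapped to the nearest integer
pixel shift of that window; sub-pixel wavevector refinement is out of
scope. Spectra are stored DC-centered with orthonormal FFTs (Parseval
holds to machine precision); a single scalar `1/hr_upsample` on the
cropped field makes a unit-transmission object produce a unit-intensity
frame.

**Defocus kernel.** `H(k, z) = exp(i·(2π/λ)·z·sqrt(1 − (λkx)² − (λky)²))`
is the standard angular-spectrum propagator; kx, ky are physical spatial
frequencies, and the λ-scaling makes the radicand dimensionless. Where
`(λk)² > 1` (evanescent, reachable only on the HR grid used for
two-plane propagation) the kernel decays as
`exp(−(2π/λ)·|z|·sqrt((λk)² − 1))`, which preserves `H(k, 0) ≡ 1` and
`H(k, −z) = conj H(k, z)` on the whole grid and vanishes numerically for
the separations of interest.

**LED ordering.** LEDs are enumerated center-outward by square ring and,
within a ring, by azimuth from the +x axis — a deterministic spiral, so
index 0 is always the on-axis LED and mini-batches follow the standard
low-to-high-frequency order on average.

**LED pitch.** The array pitch is not part of the hardware description we
target beyond "13×13 at 52 mm"; the default of 4 mm is a common
commercial spacing and gives ≈ 0.55 illumination NA at the array corner,
with ~85% pupil-overlap between neighbouring LEDs — comfortably inside
the overlap regime where spectrum stitching converges.

**Noise.** Optional and off by default: Poisson shot noise at a stated
photon budget per unit-intensity pixel, plus additive Gaussian read noise
in counts, both driven by one seeded generator.

## Reconstruction

The reconstructor minimizes the batch-mean per-pixel data misfit — mean
absolute error (default) or mean squared error — with Adam
(β₁ = 0.9, β₂ = 0.999) over shuffled mini-batches of LED indices, jointly
updating four parameter groups:

| group     | parameterization           | default lr |
|-----------|----------------------------|-----------|
| spectrum  | complex HR spectrum        | 1e−2      |
| pupil     | Noll Zernike coefficients (15) | 1e−3  |
| z         | scalar, μm                 | 1e−1      |
| γ         | log γ (positivity)         | 1e−3 (Adam mode) |

Defaults: 200 epochs, batch 13, seed 0; fixed epoch count, no early
stopping, so runs are exactly reproducible. Any group can be frozen;
frozen groups are returned bit-identical.

Gradients are analytic Wirtinger derivatives: intensity → field → filtered
window → scattered HR-spectrum adjoint, with `∂H/∂z` analytic and the
Zernike chain rule for the pupil phase. For a complex parameter the
optimizer receives `2·∂ε/∂p̄`, the exact gradient with respect to its real
and imaginary parts; every gradient is verified against central finite
differences in the test suite. Complex Adam uses `|g|²` for the second
moment (phase-rotation invariant).

**Initialization.** Amplitude = square root of the central-LED frame,
Fourier-upsampled with zero phase; z = 0; Zernike coefficients
(1, 0, …, 0) (a pure piston, i.e. a gauge); γ ≡ 1.

**Intensity factors.** Dark-field frames are 10²–10⁴× dimmer than
bright-field frames, and a dark frame's γ trades off against the spectrum
annulus that only this frame observes; gradient descent on log γ follows
that near-degenerate valley extremely slowly (empirically: the loss
reaches 1e−6 while outer-ring γ is still tens of percent off). By default
γ is therefore refreshed once per epoch with the classic closed-form LED
intensity correction, multiplying each γ_i by the ratio of measured to
predicted mean frame brightness; this recovers all 169 factors to < 2%
under the default conditions. Pure-Adam updates remain available
(`gamma_update="adam"`).

**Gauges.** A global phase piston, a global intensity scale (traded
between spectrum and γ), and — within the pupil support — the split of
defocus between z and the pupil's Zernike defocus/spherical modes are not
determined by the data. Outputs fix the first (mean phase removed) and
comparisons fix the second (least-squares scale, γ_central = 1). The
z↔pupil split is left free: with a free pupil the jointly recovered z
shows a systematic ≈ 1.8 μm offset at |z| = 30 μm (the pupil absorbs the
residual as aberration); freezing the pupil removes it (< 0.02 μm). Both
stay inside the 2 μm accuracy targeted for digital refocusing.

**Loss choice.** The absolute-error objective is the default; the
squared-error objective is retained because the misfit is naturally a
squared Euclidean distance and because, on scenes that violate the
single-plane model (see below), it averages inconsistent out-of-plane
interference rather than committing to it.

## Digital refocusing and occluder suppression

`refocus` offers two modes: `joint_opt` (full reconstruction with z free)
and `sweep` (short, 20-epoch reconstructions with z frozen on a candidate
grid; score = final misfit; ties break toward the smallest |z|; an
endpoint winner sets a too-narrow-range flag).

`suppress_occluder` reconstructs with z pinned to a chosen focal plane.
Content on other planes shifts laterally by `separation · sin θ` between
LEDs — tens of μm for a 150 μm separation, far beyond the field — so it
is mutually inconsistent across captures and is averaged down, while the
selected plane reinforces.

## Synthetic data

* **tissue** — smoothed random stroma with sharp nucleus-like disks,
  absorption and phase correlated (μ, φ up to 1.5, keeping |o| ≥ 0.22 and
  phase far from wrapping). Both fields pass a raised-cosine spectral
  low-pass at 1.5 μm⁻¹: just inside the widest synthetic aperture of the
  default geometry (1.62 μm⁻¹ at 523 nm), so the phantom is recoverable in
  principle while still giving the dark-field captures realistic signal.
* **two_point** — two single-pixel clear points on a strongly absorbing
  background; deliberately *not* band-limited (the point is to probe the
  band limit).
* **star / bars / uniform** — Siemens star, bar groups, clear glass.
* **two-plane scenes** — tissue at z = 0 and marker-pen strokes
  (μ = 3 ≈ 95% absorption, a few μm wide) on a plane `separation` above
  it; the simulator propagates the tilted field from tissue to marker
  with the HR angular-spectrum kernel, applies the marker transmission,
  and images with the residual defocus. With a transparent marker it
  reduces frame-exactly to the single-plane simulator.

**What the phantoms do not emulate:** real H&E color texture, slide
thickness variation across the field (defocus is a single global z),
LED-position errors, partial coherence, or sensor nonlinearity. Passing
tests therefore demonstrate correctness and identifiability of the
algorithm under its own physics, not robustness to every real-microscope
deviation. The two-plane scenes are also a scaled-down emulation: a real
marker stroke (~1 mm) dwarfs a 21 μm field, so the synthetic strokes are
field-scale and suppression is dominated by edge/parallax effects, which
is the mechanism of interest. The measured occluded-region error ratio
varies with the scene realization (≈ 0.26–0.63 across seeds at 150 μm).

## Metrics

* `amplitude_rmse` — RMS amplitude error after a least-squares global
  scale fit.
* `phase_correlation` — Pearson correlation of phase maps (piston drops
  out); two constant maps correlate perfectly by convention, one constant
  map against a varying one raises.
* `resolution_probe` — operational two-point criterion: resolved when the
  profile between the expected peak positions dips ≥ 20% below the lower
  peak. The validation separations are 2.6 μm (above the 0.87 μm Abbe
  limit of the 0.3-NA objective and an exact multiple of the 0.65 μm LR
  pixel so the LR profile is sampled on-pixel), 0.65 μm (between the
  objective and synthetic-aperture limits), and 0.26 μm (below the
  0.31 μm synthetic limit).

## Validation problem sizes

All end-to-end experiments use 32×32 captures upsampled ×4 (128×128
object grid) with the full 169-LED sequence: 200 epochs for recovery,
resolution and suppression runs, 80 for the defocus-recovery series.
These sizes keep a complete validation under a couple of minutes on one
CPU core while leaving every qualitative regime (bright/dark field,
defocus range, sub-Abbe separations) represented.

## Known limitations

* Nearest-pixel spectral shifts bound the geometric fidelity at dk/2;
  fine LED-position calibration is out of scope.
* Single field of view; no multi-field whole-slide stitching.
* No phase unwrapping (phantom phases stay within one period by design).
* The three color channels are reconstructed independently; chromatic
  coupling is not modeled.
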