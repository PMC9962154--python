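# Methods

This note documents the models behind `veinscan`, the parameters that
matter, the numerical choices, and what the synthetic phantom does and does
not establish.

## Optical phantom

The phantom is a per-pixel optical model of a trans-illuminated finger, not
a radiative-transfer simulation.  For each lit diode `j` of wavelength `λ`
the irradiance at pixel `(r, c)` is

```
E_j(r, c, t) = P_j · G_j(r, c) · exp(−μ_t(λ)·T_eff(r,c) − μ_b(λ)·V(r,c)·(1 + a·w(t)))
```

* `P_j` — relative diode power.  The three wavelength rows carry the
  device's parts as relative weights (940 nm: 140/240, 875 nm: 210/240,
  730 nm: 1.0), scaled by `source_scale = 0.8` so the brightest finger
  pixels stay near but below the 8-bit range (no in-finger saturation with
  a 30 ADU stray-light pedestal on top).
* `G_j` — an isotropic Gaussian falloff (σ ≈ 70 px at default geometry)
  standing in for diffuse transmission through tissue.  No scattering PSF
  beyond this kernel; the irradiance of co-lit sources superposes linearly.
* `T_eff` — bulk-tissue path length: an elliptical chord profile with
  mid-line maximum `tissue_depth_max = 2.0` (arbitrary length units),
  multiplied by `nail_factor = 0.35` inside the nail/lunula ellipse — the
  bright nail regions visible in real trans-illuminated fingers.
* `V` — vein blood path length.  The vein network is grown by branching
  random walks from a single root (so it is connected), stamped as disks of
  slowly varying radius (widths 2–8 px) with `V = radius ·
  vein_depth_scale` (0.8), lightly smoothed.  Outside the silhouette the
  frame is dark (the housing aperture blocks direct light).
* `μ_t, μ_b` — absorption coefficients per wavelength.  Only the
  wavelengths are instrument facts; the coefficients are free parameters
  chosen so veins are visible at all three wavelengths with a strict,
  configurable contrast ordering (defaults `μ_b` = 0.7 / 1.0 / 1.3 at
  730 / 875 / 940 nm; tests assert only orderings, never absolute values).
* `w(t)` — cardiac waveform: fundamental sinusoid plus a second harmonic at
  0.3 relative weight (the asymmetric upstroke of a real
  photoplethysmogram), normalized to zero mean and **unit peak-to-peak**, so
  a pixel with unit blood optical depth modulated at amplitude `a` swings by
  ≈ `a` peak-to-peak.  Physiological amplitudes are a few percent; the
  parameter is capped at 0.2.

The front-lit (external 830 nm LED) image is pure surface reflectance:
falloff × multiplicative texture inside the silhouette.  Veins are
sub-surface and carry no contrast in reflection — the generated texture is
statistically independent of the vein map (|r| < 0.1 by test).

## Illumination protocol and camera

Per pattern cycle: register update `t_u` (17 ms, hardware-determined in the
real device and chosen here so one cycle is 30 ms), delay `t_delay` (3 ms),
then the selected NIR LEDs switch on, the 7-segment indicator displays the
pattern for `t_on` = 10 ms, then indicator off, LEDs off.  Thirteen
patterns per sweep (P1–P12 single-diode, P13 external-light with indicator
sentinel `000011110000`); 13 patterns / 0.39 s ≈ 33.3 extracted frames/s.

`seg_lag` (default 1.5 ms) models the controller/display transaction
latency: the LEDs switch on one lag before the indicator and off one lag
after it, so the LED window is `t_on + 2·seg_lag` = 13 ms, at the expense
of the nominal off period `t_u + t_delay`.  This default is load-bearing:
with a 5 ms exposure and a 7.69 ms frame period, a sensor row is guaranteed
one fully illuminated exposure per cycle only if the LED window reaches
`exposure + frame period` ≈ 12.7 ms.  Below that bound the per-pixel
maximum cannot reconstruct fully lit images and the extracted series
acquires a deterministic brightness beat (at the 3.33 Hz recurrence of the
cycle/frame-period phase, σ ≈ 7% of the ROI mean) that buries the
few-percent pulse — the device's clean extracted images imply its LED
window satisfied the bound, even though only the indicator time is
published.

The camera is an ideal integrate-and-dump rolling shutter: row `r` of frame
`k` integrates irradiance over `[k/f + r·ρ, k/f + r·ρ + exposure]` with
`ρ = frame period / rows`; the integral is evaluated piecewise between
illumination events (exact for the piecewise-constant protocol states; the
slow cardiac modulation is sampled at each piece's midpoint, an error of
order `(f_cardiac · 10 ms)²`).  Gain maps an irradiance of 1.0 sustained
over a full exposure to 255 ADU; values are floored to integer ADU (with a
1e-9 epsilon against exact-integer boundary flips) and clipped.  Optional
Gaussian read noise (σ in ADU) is off by default.  Frame timestamps are
`k / frame_rate` — free-run, never synchronized to the illuminator.

Indicator sites are modeled as 3×3 saturating blobs (4 displays × 3
segments; diode `j` → display `j mod 4`, segment `j div 4`); glyph shapes
are cosmetic in the real device since only the calibrated detector pixels
are ever read.

## Extraction

Per frame: read the 12 detector pixels, subtract a per-site dark baseline
(the minimum over the stream — the software analogue of the one-off device
calibration; it makes the 20 ADU threshold immune to a constant stray-light
pedestal), threshold at 20 ADU (≥ counts as lit), all-zero ⇒ dark frame.

Dark frames delimit illumination windows.  Within a window the consensus
code is the one with the most set bits (rolling-shutter transition frames
can only lose bits), ties broken by frequency then first occurrence; frames
matching the consensus are combined by per-pixel maximum, the others
rejected.  The background `B` is the pixel-wise minimum over the most
recent contiguous dark run — it tracks slowly varying stray light like a
single reference frame, while rejecting the LED slivers that can leak into
delimiter frames at a window's edge — and is subtracted with clipping at 0.
A trailing window with no closing delimiter is incomplete (its maximum
under-represents the illumination) and is dropped.  Each kept window emits
one image, the timestamp of its first contributing frame, and its code.

Consequences that are tested rather than assumed: one entry per cycle
(≈ 33/s at paper timing), 100% code agreement with simulator ground truth
on noise-free runs, invariance of every extracted finger pixel to a
constant ≤ 30 ADU stray offset within 1 ADU, and monotonicity of the
detection count in the threshold.

## Pulse recovery

One sample per extracted image: the arithmetic ROI mean (the default ROI is
a central rectangle over the densest part of the vein network; its
coordinates are a required input in general since the real measurement
patch is arbitrary).  Each diode's sub-series is normalized to mean 1 —
scale-invariant by construction, which is what permits combining diodes of
different power and wavelength — then merged time-ordered into one
irregularly sampled signal at ≈ 33 samples/s.

Rate estimation: Lomb–Scargle periodogram over 0.6–3.5 Hz (36–210 bpm;
frequencies with fewer than 3 cycles in the observation span are excluded,
and a span under 3 cycles at the band top is an error), followed by
least-squares sinusoid fits on a fine local grid; the amplitude is the
fitted peak-to-peak swing relative to the unit mean.  Per-diode linear
detrending is available but off by default.

Detection ("liveness"): a pulse is reported only if the fitted peak-to-peak
amplitude is ≥ 5·10⁻⁴ of the mean and the periodogram peak exceeds 5× the
band median power.  The floor was placed experimentally against the
instrument's own noise — the quantization jitter of an ROI mean over a few
thousand pixels is ~1e-4 relative, while a physiological pulse at the 1%
modulation bound moves the brightness-weighted ROI mean by ~1e-3 — the
same way the device's 20 ADU detector threshold was chosen.

## What the phantom does and does not establish

Green end-to-end tests establish that the protocol, the demultiplexer and
the pulse chain are mutually consistent: codes are recovered exactly, yield
matches the timing arithmetic, configured heart rates (50–150 bpm) come
back within 5%, and a non-pulsating phantom produces no detection.  They do
not establish performance on real fingers: the phantom has no motion, no
specular skin reflections, no sensor fixed-pattern or shot noise beyond the
optional Gaussian term, a separable-Gaussian light transport instead of
real diffusion, and vein geometry with convenient statistics.  Absolute
optical coefficients are illustrative, not physiological, so image
*contrast levels* carry no claim — only orderings and pipeline behaviour
do.

## Numerical details and edge cases

* Quantization: floor after gain, clip to [0, 255]; superposition of
  captures therefore holds within 1 ADU.
* Raw frames are named by capture second with 3 decimals (2 would collide
  at 130 FPS); processed files use the release scheme `D<nn>_<t>.png` /
  `DEXT_<t>.png` with 2 decimals, plus a full-precision `manifest.csv` so a
  directory round-trip reproduces the buffers exactly.  Timestamps of raw
  directories without a sidecar are parsed from filenames and sorted
  numerically.
* A lone multi-bit code delimited by dark frames on both sides is emitted
  as-is (written `P<code>_<t>.png`): with no clean frame in the window it
  cannot be distinguished from a legitimate multi-diode pattern.
* Degenerate inputs raise: empty videos, streams with no dark delimiter or
  no pattern frames, zero-mean diode subsets, too-short pulse signals,
  out-of-bounds ROIs and detector sites, 12-bit code violations.
* Determinism: the phantom is a pure function of its seed; noise-free runs
  are bit-reproducible end to end.
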