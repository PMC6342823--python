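# Methods

`miroct` is a virtual bench for a mid-infrared spectral-domain OCT system
whose detection chain runs through nonlinear frequency upconversion.  It has
two simulation engines sharing one set of phantoms and metrics: a spectral
forward model + reconstruction chain (the interferometric half), and a
time-resolved voxel Monte Carlo (the radiometric half).  This note records
the models, their assumptions, the defaults, and what the synthetic tests do
and do not demonstrate.

## Conventions and units

Lengths in µm, wavelengths in nm, time in fs/ps, absorption and scattering
coefficients in mm⁻¹.  Every depth axis is **one-way optical path difference
(OPD) in air**: a reflector behind optical thickness Σ nᵢdᵢ appears at that
OPD, and the fringe phase of a reflector at OPD z is 2kz.  Wavenumbers
k = 2π/λ are on the mid-IR scale in rad/µm.

## Upconversion map

Sum-frequency generation with a pump at λ_P converts a mid-IR wavelength by
energy conservation, 1/λ_P + 1/λ_IR = 1/λ_UP.  With the 1064 nm pump the
3576–4625 nm band lands on 820–865 nm, i.e. a >1 µm mid-IR band is squeezed
into 45 nm of near-IR — the reason a silicon spectrometer can read it.
Spectral remapping applies the exact Jacobian |dλ_UP/dλ_IR| = (λ_UP/λ_IR)²
so photon count is conserved up to the scalar quantum efficiency (default
1%, flat across the band; a wavelength-dependent efficiency table can be
passed per call, since no published curve is available).  Phase matching is
reduced to the collinear first-order scalar mismatch
Δk = 2π(n_UP/λ_UP − n_P/λ_P − n_IR/λ_IR − 1/Λ), Λ = 23 µm by default;
angular (noncollinear) phase matching and the radially varying output mode
are not modeled geometrically — their net effect appears only as the
spectrometer's finite spectral resolution.  Refractive indices are
caller-supplied; no Sellmeier tables are bundled.

## Spectral forward model

The sample frame follows

    I(k) = S(k) [ ρ_ref + Σ rⱼ² + Σ 2√ρ_ref · rⱼ · cos(2 k zⱼ + φⱼ(k)) ]

with S(k) the source envelope (flat, Gaussian or tabulated; normalized;
dense grid of 8× the pixel count), ρ_ref = 0.5 for an ideal splitter
(configurable), and φⱼ(k) the accumulated quadratic dispersion phase
½·GDD·(ω−ω₀)² plus optional higher-order polynomial and a global
interferometer mismatch.  Cross terms between sample reflectors are
neglected (weak-reflector regime).

Finite spectral resolution is a Gaussian kernel of FWHM δλ (default 2.7 nm
on the mid-IR scale) applied by convolution in uniform k before pixel
sampling.  Its Fourier pair is the amplitude roll-off
A(z) = exp(−z²δk²/(4 ln 2)) with δk = 2πδλ/λ₀², so the 6 dB *power* drop
sits at z₆ = ln 2·λ₀²/(πδλ); with λ₀ the geometric mean of the band edges
(4066.8 nm) this gives 1.35 mm ↔ 2.7 nm, the pair the metrics module
inverts.  The arithmetic-vs-geometric choice of λ₀ moves the result by
under 2%.  Pixel-integration (sinc) roll-off is intentionally off: the real
instrument's roll-off is dominated by the upconverted beam's spatial
profile, which we do not model geometrically.

The spectrometer samples 4096 pixels over 796–879 nm (10 bit, 45 kHz).  The
pixel map is linear in near-IR wavelength with optional quadratic/cubic
distortion; note that even the undistorted map is *nonlinear in mid-IR k*
because of the upconversion relation — this nonlinearity is exactly what the
two-interferogram calibration must recover.  Detector gain is anchored so
the reference maximum reaches 80% of full well at the nominal integration
time (avoids synthetic saturation while exercising the bit depth); counts
scale linearly with integration time before quantization (round-half-even,
clipped).  Noise, when enabled, is Poisson shot noise plus Gaussian dark
counts; relative intensity noise is excluded for lack of data.  Because the
fringe term adds up to 2√ρ·r on top of the reference level, mirrors used
for calibration and characterization default to r = 0.05 — stronger mirrors
would clip at full well and the saturated pixels would be masked out.

## Reconstruction chain

Fixed order: (1) fringe extraction (S−D)/(R−D) − 1 with masking of dead and
saturated pixels; (2) two-interferogram calibration; (3) cubic-spline
resampling onto a uniform k grid of n_pixels/2 points spanning the occupied
support; (4) multiplication by exp(−i·ψ(k)) for dispersion compensation;
(5) Hanning window across the resampled support; (6) zero-padding (default
4×) and FFT; (7) magnitude, with dB displayed as 20·log₁₀(mag/median).

Calibration uses two noiseless single-mirror interferograms at OPDs z_a,
z_b.  The analytic signal of each fringe comes from one-sided band-pass
filtering around the dominant fringe carrier (this rejects the DC /
autocorrelation terms whose leakage otherwise corrupts the phase); phase
tears beyond π relative to the local trend raise a calibration error rather
than silently unwrapping.  Then k(p) = (φ_a−φ_b)/(2(z_a−z_b)) up to a
constant quantized in π/|z_a−z_b|, which is anchored by snapping to the
nominal spectrometer map; ψ(p) = φ_a − 2k(p)z_a is the interferometer
mismatch phase, stored mean-removed (its constant is unphysical) and
smoothed by a degree-8 polynomial fit in k (physical dispersion is smooth;
the raw estimate carries bit-depth ripple).  Edge trimming of 3% plus a
5%-of-maximum support threshold excludes the band-pass transients.

The calibration OPD pair defaults to 300/900 µm.  Placing the pair deep in
the axial range is counterproductive on this instrument: its own 2.7 nm
resolution suppresses fringes at millimetre OPDs by orders of magnitude, so
the calibration mirrors must sit well inside the 1.35 mm roll-off while
keeping their two carriers clearly separated.

Achievable figures on the synthetic bench: recovered k(p) matches the true
map to ~5×10⁻⁵ (limited by band-pass edge effects, not bit depth), injected
quadratic phases are recovered to better than 0.01 rad RMS, and a mirror
reconstructed without window has FWHM 3.791/Δk of the occupied span
(≈10.1 µm here; slightly above the ideal-band 9.5 µm because the support
trims the smoothed band edges).  With the Hanning window the width grows by
the standard 1.63× (≈16.5 µm) and the first sidelobe drops ≥18 dB.  The
instrument's measured 8.6 µm resolution is *not* a target: it belongs to the
real, untabulated source envelope.

## Monte Carlo transport

Photon packets move through a uniform voxel grid of (µa, µs, g, n) with
exact ray–voxel boundary stepping (Siddon-style), so arrival times are exact
for ballistic paths — important because the detection surface is time-gated.
Free paths are sampled per dimensionless optical depth −ln U and consumed
across voxels; interactions deposit w·µa/µt and scatter by
Henyey–Greenstein sampling of cos θ with uniform azimuth.  At any voxel face
where the index changes (including all domain faces, with air outside),
unpolarized Fresnel coefficients apply: deterministic weight splitting for
packets above 10⁻³ weight (reflected branch pushed on a per-photon stack of
depth 64), stochastic branch choice below; total internal reflection
reflects.  Optical time advances by n·ds/c; packets exceeding the time cap
terminate; Russian roulette (survival 1/10) handles weights below 10⁻⁴.
Every run returns a weight ledger — absorbed, exited top, exited elsewhere,
time-expired, roulette net — that sums to the launched weight to floating
precision, which the property tests verify on random domains.

The source is a Gaussian footprint of constant 1/e² intensity radius (5 µm
for the 1.3 µm configuration, 15 µm for 4 µm) aimed along +z; beam
divergence is reintroduced afterwards by the overlap correction.  Detection
gates top-face exits into bins of dt = 24 fs over T = 14.4 ps (600 gates),
with depth dz = c·dt/2 = 3.6 µm in air, and accepts exit angles (in air,
after refraction at the top surface — the instrument collects in air) with
sin θ ≤ NA = 0.1.  Flux is normalized per launched photon; this affects only
the absolute scale.  B-scans step the source across the full X extent
(floor(extent/step) lines, 700 for the default ceramic domain at 10 µm) with
per-line random streams keyed by (global seed, line index), so they are
reproducible and trivially parallel.

The confocal factor is the closed form

    C(z) = 4w₀⁴π²(4(z−z_F)²λ² + π²w₀⁴) / (4(z−z_F)²λ² + 2π²w₀⁴)²

— the overlap of the focal mode with the beam reflected at depth z, which
after the double pass looks like the free beam at 2(z−z_F) from focus.  It
equals 1 in focus and decays as π²w₀⁴/((z−z_F)²λ²); the tests verify it
against direct quadrature of the defining overlap integral.  Roll-off
correction multiplies the A-scan by the (squared-amplitude) roll-off curve
of the spectral bench, making MC and interferometric A-scans comparable on
the same dB convention.

## Phantoms

*Ceramic stack*: 375 µm zirconia (n 2.138) / 475 µm alumina (n 1.675) with
60 µm deep valleys milled into the alumina's top face / 300 µm alumina
backing.  The voxelization (default 1400×9×230 at 5 µm = 7000×45×1150 µm³,
uniform in Y) lays the 36 valleys of widths 5..180 µm (step 5) left to right
with uniform gaps; the physically milled part spans widths up to 300 µm,
which the spec generator exposes as an option.  Because the C2 and C3 plates
are stacked rather than bonded, a one-voxel (5 µm) air film separates them
(carved from C3's allocation so the stack depth stays 1150 µm); without it
the index-matched alumina/alumina boundary would be invisible to a
geometric-optics transport, whereas the real instrument sees a clear echo
there.  The reflector-stack version places interfaces at cumulative optical
depths with normal-incidence Fresnel amplitudes and drops index-matched
interfaces.

*Silicon wafer*: two interfaces 255 µm apart (times the caller-supplied
group index — not part of the sample description here; ≈3.6 is a standard
literature value), the back one carrying double-pass GDD = 2·d·GVD with
GVD 1576 fs²/mm at 1.3 µm and 385 fs²/mm at 4 µm.

*Alumina tape on acetate foil*: strongly scattering tape (n≈1.68) of
configurable thickness over a 62 µm foil (n 1.48), at 2 µm voxels.

**Placeholder optical properties.**  Scattering/absorption coefficients for
zirconia, alumina, the tape and the foil are not published with the
geometry.  The shipped values (e.g. alumina µs 20 mm⁻¹ at the 1.3 µm tag vs
2 mm⁻¹ at 4 µm, with more forward-peaked scattering at 1.3 µm) are
placeholders chosen once to realize the qualitative regime the samples are
known to be in — strong Mie-type scattering at 1.3 µm, weak Rayleigh-like
scattering at 4 µm.  Tests built on them check *ordering and conservation*,
never absolute levels; quantitative use requires measured coefficients via
`MaterialProperties`.

## Metrics

Axial resolution fits a Gaussian to the zero-padded A-scan peak over ±3
nominal widths, restricted to samples above a quarter of the peak so
sidelobes of sinc-like responses do not bias the width, with no-peak /
multi-peak / bad-fit conditions raising errors instead of numbers; a
model-free half-max width (`peak_fwhm`) is also provided.  The roll-off
curve takes the peak sensitivity (dB relative to the shallowest probe,
100 µm by default to stay clear of the DC term) at ≥5 probe OPDs and
interpolates the −6.0 dB crossing linearly in dB; if never bracketed the
deepest probe is flagged as a lower bound.  Its inverse,
δλ = ln 2·λ₀²/(π·z₆), reproduces the 1.35 mm ↔ 2.7 nm pair; the −6.0 dB
interpolation versus the factor-4 (−6.02 dB) closed form, and the
shallow-probe normalization, each bias the pair by a few µm — far below the
curve's probe spacing.  Thickness from OPD is d = OPD/n with uncertainty
2·(sampling)/n; sampling resolutions are band/pixels (0.46 nm for 1049 nm
over 2286 illuminated pixels) and speed×integration (9 µm at 3 mm/s, 3 ms).

## What the synthetic tests show — and what they do not

The generators exercise the full pipelines under the instrument's stated
conditions (band, resolution, pixel count, bit depth, time gating, NA,
geometry), so passing tests demonstrate internal consistency, calibration
round trips, conservation laws, and the closed-form pairs above.  They do
not demonstrate: the measured 8.6 µm axial resolution or 60 dB sensitivity
(real envelope and hardware), quantitative penetration depths in the
ceramics (unpublished coefficients), wave-optics effects (speckle,
interference inside the MC — geometric optics only), polarization, or
GPU-scale photon counts.

## Numerical choices

Dense source grids: 32768 points, 5% spectral margin.  Resolution
convolution: Gaussian, truncated at 6σ, zero boundary.  Resampling: cubic
spline (linear available for tests).  Zero padding: 4×.  Quantization:
round-half-even.  MC: splitting threshold 10⁻³, roulette threshold 10⁻⁴
with survival 1/10, per-photon branch stack 64 deep, record capacity grown
geometrically on overflow.  Degenerate inputs fail loudly: equal calibration
OPDs, dead reference frames, non-monotone recovered k(p), single-line
B-scans, steps larger than the domain.

Problem sizes in the tests were chosen to probe each property at the
smallest scale that decides it: 10³–10⁴ photons for conservation and timing
oracles, 2×10⁵ samples for phase-function moments, and 10⁶ photons per
wavelength for the deep-interface contrast ordering (about a minute per
wavelength on one core with the JIT-compiled kernel).
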