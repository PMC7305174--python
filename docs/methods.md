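# Methods

## Physical model and its assumptions

The simulator works entirely at baseband. Every measurable signal in
dual-comb photoacoustic spectroscopy lives at the multi-heterodyne beat
frequencies $f_n = n\,|\Delta f_\mathrm{rep}|$, so optical-rate fields are
never sampled; per-tooth optical powers stand in for the fields, and the
beat-note intensity amplitude of pair $n$ is $2\sqrt{P_{1,n}P_{2,n}}$.
One simulated record is exactly one interferogram period
$1/|\Delta f_\mathrm{rep}|$, of length
$N = \mathrm{round}(f_s/|\Delta f_\mathrm{rep}|)$ samples, which places
every beat note on an exact FFT bin; synthesis is therefore a single
inverse real FFT and is numerically exact (Parseval holds to $10^{-9}$
relative, and this is tested).

The mapping offset $\nu_0$ (the optical frequency of the zero-frequency
beat) depends on carrier-envelope offsets that the model does not track;
it is taken as a configuration parameter and, by default, solved from one
anchor point of the linear mapping: 7.5 MHz acoustic ↔ 171.2 THz optical,
the transducer peak. Tooth $n$ is reported at its mapped frequency
$\nu_0 + n\,(f_{\mathrm{rep},1}+f_{\mathrm{rep},2})/2$, which keeps the
mapping exactly bijective; comb-1 and comb-2 teeth differ from it by at
most $n\,\Delta f_\mathrm{rep}/2 \approx 3$ MHz on 170 THz (relative
$2\times10^{-8}$), which is ignored.

Photoacoustic generation is Beer's law times a scalar conversion factor:
$p_n = \beta\,[1-e^{-\mu_A(\nu_n)L}]\,I_{0,n}$. Thermal diffusion,
Grüneisen physics, acoustic focusing and impedance mismatch are all folded
into $\beta$, which is assumed independent of acoustic frequency.
Propagation to the transducer is a pure delay $t_\mathrm{acoustic}$
(default 14 µs of water path), i.e. a linear spectral phase; diffraction
is out of scope. Because the recovery chain uses magnitude spectra, the
delay only matters for apodization (the window must sit on the
centerburst), not for the spectral amplitudes themselves.

The transducer is an analytic band-pass magnitude normalized to 1 at its
peak — Gaussian by default, peak 7.5 MHz, FWHM 7.5 MHz ("bandwidth" is
interpreted as FWHM; a raised-cosine shape and tabulated calibration
curves are also accepted). The electronics apply 80 dB of gain and a
15 MHz low-pass (4th-order Butterworth magnitude; the order is a realism
choice, configurable). Detector noise is additive, white and Gaussian,
injected at the transducer output before gain — consistent with
detector-noise-limited operation, whose signatures (SNR ∝ √τ and
SNR ∝ optical power) the simulator reproduces and tests. The optical
reference channel is treated as noiseless (high-SNR photodetection).

Residual comb phase noise is modeled as a single global phase per shot,
drawn from $N(0, \sigma^2)$ and shared by both channels — a rigid
interferogram phase, not per-tooth decoherence. Phase correction
estimates each shot's phase from the analytic signal of the reference
channel at its centerburst peak and counter-rotates both channels before
co-adding, as real-time dual-comb averaging systems do. Uncorrected
averaging attenuates the signal by the Gaussian phasor factor
$e^{-\sigma^2/2}$; this closed form is the oracle for the corresponding
test.

## Recovery chain

Coherent average → circular shift by
$\mathrm{round}(t_\mathrm{acoustic} f_s)$ samples → apodization with a
window (default rectangular, 4.8 µs) centered on the centerburst, zeros
outside (zero padding preserves the record length and hence the bin
spacing) → one-sided magnitude spectrum calibrated so an on-grid unit
cosine reads 1.0 at its bin → relabeling of acoustic bins to optical
frequencies → division by the excitation magnitude spectrum and the known
instrument response.

Two deliberate choices here:

- **Rectangular default window.** The per-element SNR gain of smoothing
  160 MHz-spaced samples to 500 GHz elements, $\sqrt{3125}\approx 56$,
  assumes boxcar averaging of independent bins; a Hann option exists.
  The rectangular window's transform has FWHM $1.2067/w$ (the $|sinc|$
  main lobe), ≈252 kHz acoustic or ≈600 GHz optical for $w=4.8$ µs; the
  nominal resolution quoted for the chain is $1/w$ mapped to optical,
  ≈500 GHz.
- **Instrument response includes the low-pass.** Normalization divides by
  the transducer magnitude *and* the detection-chain low-pass magnitude.
  The filter is a known part of the electronics; leaving it in would tilt
  the recovered spectrum by ~3% across the band and a flat absorber would
  not normalize flat. With it, a noiseless flat-absorber scene normalizes
  to the absorbed fraction with relative spread $<10^{-14}$.
- **Masking.** Bins where the excitation magnitude or the instrument
  response falls below 5% of its peak are reported as missing (NaN +
  mask) rather than amplified; band edges otherwise blow up as $1/I_0$.
- **Magnitude, not complex, spectra** throughout: the method compares
  magnitude responses to absorbance, and magnitudes are immune to the
  residual sub-sample delay left by integer-sample shift removal.

## Samples

Three analytic samples emulate common targets in the 158–188 THz C–H
first-overtone window. Only *relative* amplitudes are meaningful; no
absolute $\mu_A$ or $\beta$ values are claimed.

| sample | peaks (THz) | FWHM (THz) | peak $\mu_A L$ | thickness |
|---|---|---|---|---|
| `vacnt_like` | flat | — | 5 (absorbed fraction 0.993) | 25 µm |
| `pdms_like` | 171.6, 176.0, 177.4 | 1.5, 1.0, 1.0 | 0.010 | 240 µm |
| `paraffin_like` | 169.8, 173.1 | 1.5, 1.5 | 0.020 | 120 µm |

The heights are set so the carbon-nanotube film's per-spectral-element
photoacoustic amplitude is ≈100× the PDMS film's and ≈50× the paraffin
film's, and paraffin ≈2× PDMS — the hierarchy of the physical samples.
The 176.0/177.4 THz PDMS pair is only 1.4 THz apart; widths of 1.0 THz
(still within the hundreds-of-GHz-to-few-THz range typical of
condensed-phase overtone features) keep them distinct maxima, as they are
in the physical film. Linearized Beer's law is available alongside the
exact form; at $\mu_A L \le 0.02$ the two differ by ≤1%.

## Problem scales and what the generator does not emulate

Three fixture scales share the same acoustic scene (4.4–10.6 MHz band,
7.5 MHz transducer) because $\Delta f_\mathrm{rep}$ and the optical
bandwidth are scaled together:

- `paper`: $\Delta f_\mathrm{rep} = 66.81$ Hz, 15 THz band → ~449,000
  samples, ~94,000 beat notes per record (~15 ms). Used for noiseless
  end-to-end recovery and resolution studies.
- `demo`: ×100 (~4,500 samples, ~940 notes). Used for averaging ladders
  (M up to 256) and jitter studies.
- `reduced`: ×1000 (~450 samples, ~90 notes, 3 µs delay so the shifted
  burst stays inside the short record). Used for Monte-Carlo studies that
  average up to ~10⁵ shots, e.g. the averaging-time-ratio study.

The default digitizer rate is 30 MS/s: the mapped band extends to
10.6 MHz, and the scene validator requires at least 2.5× the highest beat
frequency.

The fixture noise level (6 mV at the transducer output, before gain) was
chosen once so the paper-scale PDMS fixture has single-shot time-domain
SNR ≈ 0.02 — the regime where reaching SNR ≈ 30 takes hours of coherent
averaging, as for the physical polymer films. The generator emulates
white detector noise and rigid per-shot phase jitter only; it does not
emulate per-tooth phase decoherence, digitizer quantization, acoustic
reverberation, sample inhomogeneity or frequency-dependent $\beta$.
Passing tests therefore validate the processing chain and the scaling
laws under those idealized conditions, not the systematics of real
hardware.

## SNR definitions and studies

Time-domain SNR is the peak |amplitude| within a centerburst window
(default half-width 2.4 µs, the apodization half-width) divided by the
standard deviation outside an exclusion window (default 3× wider); scaled
scenes use proportionally narrower windows (0.5/1.5 µs) since their
bursts are ~0.26 µs wide. Spectral SNR is the per-bin mean over ≥8
repeated measurements divided by the per-bin standard deviation.
"Averaging time" for simulated data is $M/|\Delta f_\mathrm{rep}|$ for
$M$ coherently averaged periods.

The averaging-time-ratio study (the headline quantity of
`scripts/acceptance.py`) averages shots of two scenes that differ only by
a 100× source amplitude — same comb, sample geometry, transducer, noise
level, and, per seed, the *same* detector-noise stream — evaluating the
time-domain SNR after every shot and recording the first crossing of
threshold 20. The strong scene's single-shot SNR is ≈7 (so the threshold
is crossed after ~10 shots and the shot count granularity is a few
percent); the weak scene crosses after ~10⁵ shots. The log₁₀ of the
time ratio, averaged over 20 seeds, lands at ≈4.0, the quadratic
amplitude–time trade-off of white-noise-limited coherent averaging. The
shot loop draws every shot's noise individually (vectorized in chunks
whose row-major order reproduces the per-shot stream exactly), so the
result is an exact sample path, not an extrapolation.

The √τ-exponent and SNR-vs-power studies use the demo scale with noise
6 mV (single-shot SNR ≈ 7): exponents are fitted in log-log space, with
SNR at each ladder point averaged over a few independent seeds to keep
the max-of-noise bias at the weakest points below the fit tolerance.

## Numerical conventions and degenerate inputs

- All windows and shifts are circular; the record is periodic by
  construction.
- The apodization window keeps samples with circular offset in
  $[-w/2, w/2)$; a window at least as long as the record is the identity.
- A beat note at bin 0 (DC) is silently excluded from synthesis; a beat
  note at or beyond the Nyquist bin is a configuration error.
- `delta_f_rep = 0` (degenerate mapping), optical frequencies below
  $\nu_0$, negative acoustic frequencies, empty shot lists, mismatched
  grids and fully masked spectra all raise `ValueError` with a specific
  message.
- A noiseless record reports infinite time-domain SNR (flagged, not an
  exception) when the out-of-burst region is exactly zero; scenes with a
  truncated spectral envelope retain deterministic band-edge ringing
  there, so their noiseless "SNR" is large but finite.
- CSV interchange uses 12 significant digits and round-trips losslessly
  at that precision; every run is reproducible from its provenance log
  (config echo + seed + versions).
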