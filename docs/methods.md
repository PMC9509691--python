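# Methods

## The measurement model

Sodium fluorescein in aqueous solution is an equilibrium mixture of four
protonation states; only the anion and the dianion fluoresce. Their relative
abundance follows a two-state Henderson–Hasselbalch partition,

    f_dianion(pH) = 1 / (1 + 10^(pKa − pH)),      f_anion = 1 − f_dianion,

with pKa = 6.43 by default (the literature value for the anion↔dianion
equilibrium; it is an exposed parameter). The emitted spectrum at any pH is
the fraction-weighted mixture of two fixed per-species emission profiles, so
the ratio of two spectral bands straddling the species peaks encodes pH while
cancelling common-mode factors: dye amount, excitation power, probe distance.

The instrument readout is

    ratio = (Ch1 − Ch2) / (Ch1 + Ch2),      pH = slope · ratio + intercept,

where Ch1 is the 524/24 nm (dianion) band amplitude and Ch2 the 549/12 nm
(anion) band amplitude. The default constants slope = 10.34 and
intercept = 3.42 are the point device's published calibration; calibrations
fitted from the forward model carry their own constants.

**A structural property worth stating explicitly.** Because the band
integrals of fixed emission profiles are pH-independent constants, the ratio
is a Möbius function of u = 10^(pH − pKa) and therefore *exactly* a logistic
in pH with one-decade transition width, for any choice of profiles, filter
bands, or pH-independent background. Model parameters can move its centre
and its asymptotes, but not its shape. A linear calibration is consequently a
local approximation: accurate near the logistic's centre and biased in the
tails, with the acid tail (pH ≲ 5) the flattest region in practice. This is
the package's explanation for the characteristic error profile of a linear
ratiometric fluorescein calibration — error largest at pH 4–4.5 and shrinking
toward neutral — and it is reproduced quantitatively by the simulator
(grid mean absolute error ≈ 0.21 pH over 4.0–7.5, maximum bias at pH 4.0).

## Forward simulator (photophysics_sim)

Per-species emission profiles are Gaussian in wavelength (published spectra
are graphical only):

| species      | peak (nm) | FWHM (nm) | relative brightness |
|--------------|-----------|-----------|---------------------|
| dianion      | 520       | 35        | 1.00                |
| anion        | 550       | 45        | 0.49                |
| autofluorescence | 475   | 80        | 0.05                |
| porphyrin    | 632       | 30        | 0.02                |

The anion brightness 0.49 tracks the anion's lower quantum yield relative to
the dianion (≈0.37 vs ≈0.93) and places the ratio-logistic's centre near
pH 6.1, which makes the simulated ratio–pH curve as close to linear as the
model family allows over 4–7.5. Excitation-wavelength dependence is folded
into the brightnesses rather than modelled through absorption spectra.
Filters are ideal rectangles of the stated FWHM. Band integrals use the
trapezoid rule on a 0.5 nm grid (400–700 nm), on which the default passbands
are grid-exact.

Electronics: the LED is modulated as a 50%-duty 0/1 square wave at
f_mod = 500 Hz; the DAQ samples at fs = 10 kHz; the gain chain is
10 MV/A × 11 V/V. One unit of band-integrated signal is mapped to 1 nA of
detector photocurrent (`responsivity_a_per_unit = 1e-9`), which puts typical
fluorescein voltages at 0.5–2.5 V against a 10 V DAQ full scale. Noise is
additive white Gaussian on the voltage (default SD 2 mV per sample), plus an
ambient DC term (0.1 V) and a 120 Hz flicker term (0.02 V) to exercise
background rejection. Shot-noise scaling is deliberately omitted.

## Demodulation

The recording is truncated to a whole number of modulation cycles
(rectangular window, no taper), FFT'd, and the amplitude 2|X[k]|/N of the
bin nearest f_mod is taken (ties break toward the lower bin; magnitude only,
no phase). Over whole-cycle windows, DFT bins are exactly orthogonal, so DC
and any interference completing whole cycles in the window shift the
estimate only at machine precision; the tests bound the shift by 1e-6
relative under 10× flicker.

One discrete-sampling subtlety: the fundamental amplitude of a *sampled*
50%-duty square wave with M = fs/f_mod samples per cycle is
2/(M·sin(π/M)) — 0.63925 at M = 20 — not the continuous-time 2/π = 0.63662
(0.4% apart). `square_wave_fundamental` returns the exact discrete value and
the noiseless simulate→demodulate loop closes to 1e-9 relative against it.
The distinction cancels entirely in the ratio and hence in pH.

Amplitudes are divided by the gain product so they are comparable across
instrument configurations; the gains likewise cancel in the ratio.

## Calibration, QC, and replicate statistics

`PHCalibration` regresses pH on ratio by ordinary least squares (the
prediction direction of the instrument) and stores the Pearson r of the
pairs exactly as fitted. The default model-derived buffer ladder is
(4.5, 5.5, 6.5, 7.5): the published protocol used four buffers "in the
range of 4 to 7.5" without listing levels, and placing the acid-most buffer
at 4.5 keeps the anchors out of the logistic's flat acid tail, where a
buffer would pin the line to a saturated response and degrade mid-range
accuracy. Predictions below 4.5 are extrapolations, which is what produces
the acid-end error profile discussed above.

QC rejects readings in a fixed precedence order (the protocol is silent, so
the order is a package choice): `high_af` (af475 above threshold), then
`low_signal` (f520+f550 below threshold, including an undefined ratio at
zero total signal), then `out_of_range` (prediction outside [4, 7.5]). The
published threshold values are not printed; defaults are 5% (AF) and 1%
(minimum signal) of the default instrument's full-scale amplitude, i.e. 4.5
and 0.9 in gain-normalised units. Spots keep reduced n when QC discards
replicates; the pooled SD uses only groups with n ≥ 2, with the standard
(n−1)-weighted formula.

## Synthetic cohort generator

The generator emulates the clinical study's structure, with defaults set to
the published summary statistics, not to any patient-level data (which are
not public):

* groups: pre-cleaning (7 subjects, 40 surfaces) and post-cleaning
  (18 subjects, 45 surfaces + 10 drop-only surfaces, reproducing the
  85 rest / 95 drop bookkeeping, 540 replicate readings in triplicate);
  the study's control group contributed no usable pH readings (too little
  biofilm fluorescence), so it defaults to absent;
* group means: rest pH 6.70/6.75, diff pH 0.84/0.48 (pre/post); the
  cohort-wide rank-0 resting mean lands near the published 6.73;
* between-surface SD 0.30 (a package choice: gives within-group spreads
  comparable to the published box plots); replicate noise at the published
  0.23 pooled SD; readings clipped to [4, 7.5];
* ranks: 15% of surfaces rank 1, with a −0.25 pH offset in the pre-cleaning
  group (carious surfaces more acidic) and +0.10 in the post-cleaning group
  (the study observed the opposite trend there);
* saliva pH per subject: normal(7.0, 0.2) truncated to [5.5, 8.5]
  ("generally neutral"; no distribution is published).

What the generator does *not* emulate: correlation between rest and drop at
the same surface (drawn independently), subject-level random effects,
QC-driven missingness beyond the fixed drop-only count, or any microbiology.
Passing pipeline tests therefore demonstrate the statistical machinery's
operating characteristics under the stated summary conditions, not clinical
reproduction of the study.

## Statistical pipeline

Per surface: diff = rest − drop (missing if either is missing; no
imputation); saliva normalisation divides biofilm pH by the subject's saliva
pH (division, as in the study's discussion; subtraction is available through
the raw columns). The comparison grid crosses {rest, drop, diff} ×
{raw, saliva-normalised} × {each group pair overall, by rank stratum, and
rank 0 vs 1 within each group}, in deterministic order; cells with fewer
than two surfaces on a side are skipped with a logged warning.

Welch's t-test (scipy) is reported only when both sides pass Shapiro–Wilk
at α (groups smaller than 3, or constant, are treated as failing the gate);
the permutation test always runs and drives the significance flag. The
permutation statistic is the absolute difference of group means, two-sided
(the study names the test but not the statistic). Enumeration is exhaustive
when C(n_a+n_b, n_a) ≤ 20 000 (exact proportion); otherwise n_perm = 10 000
seeded shuffles with the (count+1)/(n_perm+1) correction so sampled p-values
are never zero. All randomness derives from one user-visible seed via a
`SeedSequence` spawned per grid cell, so skipped cells do not shift other
cells' draws.

Measured operating characteristics (recomputed by the test suite): type-I
rate of the diff comparison on null cohorts 0.05 ± 0.02 over 500 seeds
(n_perm = 1000 there, a runtime choice — the rejection rate is insensitive
to it); power ≥ 80% (measured ≈ 0.94) against the published 0.84 vs 0.48
diff means at n = 40/45 over 120 seeds.

## Imaging

The imaging device shares the ratiometric principle with G = 520/24 nm and
R = 549/12 nm bands: frames are averaged (10 by default), the per-pixel
ratio (G−R)/(G+R) goes through the same linear family, and pixels are
invalid when G+R is below `min_signal` (default 2% of the image's
99th-percentile combined signal — air bubbles and background), zero, or the
prediction leaves the calibration range. On spatially constant images the
per-pixel path reproduces the scalar path bit-for-bit (identical
floating-point expressions). Invalid pixels keep their raw prediction; the
mask, not the value, carries acceptance.

The imaging calibration constants are not published; `fit_imaging_calibration`
fits the linear family on the forward model over a stated pH range (default
5.5–6.6, bracketing resting biofilm). Because of the logistic shape, a
linear imaging calibration is trustworthy only over the range it was built
on: the default phantom (smooth relief 5.8–6.4) round-trips noiselessly
within 0.017 pH, while a rest-6.7/drop-5.2 phantom pair inverted with a
single 5.0–7.0 fit recovers the mean Stephan drop as 1.55 vs the true 1.5.
Frames are assumed co-registered; registration/stitching is out of scope.
On disk frames are 16-bit TIFF rescaled to unit range in memory; pH maps
export as 32-bit float TIFF plus a PNG heatmap.

## Numerical choices and degenerate inputs

* Lock-in bin ties break toward the lower frequency; amplitude (not power)
  convention, scaled 2/N, so constants are window-length independent.
* Permutation-test ties count as exceedances, with a 1e-12 relative
  tolerance so floating-point-equal statistics are not dropped.
* `compute_ratio` raises on zero total signal at the scalar level; the
  imaging path converts the same condition into mask invalidity instead.
* Zero-variance Welch inputs: identical constant groups return t = 0, p = 1;
  unequal constant groups raise.
* Degenerate calibration input (all ratios equal) raises rather than
  returning an unconstrained line.
* Floats are serialised with 17 significant digits, so write/read round
  trips are bit-exact.

## Problem sizes

Default simulations are sized for interactive runs: 1 s acquisitions
(10 000 samples), 15-point pH grids, 64×64 phantoms, 500-seed null
calibration at n_perm = 1000, 120-seed power estimation at n_perm = 2000.
All are parameters, and larger runs only tighten the Monte-Carlo error.

## Known limitations

* Two-state photophysics: the cation and neutral species (relevant below
  pH ~4.3) are not modelled, consistent with bounding measurements at pH 4.
* Gaussian profiles are calibrated to reproduce response linearity, not the
  instrument's exact reference spectra, which are unpublished.
* No shot noise, no detector saturation, no fibre-geometry or distance
  effects.
* The linear calibration family is retained even where a sigmoidal fit
  would extend range — matching the instrument, which accepts the acid-end
  bias to avoid overfitting.
* The cohort generator's independence assumptions (rest vs drop, surfaces
  within subject) make its power estimates optimistic relative to clustered
  real data.
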