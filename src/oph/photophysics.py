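"""Forward model of fluorescein fluorescence through a filtered, lock-in photodetector.

Sodium fluorescein in aqueous solution is an equilibrium mixture of four
protonation states, of which only the anion and the dianion fluoresce.  Their
relative abundance follows a two-state acid-base equilibrium with an apparent
pKa near 6.4, and the two species emit with distinct spectral peaks (dianion
~520 nm, anion ~550 nm).  The emitted spectrum at a given pH is therefore a
pH-weighted mixture of two fixed emission profiles, and the ratio of two
spectral bands straddling the two peaks encodes pH independently of dye
amount, excitation power, and probe distance.

This module renders that physics into synthetic photodetector recordings:

* :func:`species_fractions` -- anion/dianion partition at a given pH,
* :func:`emission_spectrum` -- the two-species fluorescein mixture spectrum,
* :func:`total_emission` -- scene spectrum including enamel autofluorescence
  (broad, ~475 nm) and bacterial porphyrin (~632 nm) backgrounds,
* :func:`expected_channel_signal` -- band-pass integration over one filter,
* :func:`simulate_acquisition` -- voltage time series for the four filtered
  photodiode channels under square-wave (lock-in) LED modulation.

Intensity units: emission profiles are dimensionless relative brightnesses;
a band integral ("channel signal") therefore carries units of brightness x nm.
The instrument model converts one such unit to detector photocurrent via
``InstrumentConfig.responsivity_a_per_unit`` (default 1e-9 A, i.e. channel
signals are numerically detector-referred nanoamps), then to volts through
the transimpedance and voltage gain stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluoresceinModel",
    "InstrumentConfig",
    "ChannelRecording",
    "species_fractions",
    "emission_spectrum",
    "total_emission",
    "expected_channel_signal",
    "expected_channel_signals",
    "simulate_acquisition",
    "square_wave_fundamental",
    "DEFAULT_WAVELENGTH_GRID",
]

#: Wavelength grid (nm) used when none is supplied: covers the fluorescein
#: emission window at 0.5 nm resolution, fine enough that rectangular band
#: integrals of the default 12-24 nm filters are grid-exact.
DEFAULT_WAVELENGTH_GRID = np.arange(400.0, 700.0 + 0.25, 0.5)


@dataclass(frozen=True)
class FluoresceinModel:
    """Photophysical parameters of fluorescein plus oral background emitters.

    The anion/dianion equilibrium constant ``pka`` defaults to 6.43, the
    literature value for the fluorescein anion<->dianion transition.  Species
    emission profiles are Gaussian in wavelength; peak positions follow the
    published emission maxima (520 nm dianion, 550 nm anion) and widths /
    relative brightnesses are chosen so the simulated band ratio responds
    near-linearly to pH over the dental-biofilm range 4-7.5 (the anion's
    lower brightness, default 0.49, mirrors its lower quantum yield).

    ``af_*`` parameters describe enamel/tissue autofluorescence (broad,
    centred near 475 nm); ``ppix_*`` describe bacterial porphyrin emission
    near 632 nm.  Both are pH-independent backgrounds.
    """

    pka: float = 6.43
    dianion_peak_nm: float = 520.0
    dianion_fwhm_nm: float = 35.0
    dianion_brightness: float = 1.0
    anion_peak_nm: float = 550.0
    anion_fwhm_nm: float = 45.0
    anion_brightness: float = 0.49
    af_brightness: float = 0.05
    af_peak_nm: float = 475.0
    af_fwhm_nm: float = 80.0
    ppix_brightness: float = 0.02
    ppix_peak_nm: float = 632.0
    ppix_fwhm_nm: float = 30.0

    def __post_init__(self) -> None:
        for name in ("dianion_fwhm_nm", "anion_fwhm_nm", "af_fwhm_nm", "ppix_fwhm_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "dianion_brightness",
            "anion_brightness",
            "af_brightness",
            "ppix_brightness",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.dianion_peak_nm < self.anion_peak_nm:
            raise ValueError("dianion_peak_nm must lie below anion_peak_nm")


@dataclass(frozen=True)
class InstrumentConfig:
    """Acquisition electronics and optics of the four-channel point probe.

    Defaults reproduce the bench instrument: blue LED square-wave modulated at
    500 Hz, DAQ sampling at 10 kHz, band-pass filters centred at 524 nm
    (dianion), 549 nm (anion), 475 nm (autofluorescence) and 632 nm
    (porphyrin), a 10 MV/A transimpedance stage followed by an 11 V/V
    non-inverting amplifier.  ``noise_sd_v`` is additive white Gaussian
    voltage noise per sample; ``ambient_dc_v`` and ``ambient_flicker_v``
    (at ``flicker_freq_hz``, default 120 Hz mains harmonic) model background
    room light that the lock-in stage must reject.
    """

    f_mod: float = 500.0
    fs: float = 10_000.0
    duration_s: float = 1.0
    filter_centers_nm: tuple[float, float, float, float] = (524.0, 549.0, 475.0, 632.0)
    filter_fwhm_nm: tuple[float, float, float, float] = (24.0, 12.0, 20.0, 22.0)
    gain_v_per_a: float = 1e7
    gain_stage2: float = 11.0
    responsivity_a_per_unit: float = 1e-9
    noise_sd_v: float = 0.002
    ambient_dc_v: float = 0.1
    ambient_flicker_v: float = 0.02
    flicker_freq_hz: float = 120.0
    daq_full_scale_v: float = 10.0

    def __post_init__(self) -> None:
        if not self.f_mod < self.fs / 2:
            raise ValueError("f_mod must be below the Nyquist frequency fs/2")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        n_cycles = self.duration_s * self.f_mod
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError("duration_s * f_mod must be a whole number of cycles")
        if any(f <= 0 for f in self.filter_fwhm_nm):
            raise ValueError("all filter FWHM must be > 0")
        if self.gain_v_per_a <= 0 or self.gain_stage2 <= 0:
            raise ValueError("gains must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    @property
    def gain_product(self) -> float:
        """Volts of output per unit of channel signal."""
        return self.gain_v_per_a * self.gain_stage2 * self.responsivity_a_per_unit


@dataclass
class ChannelRecording:
    """Sampled output voltage of one photodiode channel."""

    samples: np.ndarray
    fs: float
    channel_id: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.channel_id not in (1, 2, 3, 4):
            raise ValueError("channel_id must be in 1..4")


def species_fractions(ph: float, pka: float = 6.43) -> tuple[float, float]:
    """Anion and dianion fractions of fluorescein at a given pH.

    Two-state Henderson-Hasselbalch partition: the dianion fraction is the
    logistic ``1 / (1 + 10**(pka - ph))``; the two fractions sum to one.

    Returns
    -------
    (f_anion, f_dianion)
    """
    ph = float(ph)
    if not math.isfinite(ph):
        raise ValueError("ph must be finite")
    f_dianion = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 - f_dianion, f_dianion


def _gaussian_profile(wavelengths: np.ndarray, peak: float, fwhm: float, brightness: float) -> np.ndarray:
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return brightness * np.exp(-0.5 * ((wavelengths - peak) / sigma) ** 2)


def emission_spectrum(
    ph: float,
    wavelengths: np.ndarray | None = None,
    model: FluoresceinModel | None = None,
) -> np.ndarray:
    """Fluorescein emission spectrum at ``ph``: the pH-weighted two-species mixture.

    ``spectrum(ph) = f_dianion * dianion_profile + f_anion * anion_profile``,
    evaluated on ``wavelengths`` (nm, sorted ascending).  Background emitters
    are deliberately excluded; see :func:`total_emission` for the full scene.
    """
    model = model or FluoresceinModel()
    wavelengths = DEFAULT_WAVELENGTH_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("wavelength grid is empty")
    if np.any(np.diff(wavelengths) < 0):
        raise ValueError("wavelengths must be sorted ascending")
    f_anion, f_dianion = species_fractions(ph, model.pka)
    return f_dianion * _gaussian_profile(
        wavelengths, model.dianion_peak_nm, model.dianion_fwhm_nm, model.dianion_brightness
    ) + f_anion * _gaussian_profile(
        wavelengths, model.anion_peak_nm, model.anion_fwhm_nm, model.anion_brightness
    )


def total_emission(
    ph: float,
    wavelengths: np.ndarray | None = None,
    model: FluoresceinModel | None = None,
) -> np.ndarray:
    """Full scene spectrum: fluorescein mixture plus autofluorescence and porphyrin."""
    model = model or FluoresceinModel()
    wavelengths = DEFAULT_WAVELENGTH_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    spec = emission_spectrum(ph, wavelengths, model)
    spec = spec + _gaussian_profile(wavelengths, model.af_peak_nm, model.af_fwhm_nm, model.af_brightness)
    spec = spec + _gaussian_profile(wavelengths, model.ppix_peak_nm, model.ppix_fwhm_nm, model.ppix_brightness)
    return spec


def expected_channel_signal(
    wavelengths: np.ndarray,
    spectrum: np.ndarray,
    filter_center_nm: float,
    filter_fwhm_nm: float,
) -> float:
    """Integrate a spectrum over one ideal rectangular band-pass filter.

    The passband is ``[center - FWHM/2, center + FWHM/2]`` with unit in-band
    transmission (measured transmission curves are not modelled).  Result is
    in brightness x nm units.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    lo = filter_center_nm - filter_fwhm_nm / 2.0
    hi = filter_center_nm + filter_fwhm_nm / 2.0
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"filter passband [{lo:g}, {hi:g}] nm does not overlap the wavelength grid"
        )
    return float(np.trapezoid(spectrum[mask], wavelengths[mask]))


def expected_channel_signals(
    ph: float,
    model: FluoresceinModel | None = None,
    config: InstrumentConfig | None = None,
    wavelengths: np.ndarray | None = None,
) -> np.ndarray:
    """Expected signals of all four channels for the full scene at ``ph``."""
    model = model or FluoresceinModel()
    config = config or InstrumentConfig()
    wavelengths = DEFAULT_WAVELENGTH_GRID if wavelengths is None else np.asarray(wavelengths, dtype=float)
    spec = total_emission(ph, wavelengths, model)
    return np.array(
        [
            expected_channel_signal(wavelengths, spec, c, f)
            for c, f in zip(config.filter_centers_nm, config.filter_fwhm_nm)
        ]
    )


def square_wave_fundamental(fs: float, f_mod: float) -> float:
    """Fundamental amplitude of a sampled unit 0/1 square wave at 50% duty.

    For M = fs/f_mod samples per cycle (M even integer), the DFT amplitude of
    the fundamental is ``2 / (M * sin(pi / M))``, which converges to the
    continuous-time Fourier coefficient 2/pi as M grows (0.63925 vs 0.63662
    at the default M = 20).  Exact for whole-cycle windows.
    """
    m = fs / f_mod
    return 2.0 / (m * math.sin(math.pi / m))


def simulate_acquisition(
    ph: float,
    model: FluoresceinModel | None = None,
    config: InstrumentConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[ChannelRecording]:
    """Simulate one four-channel acquisition at a known biofilm pH.

    Per channel ``c`` the output voltage is::

        v_c(t) = G * S_c * m(t) + ambient_dc + flicker * sin(2 pi f_fl t) + noise

    where ``S_c`` is the band-integrated scene signal, ``G`` the end-to-end
    gain (``config.gain_product``), ``m(t)`` a 50%-duty 0/1 square wave at the
    LED modulation frequency, and the noise additive white Gaussian with SD
    ``config.noise_sd_v``.  The lock-in amplitude of a noiseless recording is
    ``G * S_c * square_wave_fundamental(fs, f_mod)``.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed seed gives
    identical samples.
    """
    model = model or FluoresceinModel()
    config = config or InstrumentConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    signals = expected_channel_signals(ph, model, config)
    n = config.n_samples
    t = np.arange(n) / config.fs
    modulation = ((t * config.f_mod) % 1.0 < 0.5).astype(float)
    background = config.ambient_dc_v + config.ambient_flicker_v * np.sin(
        2.0 * np.pi * config.flicker_freq_hz * t
    )
    recordings = []
    for channel_id, s in enumerate(signals, start=1):
        v = config.gain_product * s * modulation + background
        if config.noise_sd_v > 0:
            v = v + rng.normal(0.0, config.noise_sd_v, size=n)
        recordings.append(ChannelRecording(samples=v, fs=config.fs, channel_id=channel_id))
    return recordings
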