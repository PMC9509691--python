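"""Lock-in amplitude extraction at the LED modulation frequency.

The sampled voltage of each channel is transformed to the frequency domain
and the amplitude at the modulation frequency (500 Hz by default) is read
off.  Because ambient room light and its mains flicker live at other
frequencies (DC, 100/120 Hz, ...), and DFT bins over whole-cycle windows are
exactly orthogonal, this discriminates the fluorescence signal from
background light without optical shielding.
"""

from __future__ import annotations

import numpy as np

from .photophysics import ChannelRecording, InstrumentConfig

__all__ = ["ChannelAmplitudes", "lockin_amplitude", "demodulate"]


class ChannelAmplitudes:
    """Demodulated amplitudes of the four channels.

    ``f520``: dianion band (channel 1), ``f550``: anion band (channel 2),
    ``af475``: autofluorescence band (channel 3), ``p632``: porphyrin band
    (channel 4).  All are nonnegative magnitudes in gain-normalised signal
    units (see :mod:`oph.photophysics`).
    """

    __slots__ = ("f520", "f550", "af475", "p632")

    def __init__(self, f520: float, f550: float, af475: float, p632: float):
        values = (f520, f550, af475, p632)
        if not all(np.isfinite(values)):
            raise ValueError("amplitudes must be finite")
        if any(v < 0 for v in values):
            raise ValueError("amplitudes must be >= 0")
        self.f520, self.f550, self.af475, self.p632 = map(float, values)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f520, self.f550, self.af475, self.p632)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ChannelAmplitudes(f520={self.f520:.6g}, f550={self.f550:.6g}, "
            f"af475={self.af475:.6g}, p632={self.p632:.6g})"
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, ChannelAmplitudes) and self.as_tuple() == other.as_tuple()


def lockin_amplitude(samples: np.ndarray, fs: float, f_mod: float) -> float:
    """Amplitude of the ``f_mod`` component of a sampled signal.

    The window is truncated to a whole number of modulation cycles
    (rectangular window, no taper), the real FFT is taken, and the amplitude
    ``2 |X[k]| / N`` of the bin nearest ``f_mod`` is returned (ties broken
    toward the lower frequency).  For a pure sinusoid of amplitude A at
    ``f_mod`` this returns A.

    Raises
    ------
    ValueError
        If fewer than two full modulation cycles are available or ``f_mod``
        is at/above the Nyquist frequency.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if not f_mod < fs / 2:
        raise ValueError("f_mod must be below the Nyquist frequency fs/2")
    n = samples.size
    n_cycles = int(np.floor(n * f_mod / fs))
    if n_cycles < 2:
        raise ValueError("window must contain at least two full modulation cycles")
    n_trunc = int(round(n_cycles * fs / f_mod))
    x = samples[:n_trunc]
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n_trunc, d=1.0 / fs)
    k = int(np.argmin(np.abs(freqs - f_mod)))  # argmin takes the first (lower) bin on ties
    return float(2.0 * np.abs(spectrum[k]) / n_trunc)


def demodulate(
    recordings: list[ChannelRecording],
    config: InstrumentConfig | None = None,
) -> ChannelAmplitudes:
    """Demodulate the four channel recordings into gain-normalised amplitudes.

    Applies :func:`lockin_amplitude` per channel and divides by the
    end-to-end gain (``config.gain_product``) so that amplitudes are
    comparable across instrument configurations and directly comparable to
    the forward model's expected channel signals (up to the square-wave
    fundamental factor).
    """
    config = config or InstrumentConfig()
    if len(recordings) != 4:
        raise ValueError("expected exactly four channel recordings")
    fs = recordings[0].fs
    n = recordings[0].samples.size
    for rec in recordings[1:]:
        if rec.fs != fs:
            raise ValueError("all recordings must share the same sampling rate")
        if rec.samples.size != n:
            raise ValueError("all recordings must share the same duration")
    by_channel = {rec.channel_id: rec for rec in recordings}
    if sorted(by_channel) != [1, 2, 3, 4]:
        raise ValueError("recordings must cover channels 1..4 exactly once")
    amps = [
        lockin_amplitude(by_channel[c].samples, fs, config.f_mod) / config.gain_product
        for c in (1, 2, 3, 4)
    ]
    return ChannelAmplitudes(*amps)
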