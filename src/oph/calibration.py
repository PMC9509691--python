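"""Ratiometric pH calibration, QC gating, and replicate statistics.

The pH readout is the normalised difference of the dianion and anion band
amplitudes,

    ratio = (Ch1 - Ch2) / (Ch1 + Ch2),

mapped to pH through a linear calibration ``pH = slope * ratio + intercept``.
The default constants (slope 10.34, intercept 3.42) are the bench
instrument's published calibration against buffered fluorescein solutions
and a laboratory pH meter.  Readings are accepted only when the
autofluorescence channel is below threshold, the combined fluorescence
signal is above threshold, and the predicted pH falls inside the trusted
4-7.5 range; everything else is rejected with a reason.

The calibration itself is exposed both as a scikit-learn estimator
(:class:`PHCalibration`, ``fit``/``predict`` on ratio-pH pairs) and as a
plain parameter record (:class:`Calibration`) that serialises to JSON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Calibration",
    "Reading",
    "PHCalibration",
    "compute_ratio",
    "predict_ph",
    "fit_calibration",
    "simulated_calibration",
    "qc_evaluate",
    "aggregate_replicates",
    "pooled_sd",
    "DEFAULT_CALIBRATION_LEVELS",
]

#: Default buffer ladder used when fitting a calibration from the forward
#: model.  The acid-most buffer sits at pH 4.5: below ~4.5 the two-species
#: band ratio saturates (the dianion fraction is already <2%), so buffers
#: there pin the linear fit to a flat region and degrade mid-range accuracy.
#: Predictions down to pH 4 are extrapolations of the line, which is what
#: produces the characteristically larger acid-end error of a linear
#: calibration.
DEFAULT_CALIBRATION_LEVELS = (4.5, 5.5, 6.5, 7.5)


@dataclass(frozen=True)
class Calibration:
    """Linear ratio-to-pH calibration with QC thresholds.

    ``af_threshold`` and ``min_signal`` are in the same gain-normalised
    amplitude units as :class:`~oph.demodulation.ChannelAmplitudes`; the
    defaults correspond to 5% and 1% of the default instrument's 10 V DAQ
    full scale referred through its gain chain.
    """

    slope: float = 10.34
    intercept: float = 3.42
    ph_min: float = 4.0
    ph_max: float = 7.5
    af_threshold: float = 4.5
    min_signal: float = 0.9
    pearson_r: float | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if not self.ph_min < self.ph_max:
            raise ValueError("ph_min must be below ph_max")
        if self.af_threshold <= 0:
            raise ValueError("af_threshold must be > 0")
        if self.min_signal < 0:
            raise ValueError("min_signal must be >= 0")


@dataclass(frozen=True)
class Reading:
    """One QC-evaluated measurement.

    ``status`` is ``"accepted"`` or ``"rejected"``; ``reject_reason`` is one
    of ``none | high_af | low_signal | out_of_range``.  ``ph`` is populated
    whenever a ratio could be formed (including out-of-range rejections).
    """

    amplitudes: "ChannelAmplitudes"
    ratio: float | None
    ph: float | None
    status: str
    reject_reason: str = "none"

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def compute_ratio(ch1, ch2):
    """Normalised band difference ``(ch1 - ch2) / (ch1 + ch2)``.

    Accepts scalars or arrays of nonnegative amplitudes.  The result lies in
    [-1, 1] and is antisymmetric under swapping the channels.  A zero total
    signal leaves the ratio undefined and raises ``ValueError``.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if np.any(ch1 < 0) or np.any(ch2 < 0):
        raise ValueError("channel amplitudes must be >= 0")
    total = ch1 + ch2
    if np.any(total <= 0):
        raise ValueError("ch1 + ch2 must be > 0 for the ratio to be defined")
    out = (ch1 - ch2) / total
    return float(out) if out.ndim == 0 else out


def predict_ph(ratio, cal: Calibration | None = None):
    """Map a band ratio to pH through the linear calibration.

    No range clipping is performed here; range enforcement is the job of
    :func:`qc_evaluate`.
    """
    cal = cal or Calibration()
    ratio = np.asarray(ratio, dtype=float)
    out = cal.slope * ratio + cal.intercept
    return float(out) if out.ndim == 0 else out


class PHCalibration(BaseEstimator, RegressorMixin):
    """Ordinary-least-squares linear calibration of pH on band ratio.

    scikit-learn estimator interface: ``fit(X, y)`` with ``X`` the ratios
    (shape ``(n,)`` or ``(n, 1)``) and ``y`` the reference pH values from a
    laboratory pH meter; ``predict(X)`` applies the fitted line.  Fitted
    attributes: ``slope_``, ``intercept_``, ``pearson_r_``.

    Parameters other than the fitted line (QC thresholds, trusted range) are
    carried through unchanged into :meth:`to_calibration`.
    """

    def __init__(
        self,
        ph_min: float = 4.0,
        ph_max: float = 7.5,
        af_threshold: float = 4.5,
        min_signal: float = 0.9,
    ):
        self.ph_min = ph_min
        self.ph_max = ph_max
        self.af_threshold = af_threshold
        self.min_signal = min_signal

    def fit(self, X, y):
        ratios = np.asarray(X, dtype=float)
        if ratios.ndim == 2:
            if ratios.shape[1] != 1:
                raise ValueError("X must have a single ratio feature")
            ratios = ratios[:, 0]
        ph = np.asarray(y, dtype=float)
        if ratios.shape != ph.shape:
            raise ValueError("X and y must have matching lengths")
        if ratios.size < 2 or np.unique(ratios).size < 2:
            raise ValueError("need at least two distinct ratio values to fit")
        # pH regressed on ratio -- the prediction direction of the instrument.
        res = stats.linregress(ratios, ph)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.pearson_r_ = float(res.rvalue)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        ratios = np.asarray(X, dtype=float)
        if ratios.ndim == 2:
            ratios = ratios[:, 0]
        return self.slope_ * ratios + self.intercept_

    def to_calibration(self) -> Calibration:
        check_is_fitted(self, "slope_")
        return Calibration(
            slope=self.slope_,
            intercept=self.intercept_,
            ph_min=self.ph_min,
            ph_max=self.ph_max,
            af_threshold=self.af_threshold,
            min_signal=self.min_signal,
            pearson_r=self.pearson_r_,
        )


def fit_calibration(pairs: Sequence[tuple[float, float]], **qc_params) -> Calibration:
    """Fit a :class:`Calibration` from ``(ratio, reference_ph)`` pairs.

    Thin wrapper over :class:`PHCalibration`; ``qc_params`` (``ph_min``,
    ``ph_max``, ``af_threshold``, ``min_signal``) are carried into the result.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (ratio, reference_ph)")
    est = PHCalibration(**qc_params).fit(arr[:, 0], arr[:, 1])
    return est.to_calibration()


def simulated_calibration(
    model=None,
    config=None,
    levels: Sequence[float] = DEFAULT_CALIBRATION_LEVELS,
    **qc_params,
) -> Calibration:
    """Calibration fitted on noiseless forward-model buffer measurements.

    Emulates the bench calibration protocol: for each buffer level, compute
    the expected channel-1/channel-2 signals through the instrument's filters
    and regress pH on the resulting band ratio.
    """
    from .photophysics import FluoresceinModel, InstrumentConfig, expected_channel_signals

    model = model or FluoresceinModel()
    config = config or InstrumentConfig()
    pairs = []
    for ph in levels:
        s = expected_channel_signals(ph, model, config)
        pairs.append((compute_ratio(s[0], s[1]), ph))
    return fit_calibration(pairs, **qc_params)


def qc_evaluate(amplitudes, cal: Calibration | None = None) -> Reading:
    """Accept or reject a demodulated measurement, in fixed precedence order.

    1. ``high_af``    -- autofluorescence amplitude above ``af_threshold``,
    2. ``low_signal`` -- combined fluorescence ``f520 + f550`` below
       ``min_signal`` (or zero, leaving the ratio undefined),
    3. ``out_of_range`` -- predicted pH outside ``[ph_min, ph_max]``.

    The first failing check is reported.  Accepted readings always carry a
    pH inside the trusted range.
    """
    cal = cal or Calibration()
    if amplitudes.af475 > cal.af_threshold:
        ratio = ph = None
        if amplitudes.f520 + amplitudes.f550 > 0:
            ratio = compute_ratio(amplitudes.f520, amplitudes.f550)
            ph = predict_ph(ratio, cal)
        return Reading(amplitudes, ratio, ph, "rejected", "high_af")
    total = amplitudes.f520 + amplitudes.f550
    if total <= 0 or total < cal.min_signal:
        ratio = ph = None
        if total > 0:
            ratio = compute_ratio(amplitudes.f520, amplitudes.f550)
            ph = predict_ph(ratio, cal)
        return Reading(amplitudes, ratio, ph, "rejected", "low_signal")
    ratio = compute_ratio(amplitudes.f520, amplitudes.f550)
    ph = predict_ph(ratio, cal)
    if not (cal.ph_min <= ph <= cal.ph_max):
        return Reading(amplitudes, ratio, ph, "rejected", "out_of_range")
    return Reading(amplitudes, ratio, ph, "accepted", "none")


def aggregate_replicates(phs: Sequence[float]) -> tuple[float, float | None, int]:
    """Mean, sample SD and count of the accepted replicate pH values of a spot.

    Spots are measured in triplicate; spots where QC left fewer than three
    replicates are retained with reduced ``n``.  The SD uses the n-1
    denominator and is ``None`` for a single reading.
    """
    values = np.asarray(list(phs), dtype=float)
    if values.size == 0:
        raise ValueError("no replicate values to aggregate")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else None
    return mean, sd, int(values.size)


def pooled_sd(triplets: Sequence[Sequence[float]]) -> float:
    """Pooled standard deviation across replicate groups.

    ``sqrt( sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) )`` over groups with at
    least two readings; smaller groups carry no spread information and are
    excluded.  This is the instrument's repeatability metric.
    """
    num = 0.0
    den = 0
    for group in triplets:
        values = np.asarray(list(group), dtype=float)
        if values.size < 2:
            continue
        num += (values.size - 1) * float(values.var(ddof=1))
        den += values.size - 1
    if den == 0:
        raise ValueError("pooled SD requires at least one group with n >= 2")
    return math.sqrt(num / den)
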