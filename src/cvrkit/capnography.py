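"""End-tidal CO2 (PetCO2) regressor extraction from raw capnography.

A nasal-cannula capnograph samples expired CO2 partial pressure (mmHg) at a
few tens of Hz.  The end-tidal value — the expiratory-plateau peak of each
breath — tracks arterial CO2 and is the physiological stimulus regressor for
breath-hold cerebrovascular-reactivity mapping.  The extraction chain is:

    detect expiratory peaks -> linear interpolation through peaks
    -> resample at the fMRI TR grid (with a shift for the sampling-line
       transit delay) -> zero-phase Butterworth band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin


class InsufficientRespiratoryEvents(ValueError):
    """Fewer than two expiratory peaks: end-tidal interpolation impossible."""


class TraceCoverageError(ValueError):
    """The recording does not cover the requested scan window."""


class NyquistError(ValueError):
    """A filter cutoff frequency is at or above the Nyquist frequency."""


@dataclass
class RawCapnoTrace:
    """Uniformly sampled expired-CO2 pressure recording.

    Parameters
    ----------
    sampling_interval : float
        Time between samples, seconds.
    values : ndarray
        CO2 partial pressure per sample, mmHg.
    acquisition_delay : float
        Transit delay of the gas sampling line, seconds.  Subtracted when
        aligning the trace to scanner time.
    """

    sampling_interval: float
    values: np.ndarray
    acquisition_delay: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("capnography values must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.sampling_interval

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.sampling_interval


@dataclass
class PetCO2Trace:
    """End-tidal CO2 trace sampled at fMRI frame times.

    ``rest_level`` is the mean over the pre-task baseline window of the
    unfiltered trace, mmHg.  After filtering (``is_filtered``) the trace is
    zero-mean; CVR betas are then per-mmHg of PetCO2 *modulation*.
    """

    frame_times: np.ndarray
    values: np.ndarray
    is_filtered: bool = False
    rest_level: float = float("nan")

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_times.shape != self.values.shape:
            raise ValueError("frame_times and values must have equal length")


@dataclass
class FilterSpec:
    """Band-pass specification expressed as cutoff periods.

    Defaults: pass band between 150 s and 10.1 s periods, i.e. 1000/150 ~ 6.7
    to 1000/10.1 ~ 99 mHz, applied as a zero-phase (forward-reverse)
    Butterworth filter of the given one-way design order.
    """

    low_cutoff_period: float = 150.0
    high_cutoff_period: float = 10.1
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not self.low_cutoff_period > self.high_cutoff_period > 0:
            raise ValueError("require low_cutoff_period > high_cutoff_period > 0")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    @property
    def band_mhz(self) -> tuple[float, float]:
        """Band edges in mHz, rounded as conventionally printed."""
        lo = round(1000.0 / self.low_cutoff_period, 1)
        hi = round(1000.0 / self.high_cutoff_period)
        return lo, hi


def detect_expiratory_peaks(
    raw: RawCapnoTrace,
    min_prominence: float = 5.0,
    min_separation: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate end-expiration peaks of the CO2 waveform.

    One peak is expected per expiration; during apnea (breath hold) the
    waveform stays near zero and no peaks are returned.  Prominence rejects
    intra-breath ripples, separation rejects double counting.

    Returns
    -------
    (peak_times, peak_values) : ndarray pair, times strictly increasing.
    """
    if raw.values.size == 0:
        raise ValueError("empty capnography trace")
    if min_separation < 2 * raw.sampling_interval:
        raise ValueError("min_separation must be >= 2 samples")
    distance = max(1, int(np.ceil(min_separation / raw.sampling_interval)))
    idx, _ = sps.find_peaks(raw.values, prominence=min_prominence, distance=distance)
    return idx * raw.sampling_interval, raw.values[idx]


def build_end_tidal_trace(
    raw: RawCapnoTrace,
    peaks: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Piecewise-linear end-tidal series on the raw time grid.

    Values before the first and after the last peak are held constant at the
    nearest peak value (no extrapolation into the regressor).
    """
    peak_times, peak_values = np.asarray(peaks[0], float), np.asarray(peaks[1], float)
    if peak_times.size < 2:
        raise InsufficientRespiratoryEvents(
            f"insufficient respiratory events: {peak_times.size} peak(s) detected, "
            "need >= 2 for end-tidal interpolation"
        )
    return np.interp(raw.times, peak_times, peak_values)


def resample_to_frames(
    end_tidal_series: np.ndarray,
    sampling_interval: float,
    tr: float,
    n_frames: int,
    shift: float = 0.0,
) -> PetCO2Trace:
    """Sample the end-tidal series at frame_time_i = i*tr + shift.

    ``shift`` compensates the gas sampling-line transit delay: a positive
    shift reads the recording *later*, aligning recorded CO2 with the
    expiration that produced it.
    """
    series = np.asarray(end_tidal_series, dtype=float)
    t = np.arange(series.size) * sampling_interval
    frame_times = np.arange(n_frames) * tr
    sample_times = frame_times + shift
    if sample_times[0] < t[0] - 1e-9 or sample_times[-1] > t[-1] + 1e-9:
        raise TraceCoverageError(
            f"trace does not cover scan: need [{sample_times[0]:.1f}, "
            f"{sample_times[-1]:.1f}] s, have [{t[0]:.1f}, {t[-1]:.1f}] s"
        )
    values = np.interp(sample_times, t, series)
    return PetCO2Trace(frame_times=frame_times, values=values)


def bandpass_filter(
    series: np.ndarray,
    spec: FilterSpec,
    sampling_interval: float,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass between 1/low and 1/high period.

    The design order is the one-way order; the forward-reverse pass doubles
    the effective magnitude-response order.  Reflective padding suppresses
    edge transients on short series.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    if n <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    fs = 1.0 / sampling_interval
    nyq = fs / 2.0
    f_lo = 1.0 / spec.low_cutoff_period
    f_hi = 1.0 / spec.high_cutoff_period
    if f_hi >= nyq or f_lo >= nyq:
        raise NyquistError(
            f"cutoff exceeds Nyquist: band ({f_lo:.4g}, {f_hi:.4g}) Hz vs "
            f"Nyquist {nyq:.4g} Hz"
        )
    sos = sps.butter(spec.order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    padlen = min(n - 1, 6 * spec.order)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=axis, padtype="even", padlen=padlen)
    return sps.sosfilt(sos, x, axis=axis)


def modulation_range(series: np.ndarray, axis: int = -1) -> float | np.ndarray:
    """95th minus 5th percentile of a series (linear-interpolation convention).

    Used as the summary amplitude of the filtered PetCO2 (mmHg) and of the
    filtered fMRI signals (%).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    hi = np.percentile(x, 95, axis=axis)
    lo = np.percentile(x, 5, axis=axis)
    return hi - lo


class PetCO2Extractor(BaseEstimator, TransformerMixin):
    """Raw capnography -> filtered PetCO2 regressor at the fMRI TR grid.

    sklearn-style transformer: ``fit`` detects expiratory peaks and builds
    the end-tidal interpolant; ``transform`` resamples at frame times and
    band-pass filters.  Fitted attributes: ``peak_times_``, ``peak_values_``,
    ``rest_level_``, ``modulation_range_``.

    Parameters
    ----------
    tr : repetition time of the fMRI series, s.
    n_frames : number of fMRI frames.
    shift : sampling-line delay compensation, s (see `resample_to_frames`).
    min_prominence, min_separation : peak-detection settings (mmHg, s).
    filter_spec : band-pass specification; None skips filtering.
    baseline_window : pre-task window over which rest_level_ is averaged, s.
    """

    def __init__(
        self,
        tr: float = 5.0,
        n_frames: int = 132,
        shift: float = 0.0,
        min_prominence: float = 5.0,
        min_separation: float = 2.0,
        filter_spec: FilterSpec | None = None,
        baseline_window: float = 60.0,
    ):
        self.tr = tr
        self.n_frames = n_frames
        self.shift = shift
        self.min_prominence = min_prominence
        self.min_separation = min_separation
        self.filter_spec = filter_spec
        self.baseline_window = baseline_window

    def fit(self, raw: RawCapnoTrace, y=None) -> "PetCO2Extractor":
        self.peak_times_, self.peak_values_ = detect_expiratory_peaks(
            raw, self.min_prominence, self.min_separation
        )
        self.end_tidal_ = build_end_tidal_trace(raw, (self.peak_times_, self.peak_values_))
        self.sampling_interval_ = raw.sampling_interval
        return self

    def transform(self, raw: RawCapnoTrace | None = None) -> PetCO2Trace:
        unfiltered = resample_to_frames(
            self.end_tidal_, self.sampling_interval_, self.tr, self.n_frames, self.shift
        )
        baseline = unfiltered.values[unfiltered.frame_times < self.baseline_window]
        rest = float(np.mean(baseline)) if baseline.size else float("nan")
        spec = self.filter_spec if self.filter_spec is not None else FilterSpec()
        values = bandpass_filter(unfiltered.values, spec, self.tr)
        trace = PetCO2Trace(
            frame_times=unfiltered.frame_times,
            values=values,
            is_filtered=True,
            rest_level=rest,
        )
        self.unfiltered_ = unfiltered
        self.rest_level_ = rest
        self.modulation_range_ = float(modulation_range(values))
        return trace

    def fit_transform(self, raw: RawCapnoTrace, y=None) -> PetCO2Trace:  # type: ignore[override]
        return self.fit(raw).transform(raw)


def extract_petco2(
    raw: RawCapnoTrace,
    tr: float,
    n_frames: int,
    shift: float = 0.0,
    filter_spec: FilterSpec | None = None,
    min_prominence: float = 5.0,
    min_separation: float = 2.0,
) -> PetCO2Trace:
    """One-call extraction chain (peaks -> interpolate -> resample -> filter)."""
    return PetCO2Extractor(
        tr=tr,
        n_frames=n_frames,
        shift=shift,
        min_prominence=min_prominence,
        min_separation=min_separation,
        filter_spec=filter_spec,
    ).fit_transform(raw)
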