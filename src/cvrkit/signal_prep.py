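"""Perfusion/BOLD separation and fractional-change normalisation.

The acquisition interleaves ASL tag and control frames.  Surround
subtraction (difference of a frame against the mean of its two opposite-
label neighbours) extracts the perfusion-weighted signal proportional to
CBF and cancels common-mode trends to second order; surround averaging
removes the parity-alternating perfusion contamination from the BOLD
signals.  Both series are then expressed as fractional change from a
pre-task baseline and band-pass filtered voxelwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .capnography import FilterSpec, bandpass_filter

log = logging.getLogger(__name__)

WEIGHTINGS = ("asl", "ge", "se")


class LabelOrderError(ValueError):
    """Tag/control frame labels do not strictly alternate."""


@dataclass
class InterleavedSeries:
    """4D fMRI volume series with alternating tag/control frames.

    volumes : (x, y, z, frame) array
    frame_labels : sequence of "tag"/"control", strictly alternating
    tr : seconds
    weighting : "asl" | "ge" | "se"
    """

    volumes: np.ndarray
    frame_labels: np.ndarray
    tr: float
    weighting: str

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.frame_labels = np.asarray(self.frame_labels)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, frame)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if self.frame_labels.size != self.volumes.shape[-1]:
            raise ValueError("one label per frame required")

    @property
    def n_frames(self) -> int:
        return self.volumes.shape[-1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr

    def validate_labels(self) -> None:
        lab = self.frame_labels
        if not set(np.unique(lab)) <= {"tag", "control"}:
            raise LabelOrderError(f"unknown labels {set(np.unique(lab))}")
        if any(lab[i] == lab[i + 1] for i in range(lab.size - 1)):
            raise LabelOrderError("label order violation: labels must alternate")


def make_labels(n_frames: int, frame_order: str = "tag_first") -> np.ndarray:
    """Alternating label vector; ``frame_order`` is 'tag_first'/'control_first'."""
    if frame_order not in ("tag_first", "control_first"):
        raise ValueError("frame_order must be 'tag_first' or 'control_first'")
    first, second = ("tag", "control") if frame_order == "tag_first" else ("control", "tag")
    return np.array([first, second] * (n_frames // 2 + 1))[:n_frames]


@dataclass
class FractionalChangeSeries:
    """Voxelwise fractional change from baseline (unitless; x100 gives %).

    ``baseline_map`` is the 3D mean over the baseline window used for
    normalisation; voxels where it is non-positive are NaN-masked.
    """

    volumes: np.ndarray
    frame_times: np.ndarray
    weighting: str
    baseline_map: np.ndarray


def _surround_neighbor_mean(vols: np.ndarray) -> np.ndarray:
    """Mean of temporal neighbours; edge frames use their single neighbour."""
    nb = np.empty_like(vols)
    nb[..., 1:-1] = 0.5 * (vols[..., :-2] + vols[..., 2:])
    nb[..., 0] = vols[..., 1]
    nb[..., -1] = vols[..., -2]
    return nb


def surround_subtract(series: InterleavedSeries) -> InterleavedSeries:
    """Perfusion-weighted difference series on the full TR grid.

    diff_i = +-(s_i - (s_{i-1}+s_{i+1})/2), signed so control - tag is
    positive; linear common-mode trends cancel at interior frames.
    """
    if series.weighting != "asl":
        raise ValueError("surround subtraction applies to the ASL weighting")
    series.validate_labels()
    sign = np.where(series.frame_labels == "control", 1.0, -1.0)
    diff = sign * (series.volumes - _surround_neighbor_mean(series.volumes))
    return replace(series, volumes=diff)


def surround_average(series: InterleavedSeries) -> InterleavedSeries:
    """BOLD series with parity-alternating perfusion contamination removed.

    avg_i = (s_i + (s_{i-1}+s_{i+1})/2)/2: any additive component that
    alternates exactly with tag/control parity cancels at interior frames.
    """
    if series.weighting not in ("ge", "se"):
        raise ValueError("surround averaging applies to BOLD weightings")
    series.validate_labels()
    avg = 0.5 * (series.volumes + _surround_neighbor_mean(series.volumes))
    return replace(series, volumes=avg)


def to_fractional_change(
    series: InterleavedSeries, baseline_window: float = 50.0
) -> FractionalChangeSeries:
    """Voxelwise (s(t) - m)/m, m = mean over frames with t < baseline_window.

    For the perfusion difference series the baseline is the mean perfusion
    difference over the same window, so the output is fractional CBF change.
    Voxels with non-positive baseline are NaN-masked (count logged).
    """
    t = series.frame_times
    sel = t < baseline_window
    if not sel.any():
        raise ValueError("series does not cover the baseline window")
    m = series.volumes[..., sel].mean(axis=-1)
    bad = ~(m > 0)
    n_bad = int(bad.sum())
    if n_bad:
        log.info("to_fractional_change: masking %d voxel(s) with baseline <= 0", n_bad)
    m_safe = np.where(bad, np.nan, m)
    fc = (series.volumes - m_safe[..., None]) / m_safe[..., None]
    return FractionalChangeSeries(
        volumes=fc, frame_times=t, weighting=series.weighting, baseline_map=m
    )


def filter_series(fc: FractionalChangeSeries, spec: FilterSpec) -> FractionalChangeSeries:
    """Voxelwise zero-phase band-pass (same contract as the PetCO2 filter)."""
    tr = float(fc.frame_times[1] - fc.frame_times[0])
    vols = fc.volumes
    finite = np.all(np.isfinite(vols), axis=-1)
    out = np.full_like(vols, np.nan)
    if finite.any():
        out[finite] = bandpass_filter(vols[finite], spec, tr, axis=-1)
    return FractionalChangeSeries(
        volumes=out,
        frame_times=fc.frame_times,
        weighting=fc.weighting,
        baseline_map=fc.baseline_map,
    )


class SignalPreparer(BaseEstimator, TransformerMixin):
    """InterleavedSeries -> filtered FractionalChangeSeries, in one transform.

    Applies the weighting-appropriate surround operation (subtraction for
    ASL, averaging for GE/SE BOLD), fractional-change normalisation over
    ``baseline_window`` seconds, and the voxelwise band-pass.
    """

    def __init__(
        self,
        baseline_window: float = 50.0,
        filter_spec: FilterSpec | None = None,
        apply_filter: bool = True,
    ):
        self.baseline_window = baseline_window
        self.filter_spec = filter_spec
        self.apply_filter = apply_filter

    def fit(self, series: InterleavedSeries, y=None) -> "SignalPreparer":
        series.validate_labels()
        return self

    def transform(self, series: InterleavedSeries) -> FractionalChangeSeries:
        if series.weighting == "asl":
            sep = surround_subtract(series)
        else:
            sep = surround_average(series)
        fc = to_fractional_change(sep, self.baseline_window)
        if self.apply_filter:
            spec = self.filter_spec if self.filter_spec is not None else FilterSpec()
            fc = filter_series(fc, spec)
        return fc


def prepare_series(
    series: InterleavedSeries,
    baseline_window: float = 50.0,
    filter_spec: FilterSpec | None = None,
) -> FractionalChangeSeries:
    """Functional shorthand for ``SignalPreparer().fit_transform``."""
    return SignalPreparer(
        baseline_window=baseline_window, filter_spec=filter_spec
    ).fit_transform(series)
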