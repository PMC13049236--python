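"""End-to-end subject processing: capnography + interleaved series -> CVR maps."""

from __future__ import annotations

import numpy as np

from .capnography import FilterSpec, PetCO2Extractor, PetCO2Trace
from .cvr_mapping import CVRMap, LagSearchSpec, map_cvr
from .signal_prep import InterleavedSeries, SignalPreparer
from .synthetic import SyntheticSubject


def process_subject(
    raw_capno,
    series: dict[str, InterleavedSeries],
    mask: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
    lag_search: LagSearchSpec | None = None,
    baseline_window: float = 50.0,
    petco2_shift: float = 0.0,
) -> tuple[dict[str, CVRMap], PetCO2Trace]:
    """Run the full single-subject pipeline.

    Extracts the filtered PetCO2 regressor at the TR grid of the first
    series, prepares each weighting (surround operation, fractional change,
    band-pass), and fits the lagged GLM per weighting (the lag is optimised
    independently for each).  Returns ({weighting: CVRMap}, PetCO2Trace).
    ``petco2_shift`` compensates the gas sampling-line delay.
    """
    first = next(iter(series.values()))
    spec = filter_spec or FilterSpec()
    extractor = PetCO2Extractor(
        tr=first.tr,
        n_frames=first.n_frames,
        shift=petco2_shift,
        filter_spec=spec,
    )
    trace = extractor.fit_transform(raw_capno)
    prep = SignalPreparer(baseline_window=baseline_window, filter_spec=spec)
    maps = {}
    for w, s in series.items():
        fc = prep.fit_transform(s)
        maps[w] = map_cvr(
            fc,
            trace,
            spec=lag_search,
            mask=mask,
            x_unfiltered=extractor.unfiltered_.values,
            frame_labels=s.frame_labels,
            filter_spec=spec,
        )
    return maps, trace


def process_synthetic_subject(
    subject: SyntheticSubject,
    mask: np.ndarray | None = None,
    **kwargs,
) -> tuple[dict[str, CVRMap], PetCO2Trace]:
    """`process_subject` convenience for generator output.

    Uses the subject's known sampling-line delay as the PetCO2 shift.
    """
    kwargs.setdefault("petco2_shift", subject.truth.capno_delay)
    return process_subject(subject.raw_capno, subject.series, mask=mask, **kwargs)
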