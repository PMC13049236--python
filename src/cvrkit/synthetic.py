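"""Synthetic breath-hold cohort generator with lossless ground truth.

Emulates the acquisition protocol (60 s free-breathing baseline, then 10
cycles of 20 s post-expiratory breath hold + 40 s recovery, TR 5 s):

* breathing-shaped capnography — one expiratory plateau per breath, near
  zero during apnea, with the first post-BH expiration carrying the
  elevated end-tidal value which then decays exponentially over recovery;
* a lagged linear CBF response f(t) = 1 + (CVR_ASL/100) * dPetCO2(t - lag);
* interleaved tag/control ASL frames whose control - tag difference is
  proportional to CBF;
* GE/SE BOLD signals via a linearised isometabolic coupling
  b = (c_micro * v_micro + c_macro * v_macro) * (f - 1), with the
  macrovascular weight v_macro taken from a per-ROI venous-density table
  (SE macrovascular coupling suppressed), plus parity-alternating perfusion
  contamination, white noise and polynomial drift.

Subject-level true GM-mean CVRs are drawn from the group distributions
(ASL 5.3 +- 1.8 %/mmHg, GE 0.18 +- 0.05, SE 0.09 +- 0.03 % BOLD/mmHg) with
a shared vasodilatory factor plus a GE-specific venous factor, so that
across-subject correlations are ordered r(SE, ASL) > r(GE, ASL).  Every
dataset carries its GroundTruth; recovery tests never learn truth from the
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .capnography import RawCapnoTrace
from .signal_prep import InterleavedSeries, make_labels

# Programmed post-BH end-tidal rise (mmHg) per mmHg of desired filtered-trace
# 95th-5th percentile range.  Calibrated once on the default protocol so the
# default trace reproduces the target modulation statistic.
RISE_PER_FILTERED_RANGE = 1.279

LAG_VALUES = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
LAG_PROBS = np.array([0.05, 0.20, 0.50, 0.20, 0.05])


@dataclass
class ProtocolSpec:
    """Breath-hold task timing and sampling parameters."""

    baseline_duration: float = 60.0
    n_cycles: int = 10
    bh_duration: float = 20.0
    recovery_duration: float = 40.0
    tr: float = 5.0
    breathing_rate: float = 12.0  # breaths/min
    capno_sampling_rate: float = 20.0  # Hz

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.n_cycles * (
            self.bh_duration + self.recovery_duration
        )

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration / self.tr))

    @property
    def breath_period(self) -> float:
        return 60.0 / self.breathing_rate


@dataclass
class GroundTruth:
    """Population-level generative parameters (the study conditions).

    CVR units: ASL %CBF/mmHg, BOLD % BOLD/mmHg.  noise_sd values are raw
    signal units (s0 = 1000 corresponds to 0.1% of baseline per unit).
    """

    petco2_rest: float = 35.0
    petco2_rest_sd: float = 1.4
    petco2_modulation: float = 6.7  # target filtered 95th-5th range, mmHg
    petco2_modulation_sd: float = 2.1
    recovery_tau: float = 15.0  # post-BH end-tidal decay constant, s
    capno_noise_sd: float = 0.3
    capno_delay: float = 0.0  # gas sampling-line transit delay, s

    asl_mean: float = 5.3
    asl_sd: float = 1.8
    ge_mean: float = 0.18
    ge_sd: float = 0.05
    se_mean: float = 0.09
    se_sd: float = 0.03
    rho_ge: float = 0.55  # loading of GE subject means on the shared factor
    tau_ge: float = 0.60  # loading of GE subject means on the venous factor
    rho_se: float = 0.75

    macro_share_ge: float = 0.40  # fraction of GE coupling through v_macro
    macro_share_se: float = 0.05  # SE macrovascular suppression
    macro_subject_sd: float = 0.5  # venous-factor wobble of the GE macro share
    v_macro_max: float = 0.5

    perfusion_fraction: float = 0.01  # baseline (control - tag)/control
    s0: float = 1000.0
    asl_common_bold: float = 0.005  # small BOLD-like common mode on ASL frames
    bold_contamination: float = 0.2  # epsilon / perfusion_fraction
    noise_sd: dict = field(
        default_factory=lambda: {"asl": 1.5, "ge": 9.0, "se": 6.5}
    )
    drift_amplitude: float = 5.0  # SD of Legendre drift coefficients, raw units

    grid_shape: tuple = (12, 12, 8)
    n_rois: int = 48
    pattern_sd: float = 0.25  # spatial SD of the shared CVR pattern
    voxel_noise_sd: float = 0.15  # subject-specific multiplicative field noise
    smoothing_tau: float = 0.0  # CBF response exponential smoothing, s


@dataclass
class SubjectTruth:
    """Per-subject slice of the ground truth (stored losslessly)."""

    rest_level: float
    modulation_target: float
    rise: float
    capno_delay: float
    anchor_times: np.ndarray  # expiration times, s
    anchor_values: np.ndarray  # programmed end-tidal values, mmHg
    cvr_asl_mean: float
    cvr_ge_mean: float
    cvr_se_mean: float
    venous_factor: float
    cvr_asl_true: np.ndarray
    cvr_ge_true: np.ndarray
    cvr_se_true: np.ndarray
    lag_true: np.ndarray
    c_micro_ge: float
    c_macro_ge: float
    c_micro_se: float
    c_macro_se: float

    def petco2_envelope(self, t: np.ndarray) -> np.ndarray:
        """Programmed PetCO2 change from rest at times t (edges held)."""
        return (
            np.interp(t, self.anchor_times, self.anchor_values) - self.rest_level
        )


@dataclass
class SyntheticSubject:
    raw_capno: RawCapnoTrace
    series: dict  # weighting -> InterleavedSeries
    truth: SubjectTruth


@dataclass
class CohortTruth:
    params: GroundTruth
    protocol: ProtocolSpec
    gm_mask: np.ndarray
    roi_labels: np.ndarray
    venous_density: dict
    v_macro: np.ndarray  # per-voxel macrovascular weight
    pattern: np.ndarray  # shared spatial CVR pattern, GM mean 1
    subjects: list


# ---------------------------------------------------------------------------
# anatomy helpers


def default_gm_mask(grid_shape: tuple = (12, 12, 8)) -> np.ndarray:
    """Ellipsoidal 'gray matter' mask occupying the grid centre."""
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (
        ((x - cx) / (nx / 2)) ** 2
        + ((y - cy) / (ny / 2)) ** 2
        + ((z - cz) / (nz / 2)) ** 2
    )
    return r <= 1.0


def default_roi_labels(gm_mask: np.ndarray, n_rois: int = 48) -> np.ndarray:
    """Split GM voxels into n_rois contiguous (lexicographic) parcels."""
    labels = np.zeros(gm_mask.shape, dtype=int)
    idx = np.argwhere(gm_mask)
    chunks = np.array_split(np.arange(len(idx)), n_rois)
    for roi, chunk in enumerate(chunks, start=1):
        for i in chunk:
            labels[tuple(idx[i])] = roi
    return labels


def default_venous_density(n_rois: int = 48) -> dict:
    """Fixed synthetic per-ROI macrovascular venous-density table (a.u.).

    Stands in for an SWI-derived atlas table; right-skewed like real venous
    volume estimates.  Deterministic (fixed internal seed) so the 'atlas'
    is a constant of the generator.
    """
    rng = np.random.default_rng(20260901)
    vals = rng.lognormal(mean=0.0, sigma=0.6, size=n_rois)
    return {i + 1: float(v) for i, v in enumerate(vals)}


# ---------------------------------------------------------------------------
# capnography


def expiration_schedule(
    protocol: ProtocolSpec, rest: float, rise: float, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Expiration (end-tidal) times and programmed values for the task.

    Breaths tile each breathing window (baseline and every recovery
    interval); none occur during breath holds.  The first expiration after
    each BH carries rest + rise; later recovery breaths decay toward rest
    with time constant tau.
    """
    tb = protocol.breath_period
    times, values = [], []

    def tile(start: float, duration: float, elevated: bool) -> None:
        n = int(np.floor(duration / tb + 1e-9))
        first = start + tb / 2
        for k in range(n):
            t = first + k * tb
            if elevated:
                values.append(rest + rise * np.exp(-(t - first) / tau))
            else:
                values.append(rest)
            times.append(t)

    tile(0.0, protocol.baseline_duration, elevated=False)
    t0 = protocol.baseline_duration
    for _ in range(protocol.n_cycles):
        t0 += protocol.bh_duration  # apnea: no expirations
        tile(t0, protocol.recovery_duration, elevated=True)
        t0 += protocol.recovery_duration
    return np.asarray(times), np.asarray(values)


def gen_capnography(
    protocol: ProtocolSpec,
    rest: float = 35.0,
    rise: float = 8.7,
    tau: float = 15.0,
    noise_sd: float = 0.3,
    delay: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[RawCapnoTrace, np.ndarray, np.ndarray]:
    """Breathing-shaped expired-CO2 waveform for the BH protocol.

    Each breath is a sin^2 bump peaking at the programmed end-tidal value at
    the expiration time; the waveform is ~0 during apnea and inspiration.
    ``delay`` shifts the recorded trace later (sampling-line transit).

    Returns (trace, anchor_times, anchor_values) where the anchors are the
    programmed end-tidal schedule (the generator's ground-truth envelope).
    """
    rng = np.random.default_rng(seed)
    fs = protocol.capno_sampling_rate
    tb = protocol.breath_period
    duration = protocol.total_duration + delay + tb
    n = int(np.ceil(duration * fs)) + 1
    t = np.arange(n) / fs
    t_true = t - delay  # time at the nose for the value recorded at t

    anchor_t, anchor_v = expiration_schedule(protocol, rest, rise, tau)
    wave = np.zeros(n)
    for tc, v in zip(anchor_t, anchor_v):
        lo, hi = tc - tb / 2, tc + tb / 2
        sel = (t_true >= lo) & (t_true < hi)
        phase = (t_true[sel] - lo) / tb
        wave[sel] = v * np.sin(np.pi * phase) ** 2
    wave += rng.normal(0.0, noise_sd, size=n)
    np.clip(wave, 0.0, None, out=wave)
    trace = RawCapnoTrace(
        sampling_interval=1.0 / fs, values=wave, acquisition_delay=delay
    )
    return trace, anchor_t, anchor_v


# ---------------------------------------------------------------------------
# hemodynamic forward model


def gen_cbf_response(
    petco2_envelope: np.ndarray,
    cvr_asl_true: float | np.ndarray,
    lag_true: float | np.ndarray = 0.0,
    smoothing_tau: float = 0.0,
    tr: float = 5.0,
    envelope_times: np.ndarray | None = None,
) -> np.ndarray:
    """Fractional CBF time course f(t) = 1 + (CVR/100) * dPetCO2(t - lag).

    ``petco2_envelope`` is the PetCO2 change from rest (mmHg) at the TR
    grid; the lagged value is linearly interpolated (edges held).  With
    smoothing_tau > 0 the response is additionally convolved with a
    first-order exponential kernel (default 0 keeps recovery exact).
    Broadcasting: scalar cvr/lag give a single series; arrays of shape S
    give an (..., n_frames) stack.
    """
    env = np.asarray(petco2_envelope, dtype=float)
    t = (
        np.arange(env.size) * tr
        if envelope_times is None
        else np.asarray(envelope_times, float)
    )
    cvr = np.atleast_1d(np.asarray(cvr_asl_true, dtype=float))
    lag = np.broadcast_to(
        np.atleast_1d(np.asarray(lag_true, dtype=float)), cvr.shape
    )
    shape = cvr.shape
    cvr_f, lag_f = cvr.ravel(), lag.ravel()
    dp = {l: np.interp(t - l, t, env) for l in np.unique(lag_f)}
    out = np.empty((cvr_f.size, env.size))
    for i, (c, l) in enumerate(zip(cvr_f, lag_f)):
        out[i] = 1.0 + (c / 100.0) * dp[l]
    if smoothing_tau > 0:
        a = np.exp(-tr / smoothing_tau)
        for i in range(out.shape[0]):
            y = out[i] - 1.0
            for j in range(1, y.size):
                y[j] = a * y[j - 1] + (1 - a) * y[j]
            out[i] = 1.0 + y
    out = out.reshape(shape + (env.size,))
    return out[0] if np.isscalar(cvr_asl_true) and np.isscalar(lag_true) else out


def _drift(n_frames: int, shape: tuple, amplitude: float, rng) -> np.ndarray:
    """Per-voxel order-2 Legendre drift (raw signal units)."""
    u = np.linspace(-1.0, 1.0, n_frames)
    p1, p2 = u, 0.5 * (3 * u**2 - 1)
    c1 = rng.normal(0.0, amplitude, size=shape)
    c2 = rng.normal(0.0, amplitude, size=shape)
    return c1[..., None] * p1 + c2[..., None] * p2


def gen_interleaved_asl(
    f: np.ndarray,
    protocol: ProtocolSpec,
    truth: GroundTruth | None = None,
    seed: int | np.random.Generator = 0,
    frame_order: str = "tag_first",
) -> InterleavedSeries:
    """Interleaved tag/control ASL series from fractional CBF f (..., frame).

    control = s0 * (1 + drift + common BOLD-like mode); tag = control -
    s0 * perfusion_fraction * f; independent white noise on every frame.
    """
    p = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    f = np.asarray(f, dtype=float)
    shape, n = f.shape[:-1], f.shape[-1]
    labels = make_labels(n, frame_order)
    common = 1.0 + p.asl_common_bold * (f - 1.0)
    base = p.s0 * common + _drift(n, shape, p.drift_amplitude, rng)
    tag_sel = labels == "tag"
    s = base.copy()
    s[..., tag_sel] -= p.s0 * p.perfusion_fraction * f[..., tag_sel]
    s += rng.normal(0.0, p.noise_sd["asl"], size=s.shape)
    return InterleavedSeries(
        volumes=s, frame_labels=labels, tr=protocol.tr, weighting="asl"
    )


def gen_bold(
    f: np.ndarray,
    weighting: str,
    coupling: np.ndarray,
    protocol: ProtocolSpec,
    truth: GroundTruth | None = None,
    seed: int | np.random.Generator = 0,
    frame_order: str = "tag_first",
) -> InterleavedSeries:
    """GE or SE BOLD series with parity-alternating perfusion contamination.

    s = s0 * (1 + coupling * (f - 1) + parity * eps * f) + drift + noise,
    with eps = bold_contamination * perfusion_fraction and parity +1 on
    control frames, -1 on tag frames (what surround averaging removes).
    ``coupling`` is the per-voxel total coefficient
    c_micro * v_micro + c_macro * v_macro (% BOLD per %CBF, unitless).
    """
    if weighting not in ("ge", "se"):
        raise ValueError("weighting must be 'ge' or 'se'")
    p = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    f = np.asarray(f, dtype=float)
    shape, n = f.shape[:-1], f.shape[-1]
    labels = make_labels(n, frame_order)
    parity = np.where(labels == "control", 1.0, -1.0)
    eps = p.bold_contamination * p.perfusion_fraction
    b = np.asarray(coupling, dtype=float)[..., None] * (f - 1.0)
    s = p.s0 * (1.0 + b + parity * eps * f)
    s += _drift(n, shape, p.drift_amplitude, rng)
    s += rng.normal(0.0, p.noise_sd[weighting], size=s.shape)
    return InterleavedSeries(
        volumes=s, frame_labels=labels, tr=protocol.tr, weighting=weighting
    )


# ---------------------------------------------------------------------------
# cohort generation


def _subject_targets(p: GroundTruth, rng) -> tuple[float, float, float, float]:
    """Draw correlated subject-level true GM-mean CVRs.

    z: shared vasodilatory factor; w: venous (macrovascular) factor loading
    only on GE.  Marginals match the group distributions; the venous factor
    makes part of the GE variance independent of ASL.
    """
    z = rng.normal()
    w = rng.normal()
    e1, e2 = rng.normal(), rng.normal()
    asl = max(p.asl_mean + p.asl_sd * z, 1.0)
    res_ge = np.sqrt(max(1.0 - p.rho_ge**2 - p.tau_ge**2, 0.0))
    ge = max(p.ge_mean + p.ge_sd * (p.rho_ge * z + p.tau_ge * w + res_ge * e1), 0.02)
    res_se = np.sqrt(max(1.0 - p.rho_se**2, 0.0))
    se = max(p.se_mean + p.se_sd * (p.rho_se * z + res_se * e2), 0.01)
    return asl, ge, se, w


def _couplings(
    target: float,
    macro_share: float,
    wobble: float,
    asl_field: np.ndarray,
    v_micro: np.ndarray,
    v_macro: np.ndarray,
    gm: np.ndarray,
) -> tuple[float, float]:
    """Micro/macro coupling coefficients calibrated to a GM-mean BOLD CVR.

    The macro share of the coupling is modulated by the subject's venous
    factor (wobble), then both coefficients are scaled so the GM mean of
    (c_micro*v_micro + c_macro*v_macro) * CVR_ASL equals ``target`` exactly.
    """
    share = macro_share * max(0.1, 1.0 + wobble)
    share = share / (share + (1.0 - macro_share))
    m_mic = float(np.mean((v_micro * asl_field)[gm]))
    m_mac = float(np.mean((v_macro * asl_field)[gm]))
    c_micro = (1.0 - share) * target / m_mic
    c_macro = share * target / m_mac if m_mac > 0 else 0.0
    return c_micro, c_macro


def gen_cohort(
    n_subjects: int = 20,
    protocol: ProtocolSpec | None = None,
    truth: GroundTruth | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[SyntheticSubject], CohortTruth]:
    """Generate a cohort of synthetic subjects with full ground truth.

    All randomness derives from ``seed``; identical seeds give bit-identical
    cohorts.  Subject-level true GM-mean CVRs are drawn per
    `_subject_targets`; spatial fields share a common smooth pattern plus
    subject-specific voxel noise, renormalised so each subject's GM-mean
    true CVR equals the drawn target exactly.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = protocol or ProtocolSpec()
    p = truth or GroundTruth()
    rng = np.random.default_rng(seed)

    gm = default_gm_mask(p.grid_shape)
    roi_labels = default_roi_labels(gm, p.n_rois)
    venous = default_venous_density(p.n_rois)
    dens_max = max(venous.values())
    v_macro = np.zeros(p.grid_shape)
    for roi, d in venous.items():
        v_macro[roi_labels == roi] = p.v_macro_max * d / dens_max
    # uniform microvascular bed; the macro compartment varies by ROI
    v_micro = np.full(p.grid_shape, 1.0 - p.v_macro_max)

    pattern = gaussian_filter(rng.standard_normal(p.grid_shape), sigma=2.0)
    sd = pattern[gm].std()
    if sd > 0:
        pattern = 1.0 + p.pattern_sd * pattern / sd
    else:
        pattern = np.ones(p.grid_shape)
    pattern = np.clip(pattern, 0.2, None)
    pattern /= pattern[gm].mean()

    frame_t = np.arange(protocol.n_frames) * protocol.tr
    subjects = []
    truths = []
    for _ in range(n_subjects):
        asl_t, ge_t, se_t, w = _subject_targets(p, rng)
        rest = rng.normal(p.petco2_rest, p.petco2_rest_sd)
        mod = max(rng.normal(p.petco2_modulation, p.petco2_modulation_sd), 2.0)
        rise = RISE_PER_FILTERED_RANGE * mod

        raw, anchor_t, anchor_v = gen_capnography(
            protocol,
            rest=rest,
            rise=rise,
            tau=p.recovery_tau,
            noise_sd=p.capno_noise_sd,
            delay=p.capno_delay,
            seed=rng,
        )

        field = pattern * (1.0 + p.voxel_noise_sd * rng.standard_normal(p.grid_shape))
        field = np.clip(field, 0.1, None)
        asl_field = asl_t * field / field[gm].mean()
        lag_field = rng.choice(LAG_VALUES, p=LAG_PROBS, size=p.grid_shape)
        lag_field[~gm] = 0.0
        asl_full = np.where(gm, asl_field, 0.0)

        cm_ge, cM_ge = _couplings(
            ge_t, p.macro_share_ge, p.macro_subject_sd * w,
            asl_full, v_micro, v_macro, gm,
        )
        cm_se, cM_se = _couplings(
            se_t, p.macro_share_se, 0.0, asl_full, v_micro, v_macro, gm
        )
        coup_ge = cm_ge * v_micro + cM_ge * v_macro
        coup_se = cm_se * v_micro + cM_se * v_macro

        env = np.interp(frame_t, anchor_t, anchor_v) - rest
        f = gen_cbf_response(
            env, asl_full, lag_field, smoothing_tau=p.smoothing_tau, tr=protocol.tr
        )
        series = {
            "asl": gen_interleaved_asl(f, protocol, p, seed=rng),
            "ge": gen_bold(f, "ge", coup_ge, protocol, p, seed=rng),
            "se": gen_bold(f, "se", coup_se, protocol, p, seed=rng),
        }
        st = SubjectTruth(
            rest_level=rest,
            modulation_target=mod,
            rise=rise,
            capno_delay=p.capno_delay,
            anchor_times=anchor_t,
            anchor_values=anchor_v,
            cvr_asl_mean=asl_t,
            cvr_ge_mean=ge_t,
            cvr_se_mean=se_t,
            venous_factor=w,
            cvr_asl_true=asl_full,
            cvr_ge_true=coup_ge * asl_full,
            cvr_se_true=coup_se * asl_full,
            lag_true=lag_field,
            c_micro_ge=cm_ge,
            c_macro_ge=cM_ge,
            c_micro_se=cm_se,
            c_macro_se=cM_se,
        )
        subjects.append(SyntheticSubject(raw_capno=raw, series=series, truth=st))
        truths.append(st)

    cohort = CohortTruth(
        params=p,
        protocol=protocol,
        gm_mask=gm,
        roi_labels=roi_labels,
        venous_density=venous,
        v_macro=v_macro,
        pattern=pattern,
        subjects=truths,
    )
    return subjects, cohort
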