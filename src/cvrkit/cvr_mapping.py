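"""Voxelwise CVR estimation by lagged linear regression on PetCO2.

Each voxel's filtered fractional-change time course (in %) is regressed on
the filtered PetCO2 trace, which is allowed to shift within +-max_lag
seconds to absorb hemodynamic delay.  The lag maximising the coefficient of
determination is kept; the slope of that fit is the CVR (% signal per mmHg),
and beta divided by its standard error is the confidence z-score used for
voxel thresholding downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .capnography import FilterSpec, PetCO2Trace, bandpass_filter
from .signal_prep import FractionalChangeSeries, _surround_neighbor_mean

log = logging.getLogger(__name__)

Z_CAP = 1e6  # finite stand-in for z of numerically perfect fits


class DegenerateRegressorError(ValueError):
    """The (shifted) PetCO2 regressor has zero variance."""


@dataclass
class LagSearchSpec:
    """Lag grid for the shifted-regressor search.

    max_lag : bound on |lag|, seconds (default 10).
    step : grid step, seconds; the default equals the TR (integer-frame
        shifts); finer steps interpolate the trace linearly.
    """

    max_lag: float = 10.0
    step: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.step <= self.max_lag) and self.max_lag > 0:
            raise ValueError("require 0 <= step <= max_lag")

    def grid(self) -> np.ndarray:
        """Candidate lags in preference order: |lag| ascending, negative first."""
        if self.max_lag == 0 or self.step == 0:
            return np.array([0.0])
        n = int(np.floor(self.max_lag / self.step + 1e-9))
        lags = [0.0]
        for k in range(1, n + 1):
            lags += [-k * self.step, k * self.step]
        return np.asarray(lags)


@dataclass
class CVRMap:
    """Voxelwise CVR result for one fMRI weighting.

    beta : % signal per mmHg (for ASL, %CBF/mmHg); z : beta / SE(beta);
    lag : selected PetCO2 shift, seconds.  NaN marks unmasked/invalid voxels.
    """

    beta: np.ndarray
    z: np.ndarray
    lag: np.ndarray
    weighting: str
    se: np.ndarray | None = None


def shift_regressor(x: np.ndarray, frame_times: np.ndarray, lag: float) -> np.ndarray:
    """Regressor delayed by ``lag`` seconds: value at t - lag, edges held."""
    if lag == 0:
        return np.asarray(x, dtype=float)
    return np.interp(frame_times - lag, frame_times, x)


def apply_surround_stencil(
    x: np.ndarray, frame_labels: np.ndarray, weighting: str
) -> np.ndarray:
    """Surround-processing transfer of the tag/control pipeline, on a regressor.

    The surround operations act on the data as a temporal smoothing
    (transfer cos^2(pi f TR) on average), so a regressor built from the raw
    PetCO2 trace over-represents the stimulus' higher harmonics and the GLM
    slope is attenuated.  Passing the candidate regressor through the same
    operator ("process the design like the data") removes that bias:

    * ASL surround subtraction leaves tag frames as the instantaneous value
      and replaces control frames by the mean of their neighbours;
    * BOLD surround averaging applies the [1/4, 1/2, 1/4] kernel everywhere.

    Edge frames mirror the data path's single-neighbour fallback.
    """
    x = np.asarray(x, dtype=float)
    if weighting in ("ge", "se"):
        return 0.5 * (x + _surround_neighbor_mean(x))
    if weighting != "asl":
        raise ValueError(f"unknown weighting {weighting!r}")
    # emulate surround subtraction of tag frames carrying -x
    s = np.where(np.asarray(frame_labels) == "tag", -x, 0.0)
    sign = np.where(np.asarray(frame_labels) == "control", 1.0, -1.0)
    return sign * (s - _surround_neighbor_mean(s))


def build_regressor_bank(
    x_unfiltered: np.ndarray,
    frame_times: np.ndarray,
    lags: np.ndarray,
    weighting: str | None = None,
    frame_labels: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
) -> dict[float, np.ndarray]:
    """Per-lag design-matched regressors: shift -> surround stencil -> filter.

    With ``weighting`` None the stencil step is skipped (plain lagged
    regressor, filtered only).
    """
    tr = float(frame_times[1] - frame_times[0])
    spec = filter_spec or FilterSpec()
    bank = {}
    for lag in np.atleast_1d(lags):
        xs = shift_regressor(x_unfiltered, frame_times, float(lag))
        if weighting is not None:
            if weighting in ("ge", "se"):
                xs = apply_surround_stencil(xs, None, weighting)
            else:
                if frame_labels is None:
                    raise ValueError("ASL stencil matching requires frame_labels")
                xs = apply_surround_stencil(xs, frame_labels, weighting)
        bank[float(lag)] = bandpass_filter(xs, spec, tr)
    return bank


def _ols_stats(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Slope, SE and R^2 of Y (n_series, n) on [1, x], vectorised."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise DegenerateRegressorError("degenerate regressor: zero variance")
    Yc = Y - Y.mean(axis=-1, keepdims=True)
    beta = Yc @ xc / sxx
    syy = np.einsum("ij,ij->i", Yc, Yc)
    rss = np.maximum(syy - beta**2 * sxx, 0.0)
    dof = n - 2
    se = np.sqrt(rss / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, 1.0 - rss / syy, 0.0)
    return beta, se, r2, syy


def fit_lagged_glm(
    y: np.ndarray,
    x: PetCO2Trace | np.ndarray,
    spec: LagSearchSpec | None = None,
    tr: float = 5.0,
) -> tuple[float, float, float, float]:
    """Lag-optimised OLS of one voxel time course on the PetCO2 trace.

    Returns (beta %/mmHg, se, z, lag s).  The lag grid is scanned in
    preference order (|lag| ascending, negative before positive at equal
    magnitude) and a candidate replaces the incumbent only on strictly
    larger R^2, which realises the tie-break toward small/negative lags.
    A zero-variance voxel returns (0, 0, 0, 0).
    """
    reg = LaggedCVRRegressor(lag_search=spec or LagSearchSpec(), tr=tr)
    if isinstance(x, PetCO2Trace):
        reg.fit(x.values, np.asarray(y, float)[None, :], frame_times=x.frame_times)
    else:
        reg.fit(np.asarray(x, float), np.asarray(y, float)[None, :])
    return (
        float(reg.beta_[0]),
        float(reg.se_[0]),
        float(reg.z_[0]),
        float(reg.lag_[0]),
    )


class LaggedCVRRegressor(BaseEstimator, RegressorMixin):
    """Mass-univariate lagged GLM: many voxels against one PetCO2 regressor.

    ``fit(x, Y)`` takes the filtered PetCO2 values ``x`` (n_frames,) and
    voxel time courses ``Y`` (n_voxels, n_frames) in percent signal change.
    Fitted attributes (per voxel): ``beta_`` (%/mmHg), ``se_``, ``z_``
    (beta/SE, capped at 1e6), ``lag_`` (s), ``r2_``, ``intercept_``.

    The regression includes an intercept even though both series are
    high-pass filtered (guards against residual DC from edge effects); no
    prewhitening is applied.
    """

    def __init__(self, lag_search: LagSearchSpec | None = None, tr: float = 5.0):
        self.lag_search = lag_search
        self.tr = tr

    def fit(
        self,
        x: np.ndarray,
        Y: np.ndarray,
        frame_times: np.ndarray | None = None,
        regressor_bank: dict[float, np.ndarray] | None = None,
    ):
        x = np.asarray(x, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[None, :]
        if x.ndim != 1 or Y.shape[-1] != x.size:
            raise ValueError("x must be 1D with length matching Y's frame axis")
        if x.size < 10:
            raise ValueError("need at least 10 frames")
        t = frame_times if frame_times is not None else np.arange(x.size) * self.tr
        spec = self.lag_search or LagSearchSpec()

        n_vox = Y.shape[0]
        finite = np.all(np.isfinite(Y), axis=-1)
        nonzero = finite & (np.ptp(Y, axis=-1) > 0)

        best_beta = np.zeros(n_vox)
        best_se = np.zeros(n_vox)
        best_r2 = np.full(n_vox, -np.inf)
        best_lag = np.zeros(n_vox)
        Yv = Y[nonzero]
        if Yv.size:
            bb = np.zeros(Yv.shape[0])
            bs = np.zeros(Yv.shape[0])
            br = np.full(Yv.shape[0], -np.inf)
            bl = np.zeros(Yv.shape[0])
            for lag in spec.grid():
                if regressor_bank is not None:
                    xs = regressor_bank[float(lag)]
                else:
                    xs = shift_regressor(x, t, lag)
                beta, se, r2, _ = _ols_stats(xs, Yv)
                better = r2 > br
                bb[better], bs[better], bl[better] = beta[better], se[better], lag
                br[better] = r2[better]
            best_beta[nonzero], best_se[nonzero] = bb, bs
            best_r2[nonzero], best_lag[nonzero] = br, bl
        best_r2[~nonzero & finite] = 0.0

        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(best_se > 0, best_beta / best_se, 0.0)
        # numerically exact fits: se == 0 but beta != 0
        exact = (best_se == 0) & (best_beta != 0)
        z[exact] = np.sign(best_beta[exact]) * Z_CAP
        z = np.clip(z, -Z_CAP, Z_CAP)

        nanmask = ~finite
        for arr in (best_beta, best_se, best_lag, z, best_r2):
            arr[nanmask] = np.nan

        n_boundary = int(np.sum(np.abs(best_lag[finite]) >= spec.max_lag - 1e-9))
        if spec.max_lag > 0 and n_boundary:
            log.info(
                "lag search: %d/%d voxel(s) selected a boundary lag (+-%g s)",
                n_boundary,
                int(finite.sum()),
                spec.max_lag,
            )
        self.n_lag_boundary_ = n_boundary
        self.beta_, self.se_, self.z_, self.lag_, self.r2_ = (
            best_beta,
            best_se,
            z,
            best_lag,
            best_r2,
        )
        self.x_, self.frame_times_ = x, t
        self.regressor_bank_ = regressor_bank

        def _reg(lag: float) -> np.ndarray:
            if regressor_bank is not None:
                return regressor_bank[float(lag)]
            return shift_regressor(x, t, lag)

        ybar = np.full(n_vox, np.nan)
        ybar[finite] = Y[finite].mean(axis=-1)
        xbar = np.array(
            [_reg(l).mean() if np.isfinite(l) else np.nan for l in best_lag]
        )
        self.intercept_ = ybar - best_beta * xbar
        return self

    def predict(self, x: np.ndarray | None = None) -> np.ndarray:
        """Fitted voxel time courses from the selected lag and slope."""
        out = np.empty((self.beta_.size, self.x_.size))
        for i, (b, a, l) in enumerate(zip(self.beta_, self.intercept_, self.lag_)):
            if not np.isfinite(b):
                out[i] = np.nan
            elif self.regressor_bank_ is not None and x is None:
                out[i] = a + b * self.regressor_bank_[float(l)]
            else:
                xv = self.x_ if x is None else np.asarray(x, float)
                out[i] = a + b * shift_regressor(xv, self.frame_times_, l)
        return out


def map_cvr(
    fc: FractionalChangeSeries,
    x: PetCO2Trace,
    spec: LagSearchSpec | None = None,
    mask: np.ndarray | None = None,
    x_unfiltered: np.ndarray | None = None,
    frame_labels: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
) -> CVRMap:
    """Apply the lagged GLM to every masked voxel of a prepared series.

    The fractional-change volumes are scaled to percent before regression so
    beta carries % signal per mmHg.  Voxels outside the mask (or with
    non-finite time courses) are NaN.

    When ``x_unfiltered`` is supplied (the PetCO2 trace resampled at frame
    times but not yet filtered), the candidate regressors are design-matched
    to the data path: shifted, passed through the weighting's surround
    stencil (ASL needs ``frame_labels``) and band-pass filtered, which
    removes the stencil's attenuation bias on beta (see
    `apply_surround_stencil`).  Otherwise the pre-filtered ``x`` is shifted
    directly.
    """
    vols = fc.volumes
    shape = vols.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {shape}")
    if not mask.any():
        raise ValueError("empty mask")
    Y = vols[mask] * 100.0
    search = spec or LagSearchSpec()
    bank = None
    if x_unfiltered is not None:
        bank = build_regressor_bank(
            x_unfiltered,
            x.frame_times,
            search.grid(),
            weighting=fc.weighting,
            frame_labels=frame_labels,
            filter_spec=filter_spec,
        )
    reg = LaggedCVRRegressor(lag_search=search)
    reg.fit(x.values, Y, frame_times=x.frame_times, regressor_bank=bank)

    def _full(v: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[mask] = v
        return out

    return CVRMap(
        beta=_full(reg.beta_),
        z=_full(reg.z_),
        lag=_full(reg.lag_),
        weighting=fc.weighting,
        se=_full(reg.se_),
    )
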