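"""Intensity autocorrelation, FCS model fits, and the
subpopulation-selective FCS (pscFCS) threshold sweep.

The autocorrelation G(t) = <I(0)I(t)> / <I>^2 of a fluorescence
intensity trace decays on the timescale of molecular transits through
the confocal focus. A two-dimensional diffusion model

    G(t) = 1 + G0 / (1 + t/tau_app)

is fitted between 10 us and 1 s; ``G0`` is the inverse mean number of
molecules in the focus and ``tau_app`` the apparent diffusion time. An
optional exponential relaxation factor (1 + A exp(-t/t_R)) handles fast
photophysics (the 2D1R model).

pscFCS correlates only the trace segments assigned to one smFRET
subpopulation: bursts are detected at a peak threshold on the
millisecond-binned trace, the selection windows are mapped back to the
microsecond acquisition binning, everything outside them is replaced by
synthetic Poisson background, and the donor+acceptor sum of the masked
trace is correlated. The peak threshold biases tau_app upward; sweeping
the threshold x and fitting the empirical law

    tau_app = tau + a x^2

extrapolates to the unbiased diffusion time tau at zero threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import lmfit

from .exceptions import (
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidArgumentError,
)
from . import trace as trace_mod
from .trace import BackgroundModel, BinnedTrace, Burst

__all__ = [
    "CorrelationCurve",
    "FcsFit",
    "ThresholdSweep",
    "autocorrelate",
    "autocorrelate_bruteforce",
    "fit_fcs_model",
    "pscfcs_apparent_tau",
    "unbiased_tau",
    "pscfcs_sweep",
]

DEFAULT_FIT_WINDOW = (10e-6, 1.0)
DEFAULT_POINTS_PER_STAGE = 16


@dataclass(frozen=True)
class CorrelationCurve:
    """Lag times (s, strictly increasing) and correlation values
    normalized by the squared mean intensity, so an uncorrelated trace
    gives G = 1."""

    lags: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if len(lags) != len(g):
            raise InvalidArgumentError("lags and g must have equal length")
        if np.any(np.diff(lags) <= 0) or (lags.size and lags[0] <= 0):
            raise InvalidArgumentError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(g)):
            raise InvalidArgumentError("g must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)

    def window(self, t_min: float, t_max: float) -> "CorrelationCurve":
        sel = (self.lags >= t_min) & (self.lags <= t_max)
        return CorrelationCurve(self.lags[sel], self.g[sel])


@dataclass(frozen=True)
class FcsFit:
    """Fitted FCS model parameters. ``relaxation_amplitude`` and
    ``relaxation_time`` are present only for the 2D1R model."""

    g0: float
    tau_app: float
    fit_window: tuple[float, float]
    residual_norm: float
    relaxation_amplitude: float | None = None
    relaxation_time: float | None = None
    stderr_tau: float | None = None

    def __post_init__(self):
        if self.tau_app <= 0:
            raise InvalidArgumentError("tau_app must be > 0")
        if (self.relaxation_amplitude is None) != (self.relaxation_time is None):
            raise InvalidArgumentError("relaxation amplitude and time go together")


@dataclass(frozen=True)
class ThresholdSweep:
    """Result of the pscFCS peak-threshold sweep: per-threshold apparent
    diffusion times, the quadratic-extrapolation intercept ``tau`` (the
    unbiased diffusion time) and curvature ``a``."""

    thresholds: np.ndarray
    tau_apps: np.ndarray
    tau: float
    curvature: float
    residuals: np.ndarray
    tau_stderr: float | None = None

    def __post_init__(self):
        x = np.asarray(self.thresholds, float)
        t = np.asarray(self.tau_apps, float)
        if np.any(np.diff(x) <= 0):
            raise InvalidArgumentError("thresholds must be strictly increasing")
        if np.any(t <= 0):
            raise InvalidArgumentError("tau_apps must be > 0")
        if self.tau <= 0:
            raise InvalidArgumentError("unbiased tau must be > 0")
        object.__setattr__(self, "thresholds", x)
        object.__setattr__(self, "tau_apps", t)


# ---------------------------------------------------------------------------
# correlators


def _intensity_from(trace_sum, bin_width=None):
    if isinstance(trace_sum, BinnedTrace):
        return trace_sum.channel_sum().astype(float), trace_sum.bin_width
    if bin_width is None:
        raise InvalidArgumentError("bin_width required when passing a raw array")
    return np.asarray(trace_sum, dtype=float), float(bin_width)


def autocorrelate(
    trace_sum,
    max_lag: float,
    bin_width: float | None = None,
    points_per_stage: int = DEFAULT_POINTS_PER_STAGE,
) -> CorrelationCurve:
    """Multi-tau autocorrelation on a quasi-logarithmic lag grid.

    ``trace_sum`` is either a :class:`BinnedTrace` (channels are summed)
    or a 1-D intensity array with ``bin_width`` given. The first stage
    evaluates lags of 1..m bins directly; each further stage halves the
    time resolution by pairwise rebinning and evaluates lags m/2+1..m in
    the coarsened units, the standard multi-tau cascade. Within a stage
    the estimator equals the direct sum
    sum_i I(i) I(i+k) / (N-k) / <I>^2 on the (rebinned) trace.
    """
    x, width = _intensity_from(trace_sum, bin_width)
    if len(x) < 2:
        raise DegenerateInputError("trace must have at least 2 bins")
    if x.mean() == 0:
        raise DegenerateInputError("zero-mean trace has no defined correlation")
    if max_lag >= len(x) * width:
        raise InvalidArgumentError("max_lag must be shorter than the trace")
    m = points_per_stage
    lags, gs = [], []
    cur = x
    level = 0
    while True:
        mean_sq = cur.mean() ** 2
        k_range = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        done = False
        for k in k_range:
            lag = k * width
            if lag > max_lag or k >= len(cur):
                done = True
                break
            n = len(cur) - k
            num = float(np.dot(cur[:n], cur[k:])) / n
            lags.append(lag)
            gs.append(num / mean_sq)
        if done or len(cur) < 2 * m:
            break
        cur = cur[: (len(cur) // 2) * 2].reshape(-1, 2).sum(axis=1)
        width *= 2
        level += 1
    return CorrelationCurve(np.array(lags), np.array(gs))


def autocorrelate_bruteforce(
    trace_sum, max_lag: float, bin_width: float | None = None
) -> CorrelationCurve:
    """Direct O(N^2) estimator sum_i I(i)I(i+k) / (N-k) / <I>^2 at every
    integer lag up to ``max_lag``. Reference implementation for small
    traces; written as an explicit per-lag loop, independent of the
    multi-tau cascade."""
    x, width = _intensity_from(trace_sum, bin_width)
    if x.mean() == 0:
        raise DegenerateInputError("zero-mean trace has no defined correlation")
    mean_sq = x.mean() ** 2
    k_max = min(int(np.floor(max_lag / width)), len(x) - 1)
    lags, gs = [], []
    for k in range(1, k_max + 1):
        acc = 0.0
        for i in range(len(x) - k):
            acc += x[i] * x[i + k]
        lags.append(k * width)
        gs.append(acc / (len(x) - k) / mean_sq)
    return CorrelationCurve(np.array(lags), np.array(gs))


# ---------------------------------------------------------------------------
# model fits


def _model_2d(t, g0, tau):
    return 1.0 + g0 / (1.0 + t / tau)


def _model_2d1r(t, g0, tau, a_rel, t_rel):
    return 1.0 + g0 / (1.0 + t / tau) * (1.0 + a_rel * np.exp(-t / t_rel))


def fit_fcs_model(
    curve: CorrelationCurve,
    model: str = "2D",
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> FcsFit:
    """Unweighted least-squares fit of the 2D or 2D1R diffusion model
    over ``fit_window`` (default 10 us to 1 s)."""
    if model not in ("2D", "2D1R"):
        raise InvalidArgumentError(f"unknown model {model!r}")
    sub = curve.window(*fit_window)
    n_par = 2 if model == "2D" else 4
    if len(sub.lags) < n_par + 1:
        raise InsufficientDataError("correlation curve does not cover the fit window")
    t, g = sub.lags, sub.g
    g0_init = max(float(g.max() - 1.0), 1e-6)
    # crude half-decay initialization for tau
    half = 1.0 + g0_init / 2
    below = np.nonzero(g < half)[0]
    tau_init = float(t[below[0]]) if below.size else float(np.median(t))
    params = lmfit.Parameters()
    params.add("g0", value=g0_init, min=0)
    params.add("tau", value=tau_init, min=t[0] * 1e-3, max=t[-1] * 1e3)
    if model == "2D1R":
        params.add("a_rel", value=0.1, min=0)
        params.add("t_rel", value=tau_init / 10, min=t[0] * 1e-4, max=t[-1])

    def residual(p):
        v = p.valuesdict()
        if model == "2D":
            return _model_2d(t, v["g0"], v["tau"]) - g
        return _model_2d1r(t, v["g0"], v["tau"], v["a_rel"], v["t_rel"]) - g

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success or not np.isfinite(result.params["tau"].value):
        raise FitFailureError(
            f"FCS fit did not converge: {result.message}",
            best_values=dict(result.params.valuesdict()),
            residual_norm=float(np.linalg.norm(result.residual)),
        )
    v = result.params.valuesdict()
    stderr = result.params["tau"].stderr
    return FcsFit(
        g0=v["g0"],
        tau_app=v["tau"],
        fit_window=fit_window,
        residual_norm=float(np.linalg.norm(result.residual)),
        relaxation_amplitude=v.get("a_rel"),
        relaxation_time=v.get("t_rel"),
        stderr_tau=float(stderr) if stderr is not None else None,
    )


# ---------------------------------------------------------------------------
# pscFCS pipeline


def pscfcs_apparent_tau(
    trace_fine: BinnedTrace,
    windows,
    background: BackgroundModel,
    threshold_used: float,
    seed: int,
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    max_lag: float | None = None,
) -> FcsFit:
    """Apparent diffusion time of one subpopulation at one threshold.

    ``windows`` are kept (start, end) bin windows on the fine trace (or
    Burst objects on the fine binning), typically a FRET-windowed burst
    selection mapped down from the millisecond binning. Everything else
    is replaced by Poisson background at ``background`` rates (in counts
    per fine bin); the donor+acceptor sum is correlated and the 2D model
    fitted.
    """
    windows = list(windows)
    if not windows:
        raise DegenerateInputError("empty selection: no windows to keep")
    masked = trace_mod.poisson_masked_trace(trace_fine, windows, background, seed)
    if max_lag is None:
        max_lag = min(fit_window[1] * 1.1, masked.duration / 2)
    curve = autocorrelate(masked, max_lag=max_lag)
    return fit_fcs_model(curve, model="2D", fit_window=fit_window)


def unbiased_tau(sweep_points: Iterable[tuple[float, float]]) -> ThresholdSweep:
    """Extrapolate apparent diffusion times to zero threshold.

    Fits tau_app = tau + a x^2 by linear least squares in the basis
    (1, x^2); the intercept tau is the unbiased diffusion time. Requires
    at least 3 distinct thresholds.
    """
    pts = sorted(set((float(x), float(t)) for x, t in sweep_points))
    xs = np.array([p[0] for p in pts])
    ts = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 3:
        raise InsufficientDataError("need >= 3 distinct thresholds for the extrapolation")
    design = np.column_stack([np.ones_like(xs), xs**2])
    coef, *_ = np.linalg.lstsq(design, ts, rcond=None)
    tau, a = float(coef[0]), float(coef[1])
    if tau <= 0:
        raise FitFailureError(
            f"extrapolated tau is non-positive ({tau:.3g} s)",
            best_values={"tau": tau, "a": a},
        )
    pred = design @ coef
    resid = ts - pred
    dof = len(xs) - 2
    tau_stderr = None
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        tau_stderr = float(np.sqrt(cov[0, 0]))
    return ThresholdSweep(
        thresholds=xs, tau_apps=ts, tau=tau, curvature=a, residuals=resid, tau_stderr=tau_stderr
    )


def pscfcs_sweep(
    trace_fine: BinnedTrace,
    e_window: tuple[float, float],
    thresholds: Sequence[float],
    seed: int,
    coarse_bin_width: float = 1e-3,
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> ThresholdSweep:
    """Full pscFCS pipeline: per threshold, detect bursts on the
    millisecond binning, select the efficiency window (background-
    corrected E_app), map to the fine binning, Poisson-mask, correlate
    and fit; then extrapolate tau_app = tau + a x^2 to zero threshold.

    Bursts are re-detected at every threshold. ``thresholds`` are counts
    per coarse bin on the summed channels. The seed fixes the Poisson
    replacement streams (one sub-stream per threshold).
    """
    from . import smfret

    thresholds = sorted(float(x) for x in thresholds)
    if len(thresholds) < 3:
        raise InsufficientDataError("need >= 3 thresholds for the sweep")
    factor = max(1, int(round(coarse_bin_width / trace_fine.bin_width)))
    coarse = trace_mod.rebin(trace_fine, factor)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(thresholds))]
    points = []
    for thr, sub_seed in zip(thresholds, child_seeds):
        bursts = trace_mod.detect_bursts(coarse, thr)
        if not bursts:
            raise DegenerateInputError(f"no bursts at threshold {thr}")
        background = trace_mod.estimate_background(coarse, bursts)
        corrected = trace_mod.background_corrected_efficiency(bursts, background)
        selected = smfret.select_by_efficiency(corrected, *e_window)
        if not selected:
            raise DegenerateInputError(
                f"no bursts in efficiency window {e_window} at threshold {thr}"
            )
        windows = trace_mod.burst_windows_to_fine(selected, factor, n_fine=len(trace_fine))
        fine_bg = background.scaled(1.0 / factor)
        fit = pscfcs_apparent_tau(
            trace_fine, windows, fine_bg, thr, sub_seed, fit_window=fit_window
        )
        points.append((thr, fit.tau_app))
    return unbiased_tau(points)
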