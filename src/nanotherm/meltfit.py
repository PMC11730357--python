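"""Two-state melting-curve analysis for label-free DSF fluorescence traces.

A thermal ramp of intrinsic fluorescence (330 nm and 350 nm channels) through
an unfolding transition is modeled as a two-state equilibrium with linear
native and denatured baselines:

    y(T) = [a_N + b_N*T + (a_D + b_D*T) * E(T)] / [1 + E(T)]
    E(T) = exp( (dH/R) * (1/T_M - 1/T) )

where a/b are baseline intercepts and slopes, T_M the apparent melting
temperature and dH/R the effective van 't Hoff enthalpy over the gas
constant. Following the labeling protocol this package reproduces, the model
is evaluated directly on Celsius temperatures (initial guesses T_M = 65 degC,
dH/R = 3000 degC), so dH/R is an effective, not thermodynamic, parameter; a
Kelvin mode is available via ``FitConfig.kelvin``.

The per-sample analysis is: fit the 350/330 ratio over the full span to get a
first-pass T_M; baseline-correct each individual channel by its own full-trace
linear regression; refit each channel inside a window around the first-pass
T_M; report the mean of the conclusive channel fits, falling back to the ratio
fit when neither channel passes quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.signal import savgol_filter

from .exceptions import ContractError

_KELVIN_OFFSET = 273.15


@dataclass
class MeltCurve:
    """One thermal-ramp fluorescence trace (both channels)."""

    temperatures: np.ndarray
    f330: np.ndarray
    f350: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        n = self.temperatures.size
        if n < 20:
            raise ContractError(f"trace has {n} points; need >= 20")
        if self.f330.size != n or self.f350.size != n:
            raise ContractError("channel vectors must match temperature length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ContractError("temperatures must be strictly increasing")

    @property
    def ratio(self) -> np.ndarray:
        """350/330 ratio; defined only where f330 != 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.f330 != 0, self.f350 / self.f330, np.nan)


@dataclass
class FitConfig:
    """Tunable parameters of the melting-curve analysis.

    ``refit_halfwidth`` bounds the per-channel refit window around the
    first-pass ratio T_M. Two-state transitions with an effective Celsius
    dH/R near 3000 are 7-10 degC wide, and the six-parameter fit becomes
    ill-conditioned when the window clips the transition, so the default
    keeps data within 10 degC of the first-pass midpoint (a tighter
    half-window is a valid configuration for sharp transitions).
    """

    smooth_window: int = 21
    smooth_order: int = 2
    init_tm: float = 65.0
    init_dh_over_r: float = 3000.0
    refit_halfwidth: float = 10.0
    baseline_fraction: float = 0.1
    amplitude_snr_min: float = 3.0       # transition amplitude >= 3x residual sd
    rss_improvement_min: float = 0.5     # >= 50% rss drop vs baselines-only fit
    kelvin: bool = False

    def __post_init__(self) -> None:
        if self.smooth_order >= self.smooth_window:
            raise ContractError("smooth_order must be < smooth_window")
        if self.refit_halfwidth <= 0:
            raise ContractError("refit_halfwidth must be > 0")


@dataclass
class TwoStateFit:
    alpha_n: float
    beta_n: float
    alpha_d: float
    beta_d: float
    dh_over_r: float
    tm: float
    rss: float
    converged: bool
    channel: str = "ratio"

    @property
    def amplitude(self) -> float:
        """Baseline separation at the midpoint (transition amplitude)."""
        return abs((self.alpha_d + self.beta_d * self.tm)
                   - (self.alpha_n + self.beta_n * self.tm))


def two_state_signal(
    T: np.ndarray,
    alpha_n: float, beta_n: float,
    alpha_d: float, beta_d: float,
    dh_over_r: float, tm: float,
    kelvin: bool = False,
) -> np.ndarray:
    """Forward evaluation of the two-state model."""
    T = np.asarray(T, dtype=float)
    Tk = T + _KELVIN_OFFSET if kelvin else T
    tmk = tm + _KELVIN_OFFSET if kelvin else tm
    x = dh_over_r * (1.0 / tmk - 1.0 / Tk)
    e = np.exp(np.clip(x, -500, 500))
    return (alpha_n + beta_n * T + (alpha_d + beta_d * T) * e) / (1.0 + e)


def smooth_trace(signal: np.ndarray, cfg: FitConfig | None = None) -> np.ndarray:
    """Savitzky-Golay smoothing (polynomial edge interpolation)."""
    cfg = cfg or FitConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.size < cfg.smooth_window:
        raise ContractError(
            f"trace of {signal.size} points shorter than the smoothing "
            f"window ({cfg.smooth_window})")
    return savgol_filter(signal, cfg.smooth_window, cfg.smooth_order,
                         mode="interp")


def _baseline_guesses(T: np.ndarray, y: np.ndarray,
                      fraction: float) -> tuple[float, float, float, float]:
    n = T.size
    m = max(3, int(round(fraction * n)))
    lo = stats.linregress(T[:m], y[:m])
    hi = stats.linregress(T[-m:], y[-m:])
    return lo.intercept, lo.slope, hi.intercept, hi.slope


def fit_two_state(
    temperatures: np.ndarray,
    signal: np.ndarray,
    cfg: FitConfig | None = None,
    window: tuple[float, float] | None = None,
    channel: str = "ratio",
) -> TwoStateFit:
    """Least-squares fit of the two-state model to one trace.

    ``window`` restricts the fit to a Celsius interval (at least 10 points
    must remain). Non-convergence never raises: the best-effort parameters
    are returned with ``converged=False``.
    """
    cfg = cfg or FitConfig()
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(signal, dtype=float)
    if window is not None:
        mask = (T >= window[0]) & (T <= window[1])
        T, y = T[mask], y[mask]
    if T.size < 10:
        raise ContractError(f"only {T.size} points inside the fit window; "
                            "need >= 10")

    a_n, b_n, a_d, b_d = _baseline_guesses(T, y, cfg.baseline_fraction)
    init_tm = cfg.init_tm
    if not (T[0] < init_tm < T[-1]):
        init_tm = float(0.5 * (T[0] + T[-1]))
    x0 = np.array([a_n, b_n, a_d, b_d, cfg.init_dh_over_r, init_tm])

    def residuals(p: np.ndarray) -> np.ndarray:
        return two_state_signal(T, *p, kelvin=cfg.kelvin) - y

    span = T[-1] - T[0]
    lower = [-np.inf, -np.inf, -np.inf, -np.inf, 1e-6, T[0] - span]
    upper = [np.inf, np.inf, np.inf, np.inf, np.inf, T[-1] + span]
    try:
        res = optimize.least_squares(residuals, x0, bounds=(lower, upper),
                                     method="trf", max_nfev=5000)
        p = res.x
        rss = float(2.0 * res.cost)
        ok = bool(res.success)
    except Exception:                            # optimizer blow-up
        p, rss, ok = x0, float(np.sum(residuals(x0) ** 2)), False
    tm = float(p[5])
    converged = ok and (T[0] < tm < T[-1])
    return TwoStateFit(
        alpha_n=float(p[0]), beta_n=float(p[1]),
        alpha_d=float(p[2]), beta_d=float(p[3]),
        dh_over_r=float(p[4]), tm=tm, rss=rss,
        converged=converged, channel=channel,
    )


def _linear_rss(T: np.ndarray, y: np.ndarray) -> float:
    fit = stats.linregress(T, y)
    return float(np.sum((y - (fit.intercept + fit.slope * T)) ** 2))


def _is_conclusive(fit: TwoStateFit, T: np.ndarray, y: np.ndarray,
                   window: tuple[float, float], cfg: FitConfig) -> bool:
    """QC gate replacing visual inspection of each channel fit."""
    if not fit.converged:
        return False
    if not (window[0] < fit.tm < window[1]):
        return False
    n_inside = int(np.sum((T >= window[0]) & (T <= window[1])))
    dof = max(n_inside - 6, 1)
    residual_sd = float(np.sqrt(fit.rss / dof))
    if fit.amplitude < cfg.amplitude_snr_min * residual_sd:
        return False
    mask = (T >= window[0]) & (T <= window[1])
    rss_lin = _linear_rss(T[mask], y[mask])
    if rss_lin <= 0:
        return False
    return (1.0 - fit.rss / rss_lin) >= cfg.rss_improvement_min


@dataclass
class CurveAnalysis:
    """Result of the full ratio-then-windowed-channel analysis of one trace."""

    tm: float | None
    provenance: str                      # individual_channels | ratio_fallback | unfittable
    ratio_fit: TwoStateFit
    channel_fits: dict[str, TwoStateFit] = field(default_factory=dict)
    conclusive: dict[str, bool] = field(default_factory=dict)
    sample_id: str = ""
    replicate_id: str = ""


def analyze_nanodsf_curve(curve: MeltCurve,
                          cfg: FitConfig | None = None) -> CurveAnalysis:
    """Extract one apparent melting temperature from a two-channel trace."""
    cfg = cfg or FitConfig()
    T = curve.temperatures

    ratio = smooth_trace(curve.ratio, cfg)
    ratio_fit = fit_two_state(T, ratio, cfg, channel="ratio")
    if not ratio_fit.converged:
        return CurveAnalysis(tm=None, provenance="unfittable",
                             ratio_fit=ratio_fit,
                             sample_id=curve.sample_id,
                             replicate_id=curve.replicate_id)
    tm0 = ratio_fit.tm
    window = (tm0 - cfg.refit_halfwidth, tm0 + cfg.refit_halfwidth)

    channel_fits: dict[str, TwoStateFit] = {}
    conclusive: dict[str, bool] = {}
    for name, raw in (("f350", curve.f350), ("f330", curve.f330)):
        sig = smooth_trace(raw, cfg)
        lin = stats.linregress(T, sig)
        corrected = sig - (lin.intercept + lin.slope * T)
        try:
            fit = fit_two_state(T, corrected, cfg, window=window, channel=name)
        except ContractError:
            continue
        channel_fits[name] = fit
        mask = (T >= window[0]) & (T <= window[1])
        conclusive[name] = _is_conclusive(fit, T, corrected, window, cfg)

    good = [f.tm for name, f in channel_fits.items() if conclusive.get(name)]
    if good:
        tm = float(np.mean(good))
        provenance = "individual_channels"
    else:
        tm = tm0
        provenance = "ratio_fallback"
    return CurveAnalysis(tm=tm, provenance=provenance, ratio_fit=ratio_fit,
                         channel_fits=channel_fits, conclusive=conclusive,
                         sample_id=curve.sample_id,
                         replicate_id=curve.replicate_id)


def aggregate_replicates(tms: list[float]) -> tuple[float, float, bool]:
    """Mean and sample standard deviation across replicate melting
    temperatures; ``(mean, sd, single_replicate_flag)``."""
    if len(tms) == 0:
        raise ContractError("need at least one replicate")
    arr = np.asarray(tms, dtype=float)
    if arr.size == 1:
        return float(arr[0]), 0.0, True
    return float(arr.mean()), float(arr.std(ddof=1)), False
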