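"""Forward "toy" model of ROI BOLD responses around a voluntary action.

Three neural input components on a fine time grid — a premotor ramp, a
negative boxcar, and a visual delta impulse — are convolved with a
gamma-family hemodynamic kernel and sampled on the TR grid.  A multiplicative
gain on the delta component captures delay-dependent visual excitability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, InputError, SingularFitError

TR_S = 3.0
N_LAGS = 7
#: fine-grid span around action onset (seconds)
GRID_START_S = -5.0
GRID_END_S = 25.0
DEFAULT_GRID_STEP_S = 0.01

CONDITIONS = ("vision_only", "action_only", "va_trough", "va_peak")


@dataclass(frozen=True)
class HrfParams:
    """Gamma-family hemodynamic kernel parameters (decay, order, onset delay)."""

    tau_s: float = 2.0
    order: int = 3
    delay_s: float = 3.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ConfigurationError(f"tau_s must be > 0, got {self.tau_s}")
        if int(self.order) != self.order or self.order < 1:
            raise ConfigurationError(f"order must be an integer >= 1, got {self.order}")
        if self.delay_s < 0:
            raise ConfigurationError(f"delay_s must be >= 0, got {self.delay_s}")


@dataclass(frozen=True)
class RampSpec:
    start_s: float = -2.0
    end_s: float = -0.55
    amplitude: float = 0.27
    #: hold the plateau value after end_s instead of dropping back to 0
    plateau: bool = False


@dataclass(frozen=True)
class BoxcarSpec:
    start_s: float = -0.55
    end_s: float = 4.0
    amplitude: float = -0.06


@dataclass(frozen=True)
class DeltaSpec:
    #: impulse weight (%BOLD * s); the fine-grid sample holds amplitude/step
    amplitude: float = 7.0


def _default_gain() -> dict:
    return {"trough": 1.0, "peak": 1.33}


@dataclass(frozen=True)
class ModelComponents:
    """Component amplitudes/timing plus per-condition visual gain."""

    ramp: RampSpec = field(default_factory=RampSpec)
    boxcar: BoxcarSpec = field(default_factory=BoxcarSpec)
    delta: DeltaSpec = field(default_factory=DeltaSpec)
    gain: dict = field(default_factory=_default_gain)

    def __post_init__(self) -> None:
        if self.ramp.start_s >= self.ramp.end_s:
            raise ConfigurationError("ramp start must precede ramp end")
        if self.ramp.end_s > self.boxcar.start_s + 1e-12:
            raise ConfigurationError("ramp must precede the boxcar")
        if self.boxcar.amplitude > 0:
            raise ConfigurationError("boxcar amplitude must be <= 0")
        for k, g in self.gain.items():
            if g <= 0:
                raise ConfigurationError(f"gain[{k!r}] must be > 0, got {g}")


@dataclass(frozen=True)
class SimulatedCurve:
    """Fine-grid response plus its TR-sampled 7-lag values."""

    time_s: np.ndarray
    response: np.ndarray
    lag_times_s: np.ndarray
    lag_values: np.ndarray


def hrf_kernel(params: HrfParams, t: np.ndarray) -> np.ndarray:
    """Gamma kernel h(t) = ((t-d)/tau)^(n-1) exp(-(t-d)/tau) / (tau (n-1)!) for t > d.

    Identically zero at and before the onset delay.  When the supplied grid is
    dense enough to carry area, the kernel is renormalized to unit area on it.
    """
    t = np.asarray(t, dtype=float)
    if t.size and np.any(t < 0):
        raise InputError("kernel time grid must be non-negative")
    u = t - params.delay_s
    h = np.zeros_like(t)
    pos = u > 0
    up = u[pos] / params.tau_s
    n = int(params.order)
    h[pos] = up ** (n - 1) * np.exp(-up) / (params.tau_s * math.factorial(n - 1))
    if t.size > 1:
        area = np.trapezoid(h, t)
        if area > 1e-9:
            h = h / area
    return h


def time_grid(grid_step_s: float = DEFAULT_GRID_STEP_S) -> np.ndarray:
    n = int(round((GRID_END_S - GRID_START_S) / grid_step_s))
    return GRID_START_S + grid_step_s * np.arange(n + 1)


def component_regressors(
    components: ModelComponents,
    grid_step_s: float = DEFAULT_GRID_STEP_S,
    delay_ms: float = 0.0,
    gain: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (t, ramp, boxcar, delta) input series on the fine grid.

    The delta is a unit-integral impulse scaled by ``gain * delta.amplitude``
    placed at ``delay_ms`` after action onset.
    """
    t = time_grid(grid_step_s)
    eps = 1e-9 * grid_step_s  # grid values are floats; include exact edges

    r = components.ramp
    ramp = np.zeros_like(t)
    rising = (t >= r.start_s - eps) & (t <= r.end_s + eps)
    ramp[rising] = r.amplitude * (t[rising] - r.start_s) / (r.end_s - r.start_s)
    if r.plateau:
        ramp[t > r.end_s + eps] = r.amplitude

    b = components.boxcar
    boxcar = np.zeros_like(t)
    boxcar[(t >= b.start_s - eps) & (t <= b.end_s + eps)] = b.amplitude

    delta = np.zeros_like(t)
    t_vis = delay_ms / 1000.0
    if not (t[0] - 1e-9 <= t_vis <= t[-1] + 1e-9):
        raise InputError(f"delta time {t_vis} s outside the grid [{t[0]}, {t[-1]}]")
    idx = int(round((t_vis - t[0]) / grid_step_s))
    delta[idx] = gain * components.delta.amplitude / grid_step_s

    return t, ramp, boxcar, delta


def _convolve_and_sample(
    t: np.ndarray, x: np.ndarray, hrf: HrfParams, grid_step_s: float
) -> SimulatedCurve:
    # kernel support padded past the grid so late responses are not clipped
    tk = grid_step_s * np.arange(int(round((GRID_END_S - GRID_START_S + 10.0) / grid_step_s)) + 1)
    h = hrf_kernel(hrf, tk)
    y = np.convolve(x, h)[: t.size] * grid_step_s
    lag_times = TR_S * np.arange(N_LAGS)
    idx = np.round((lag_times - t[0]) / grid_step_s).astype(int)
    return SimulatedCurve(time_s=t, response=y, lag_times_s=lag_times, lag_values=y[idx])


def predict_curve(
    components: ModelComponents,
    hrf: HrfParams,
    include: tuple[str, ...] = ("ramp", "boxcar", "delta"),
    delay_ms: float = 0.0,
    gain: float = 1.0,
    grid_step_s: float = DEFAULT_GRID_STEP_S,
) -> SimulatedCurve:
    """Convolve the selected components with the kernel; sample at TR lags."""
    t, ramp, boxcar, delta = component_regressors(
        components, grid_step_s=grid_step_s, delay_ms=delay_ms, gain=gain
    )
    x = np.zeros_like(t)
    if "ramp" in include:
        x += ramp
    if "boxcar" in include:
        x += boxcar
    if "delta" in include:
        x += delta
    return _convolve_and_sample(t, x, hrf, grid_step_s)


def simulate_condition(
    components: ModelComponents,
    hrf: HrfParams,
    condition: str,
    delay_ms: float = 0.0,
    grid_step_s: float = DEFAULT_GRID_STEP_S,
) -> SimulatedCurve:
    """Predicted V1-style response for one of the four canonical conditions."""
    if condition not in CONDITIONS:
        raise InputError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if condition == "vision_only":
        include: tuple[str, ...] = ("delta",)
        gain = 1.0
    elif condition == "action_only":
        include = ("ramp", "boxcar")
        gain = 1.0
    else:
        include = ("ramp", "boxcar", "delta")
        gain = components.gain["peak"] if condition == "va_peak" else components.gain["trough"]
    return predict_curve(
        components, hrf, include=include, delay_ms=delay_ms, gain=gain, grid_step_s=grid_step_s
    )


_FREE_PARAMS = ("a_ramp", "a_box", "a_vis", "g")


def _unit_bases(
    components: ModelComponents, hrf: HrfParams, delay_ms: float, grid_step_s: float
) -> dict[str, np.ndarray]:
    unit = ModelComponents(
        ramp=replace(components.ramp, amplitude=1.0),
        boxcar=replace(components.boxcar, amplitude=0.0),
        delta=DeltaSpec(amplitude=1.0),
        gain=dict(components.gain),
    )
    ramp = predict_curve(unit, hrf, include=("ramp",), grid_step_s=grid_step_s).lag_values
    box_unit = ModelComponents(
        ramp=components.ramp, boxcar=components.boxcar, delta=components.delta,
        gain=dict(components.gain),
    )
    # boxcar amplitude is constrained <= 0, so build the unit basis by rescale
    if components.boxcar.amplitude != 0:
        box = (
            predict_curve(box_unit, hrf, include=("boxcar",), grid_step_s=grid_step_s).lag_values
            / components.boxcar.amplitude
        )
    else:
        neg = ModelComponents(
            ramp=components.ramp, boxcar=replace(components.boxcar, amplitude=-1.0),
            delta=components.delta, gain=dict(components.gain),
        )
        box = -predict_curve(neg, hrf, include=("boxcar",), grid_step_s=grid_step_s).lag_values
    delta = predict_curve(
        unit, hrf, include=("delta",), delay_ms=delay_ms, gain=1.0, grid_step_s=grid_step_s
    ).lag_values
    return {"ramp": ramp, "box": box, "delta": delta}


def fit_component_amplitudes(
    observed: np.ndarray,
    components: ModelComponents,
    hrf: HrfParams,
    free: tuple[str, ...] = ("a_ramp", "a_box", "a_vis"),
    delay_ms: float = 0.0,
    grid_step_s: float = DEFAULT_GRID_STEP_S,
) -> tuple[dict[str, float], float]:
    """Linear least-squares fit of the free component amplitudes to a 7-lag curve.

    ``g`` enters linearly on the delta regressor with ``a_vis`` held fixed;
    freeing both at once is unidentifiable and rejected.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (N_LAGS,):
        raise InputError(f"observed curve must have {N_LAGS} lags, got shape {observed.shape}")
    bad = set(free) - set(_FREE_PARAMS)
    if bad:
        raise InputError(f"unknown free parameters: {sorted(bad)}")
    if "a_vis" in free and "g" in free:
        raise InputError("a_vis and g cannot both be free (their product is identified)")
    if len(free) == 0:
        raise InputError("at least one free parameter required")
    if observed.size < len(free):
        raise InputError("fewer data points than free amplitudes")

    bases = _unit_bases(components, hrf, delay_ms, grid_step_s)
    cols, names = [], []
    offset = np.zeros(N_LAGS)
    g_fixed = components.gain.get("trough", 1.0)

    if "a_ramp" in free:
        cols.append(bases["ramp"]); names.append("a_ramp")
    else:
        offset += components.ramp.amplitude * bases["ramp"]
    if "a_box" in free:
        cols.append(bases["box"]); names.append("a_box")
    else:
        offset += components.boxcar.amplitude * bases["box"]
    if "a_vis" in free:
        cols.append(g_fixed * bases["delta"]); names.append("a_vis")
    elif "g" in free:
        cols.append(components.delta.amplitude * bases["delta"]); names.append("g")
    else:
        offset += g_fixed * components.delta.amplitude * bases["delta"]

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(
            f"component curves {names} are collinear at TR sampling"
        )
    y = observed - offset
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta + offset
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return dict(zip(names, (float(b) for b in beta))), r2


def estimate_visual_gain(
    trough_curve: np.ndarray,
    peak_curve: np.ndarray,
    components: ModelComponents,
    hrf: HrfParams,
    delay_trough_ms: float = 0.0,
    delay_peak_ms: float | None = None,
    grid_step_s: float = DEFAULT_GRID_STEP_S,
) -> dict:
    """Fit shared amplitudes on the trough curve, then the visual gain on the peak curve."""
    if delay_peak_ms is None:
        delay_peak_ms = delay_trough_ms
    trough_curve = np.asarray(trough_curve, dtype=float)
    peak_curve = np.asarray(peak_curve, dtype=float)
    if trough_curve.shape != peak_curve.shape:
        raise InputError("trough and peak curves must share the lag grid")

    shared, r2_trough = fit_component_amplitudes(
        trough_curve, components, hrf,
        free=("a_ramp", "a_box", "a_vis"),
        delay_ms=delay_trough_ms, grid_step_s=grid_step_s,
    )
    if abs(shared["a_vis"]) < 1e-9:
        raise InputError("fitted visual amplitude is ~0; gain is not identifiable")
    fitted = ModelComponents(
        ramp=replace(components.ramp, amplitude=shared["a_ramp"]),
        boxcar=replace(components.boxcar, amplitude=min(shared["a_box"], 0.0)),
        delta=DeltaSpec(amplitude=shared["a_vis"]),
        gain={"trough": 1.0, "peak": components.gain.get("peak", 1.33)},
    )
    # keep the (possibly positive) boxcar estimate on the linear path
    bases = _unit_bases(fitted, hrf, delay_peak_ms, grid_step_s)
    offset = shared["a_ramp"] * bases["ramp"] + shared["a_box"] * bases["box"]
    x = shared["a_vis"] * bases["delta"]
    y = peak_curve - offset
    g = float(np.dot(x, y) / np.dot(x, x))
    fitted_peak = offset + g * x
    ss_res = float(np.sum((peak_curve - fitted_peak) ** 2))
    ss_tot = float(np.sum((peak_curve - peak_curve.mean()) ** 2))
    r2_peak = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {
        "g": g,
        "a_ramp": shared["a_ramp"],
        "a_box": shared["a_box"],
        "a_vis": shared["a_vis"],
        "r_squared_trough": r2_trough,
        "r_squared_peak": r2_peak,
    }
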