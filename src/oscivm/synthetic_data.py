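"""Synthetic behavioral trials and two-ROI event-related BOLD runs.

The behavioral generator draws Bernoulli trial outcomes whose success
probability is sinusoidally modulated over the visuo-motor delay.  The BOLD
generator builds event schedules with truncated-normal gaps, injects the
forward-model condition curves per event (V1 with a delay-dependent visual
gain; M1 without the visual component), and adds linear drift, independent
white noise, and an event-gated shared-noise component whose gain can depend
on the delay — the mechanism producing delay-dependent residual correlation.

Everything is deterministic given the config seed; fixtures serialize to
plain TSV/JSON and round-trip through :mod:`oscivm.io`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import forward_model as fm
from .exceptions import ConfigurationError, InputError
from .fmri_glm import RoiTimeSeries

DEFAULT_DELAYS_MS = (70, 150, 230, 310)


def _default_visual_gain() -> dict:
    return {70: 1.0, 150: 1.33, 230: 1.0, 310: 1.33}


def _default_shared_gain() -> dict:
    return {70: 1.0, 150: 1.0, 230: 1.0, 310: 1.0}


@dataclass
class GeneratorConfig:
    seed: int = 0
    subject_id: str = "agg"
    # behavioral generator
    n_trials: int = 1000
    baseline_acc: float = 0.7
    osc_amp: float = 0.1
    osc_freq_hz: float = 5.4
    osc_phase_rad: float = 0.0
    delay_min_ms: float = 0.0
    delay_max_ms: float = 600.0
    delay_step_ms: float = 10.0
    # BOLD generator
    n_runs: int = 1
    tr_s: float = 3.0
    run_len_tr: int = 130
    mean_gap_s: float = 19.0
    sd_gap_s: float = 3.0
    min_gap_s: float = 15.0
    delays_ms: tuple = DEFAULT_DELAYS_MS
    condition_weights: dict | None = None  # trial_type -> prob; default uniform on delays
    noise_sd: float = 0.3
    drift_slope: float = 0.0
    shared_sd: float = 0.0
    shared_gain_by_delay: dict = field(default_factory=_default_shared_gain)
    visual_gain_by_delay: dict = field(default_factory=_default_visual_gain)
    model: fm.ModelComponents = field(default_factory=fm.ModelComponents)
    hrf: fm.HrfParams = field(default_factory=fm.HrfParams)

    def validate(self) -> None:
        if not 0.0 <= self.baseline_acc <= 1.0:
            raise ConfigurationError(f"baseline_acc {self.baseline_acc} outside [0, 1]")
        if self.osc_amp < 0:
            raise ConfigurationError("osc_amp must be >= 0")
        lo, hi = self.baseline_acc - self.osc_amp, self.baseline_acc + self.osc_amp
        if lo < 0.0 or hi > 1.0:
            raise ConfigurationError(
                f"baseline_acc +/- osc_amp = [{lo}, {hi}] leaves the probability range"
            )
        if self.delay_step_ms <= 0 or self.delay_max_ms < self.delay_min_ms:
            raise ConfigurationError("invalid behavioral delay grid")
        if self.delay_grid().size == 0:
            raise ConfigurationError("empty delay grid")
        if self.tr_s <= 0:
            raise ConfigurationError("tr_s must be > 0")
        if self.run_len_tr <= fm.N_LAGS + 7:
            raise ConfigurationError("run too short for a single event plus its window")
        if self.noise_sd < 0 or self.shared_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.min_gap_s < 5 * self.tr_s - 1e-9:
            raise ConfigurationError("minimum event gap must be >= 5 TRs")

    def delay_grid(self) -> np.ndarray:
        n = int(round((self.delay_max_ms - self.delay_min_ms) / self.delay_step_ms))
        return self.delay_min_ms + self.delay_step_ms * np.arange(n + 1)

    def trial_types(self) -> list[str]:
        if self.condition_weights is not None:
            return list(self.condition_weights.keys())
        return [f"d{int(d)}" for d in self.delays_ms]

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def trial_type_delay_ms(trial_type: str) -> float:
    """Delay (ms) encoded in a d<ms> label; 0 for the special conditions."""
    if trial_type.startswith("d") and trial_type[1:].isdigit():
        return float(trial_type[1:])
    return 0.0


def gen_behavior_trials(cfg: GeneratorConfig) -> pd.DataFrame:
    """Bernoulli trials with p(d) = baseline + amp*sin(2*pi*f*d/1000 + phase)."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    grid = cfg.delay_grid()
    delays = rng.choice(grid, size=cfg.n_trials)
    p = cfg.baseline_acc + cfg.osc_amp * np.sin(
        2.0 * np.pi * cfg.osc_freq_hz * delays / 1000.0 + cfg.osc_phase_rad
    )
    correct = (rng.random(cfg.n_trials) < p).astype(int)
    return pd.DataFrame(
        {"subject_id": cfg.subject_id, "delay_ms": delays, "correct": correct}
    )


def gen_event_schedule(cfg: GeneratorConfig) -> pd.DataFrame:
    """Event onsets with truncated-normal gaps, TR-uniform jitter, delay labels.

    Onsets are placed after the 6 TRs later discarded by preprocessing and at
    least 7 TRs before the run end (the FIR window plus the preprocessing
    shift both stay in bounds).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    types = cfg.trial_types()
    if cfg.condition_weights is not None:
        w = np.array([cfg.condition_weights[t] for t in types], dtype=float)
        w = w / w.sum()
    else:
        w = np.full(len(types), 1.0 / len(types))

    a = (cfg.min_gap_s - cfg.mean_gap_s) / cfg.sd_gap_s
    run_len_s = cfg.run_len_tr * cfg.tr_s
    last_ok_tr = cfg.run_len_tr - 8  # event_tr - 6 + 6 <= run_len - 7 - 1 after the drop

    rows = []
    for r in range(cfg.n_runs):
        rid = f"run{r:02d}"
        t = 6 * cfg.tr_s  # events only in the retained portion
        n_run = 0
        while True:
            gap = stats.truncnorm.rvs(a, np.inf, loc=cfg.mean_gap_s,
                                      scale=cfg.sd_gap_s, random_state=rng)
            t += gap
            # uniform jitter of the keypress phase within its TR
            onset = np.floor(t / cfg.tr_s) * cfg.tr_s + rng.uniform(0.0, cfg.tr_s)
            event_tr = int(onset // cfg.tr_s)
            if event_tr > last_ok_tr or onset >= run_len_s:
                break
            tt = rng.choice(types, p=w)
            rows.append(
                {"onset": onset, "duration": 0.03, "trial_type": str(tt),
                 "run_id": rid, "event_tr": event_tr,
                 "delay_ms": trial_type_delay_ms(str(tt))}
            )
            n_run += 1
        if n_run == 0:
            raise ConfigurationError(f"run {rid} too short to place any event")
    return pd.DataFrame(rows)


def _condition_curves(cfg: GeneratorConfig) -> dict[str, dict[str, np.ndarray]]:
    """TR-lag ground-truth curves per ROI and trial type."""
    curves: dict[str, dict[str, np.ndarray]] = {"V1": {}, "M1": {}}
    action = fm.predict_curve(cfg.model, cfg.hrf, include=("ramp", "boxcar")).lag_values
    for tt in cfg.trial_types():
        if tt == "vision_only":
            vis = fm.predict_curve(cfg.model, cfg.hrf, include=("delta",), delay_ms=0.0).lag_values
            curves["V1"][tt] = vis
            curves["M1"][tt] = np.zeros(fm.N_LAGS)
        elif tt == "action_only":
            curves["V1"][tt] = action.copy()
            curves["M1"][tt] = action.copy()
        else:
            d = trial_type_delay_ms(tt)
            g = cfg.visual_gain_by_delay.get(int(d), 1.0)
            curves["V1"][tt] = fm.predict_curve(
                cfg.model, cfg.hrf, include=("ramp", "boxcar", "delta"), delay_ms=d, gain=g
            ).lag_values
            curves["M1"][tt] = action.copy()
    return curves


#: TR offsets around each event over which the shared-noise gain applies (-3..+12 s)
SHARED_WINDOW_TR = np.arange(-1, 5)


def gen_roi_timeseries(
    events: pd.DataFrame, cfg: GeneratorConfig
) -> tuple[list[RoiTimeSeries], dict]:
    """Per-run V1/M1 series: event curves + drift + white noise + gated shared noise."""
    cfg.validate()
    if events.empty:
        raise InputError("empty event table")
    unknown = set(events["trial_type"]) - set(cfg.trial_types())
    if unknown:
        raise ConfigurationError(f"events contain types absent from the config: {sorted(unknown)}")
    rng = np.random.default_rng([cfg.seed, 2])
    curves = _condition_curves(cfg)
    n = cfg.run_len_tr
    drift = cfg.drift_slope * np.arange(n, dtype=float)

    series: list[RoiTimeSeries] = []
    run_ids = sorted(events["run_id"].unique())
    for rid in run_ids:
        ev_run = events[events["run_id"] == rid]
        signal = {"V1": np.zeros(n), "M1": np.zeros(n)}
        gain_vec = np.ones(n)
        for _, ev in ev_run.iterrows():
            t = int(ev["event_tr"])
            if t < 0 or t + fm.N_LAGS > n:
                raise InputError(f"event at TR {t} of {rid} does not fit the run")
            for roi in ("V1", "M1"):
                signal[roi][t : t + fm.N_LAGS] += curves[roi][ev["trial_type"]]
            g = cfg.shared_gain_by_delay.get(int(ev["delay_ms"]), 1.0)
            idx = t + SHARED_WINDOW_TR
            idx = idx[(idx >= 0) & (idx < n)]
            gain_vec[idx] = g
        shared = rng.normal(0.0, cfg.shared_sd, n) if cfg.shared_sd > 0 else np.zeros(n)
        shared = shared * gain_vec
        for roi in ("V1", "M1"):
            noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)
            series.append(
                RoiTimeSeries(roi=roi, run_id=rid,
                              values=signal[roi] + drift + noise + shared, tr_s=cfg.tr_s)
            )
    ground_truth = {
        "seed": cfg.seed,
        "curves": {roi: {tt: c.tolist() for tt, c in per.items()} for roi, per in curves.items()},
        "visual_gain_by_delay": {str(k): v for k, v in cfg.visual_gain_by_delay.items()},
        "shared_gain_by_delay": {str(k): v for k, v in cfg.shared_gain_by_delay.items()},
        "noise_sd": cfg.noise_sd,
        "shared_sd": cfg.shared_sd,
        "drift_slope": cfg.drift_slope,
    }
    return series, ground_truth


def write_fixture_bundle(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    series: list[RoiTimeSeries],
    path: str | Path,
    cfg: GeneratorConfig,
    ground_truth: dict | None = None,
) -> dict:
    """Write trials.tsv / events.tsv / bold.tsv / ground_truth.json / manifest.json."""
    from . import io as oio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    oio.write_trials(trials, path / "trials.tsv")
    oio.write_events(events, path / "events.tsv")
    oio.write_bold(series, path / "bold.tsv")
    if ground_truth is None:
        ground_truth = {"seed": cfg.seed}
    (path / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=1, sort_keys=True) + "\n"
    )
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_trials": int(len(trials)),
        "n_events": int(len(events)),
        "n_series": len(series),
        "files": ["trials.tsv", "events.tsv", "bold.tsv", "ground_truth.json"],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def read_fixture_bundle(path: str | Path) -> dict:
    """Load a fixture bundle, warning when the manifest seed disagrees with ground truth."""
    from . import io as oio

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    ground_truth = json.loads((path / "ground_truth.json").read_text())
    if "seed" in ground_truth and ground_truth["seed"] != manifest.get("seed"):
        warnings.warn(
            f"fixture mismatch: manifest seed {manifest.get('seed')} != "
            f"ground-truth seed {ground_truth['seed']}"
        )
    return {
        "trials": oio.read_trials(path / "trials.tsv"),
        "events": oio.read_events(path / "events.tsv"),
        "series": oio.read_bold(path / "bold.tsv"),
        "ground_truth": ground_truth,
        "manifest": manifest,
    }
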