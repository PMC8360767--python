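"""M1-V1 functional connectivity from FIR-GLM residuals.

Residual epochs are extracted at TR offsets {-1..4} (-3 to +12 s) around each
event; per delay and offset, the Pearson correlation is computed across
events between the two ROIs, averaged over offsets, and peak-vs-trough delay
differences are tested by resampling events with replacement (one-tailed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .fmri_glm import GlmFit

#: TR offsets relative to the event TR (TR = 3 s -> -3, 0, 3, 6, 9, 12 s)
OFFSETS_TR = np.arange(-1, 5)
OFFSET_TIMES_S = OFFSETS_TR * 3.0
PEAK_DELAYS = ("d150", "d310")
TROUGH_DELAYS = ("d70", "d230")


@dataclass
class ResidualEpochs:
    trial_type: np.ndarray       # (n_events,)
    v1: np.ndarray               # (n_events, 6)
    m1: np.ndarray               # (n_events, 6)
    n_dropped: int = 0

    def subset(self, trial_type: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.trial_type == trial_type
        return self.v1[mask], self.m1[mask]


@dataclass
class ConnectivityEstimate:
    per_offset_r: dict           # trial_type -> (6,) array
    mean_r: dict                 # trial_type -> float
    n_events: dict               # trial_type -> int
    offsets_s: np.ndarray = field(default_factory=lambda: OFFSET_TIMES_S.copy())


@dataclass
class BootstrapResult:
    statistic: float
    boot_distribution: np.ndarray
    p_value: float
    n_boot: int
    seed: int | None
    group_mean_r: dict           # {"peak": float, "trough": float}


def extract_residual_epochs(
    fit_v1: GlmFit, fit_m1: GlmFit, events: pd.DataFrame
) -> ResidualEpochs:
    """Six-offset residual vectors per event for both ROIs; boundary epochs dropped."""
    if set(fit_v1.residuals) != set(fit_m1.residuals):
        raise InputError(
            f"run ids differ between fits: {sorted(fit_v1.residuals)} vs {sorted(fit_m1.residuals)}"
        )
    types, v1_rows, m1_rows = [], [], []
    n_dropped = 0
    for _, ev in events.iterrows():
        rid = ev["run_id"]
        if rid not in fit_v1.residuals:
            raise InputError(f"event references run {rid!r} absent from the GLM fits")
        rv, rm = fit_v1.residuals[rid], fit_m1.residuals[rid]
        idx = int(ev["event_tr"]) + OFFSETS_TR
        if idx[0] < 0 or idx[-1] >= rv.size:
            n_dropped += 1
            continue
        types.append(ev["trial_type"])
        v1_rows.append(rv[idx])
        m1_rows.append(rm[idx])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} epoch(s) crossing run boundaries")
    if not types:
        raise InputError("no usable epochs (all events cross run boundaries)")
    return ResidualEpochs(
        trial_type=np.array(types), v1=np.array(v1_rows), m1=np.array(m1_rows),
        n_dropped=n_dropped,
    )


def _pearson_columns(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r across events; zero-variance columns give r = 0."""
    vc = v - v.mean(axis=0)
    mc = m - m.mean(axis=0)
    sv = np.sqrt(np.sum(vc ** 2, axis=0))
    sm = np.sqrt(np.sum(mc ** 2, axis=0))
    denom = sv * sm
    r = np.zeros(v.shape[1])
    ok = denom > 0
    if not np.all(ok):
        warnings.warn("zero-variance residual vector; correlation set to 0 at that offset")
    r[ok] = np.sum(vc * mc, axis=0)[ok] / denom[ok]
    return r


def delay_connectivity(epochs: ResidualEpochs, min_events: int = 5) -> ConnectivityEstimate:
    """Per-delay, per-offset correlations across events, averaged over the 6 offsets."""
    per_offset, mean_r, n_events = {}, {}, {}
    for tt in sorted(set(epochs.trial_type)):
        v, m = epochs.subset(tt)
        if v.shape[0] < min_events:
            raise InputError(f"delay {tt}: only {v.shape[0]} events (< {min_events})")
        r = _pearson_columns(v, m)
        per_offset[tt] = r
        mean_r[tt] = float(r.mean())
        n_events[tt] = int(v.shape[0])
    return ConnectivityEstimate(per_offset_r=per_offset, mean_r=mean_r, n_events=n_events)


def _boot_r_per_offset(
    v: np.ndarray, m: np.ndarray, idx: np.ndarray, chunk: int = 2000
) -> np.ndarray:
    """Per-offset correlations for resampled event sets; returns (n_boot, 6)."""
    n_boot = idx.shape[0]
    out = np.empty((n_boot, v.shape[1]))
    for lo in range(0, n_boot, chunk):
        sub = idx[lo : lo + chunk]
        vb, mb = v[sub], m[sub]                    # (B, m, 6)
        vb = vb - vb.mean(axis=1, keepdims=True)
        mb = mb - mb.mean(axis=1, keepdims=True)
        num = np.sum(vb * mb, axis=1)
        den = np.sqrt(np.sum(vb ** 2, axis=1) * np.sum(mb ** 2, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, 0.0)
        out[lo : lo + chunk] = r
    return out


def bootstrap_peak_vs_trough(
    epochs: ResidualEpochs,
    peak: tuple = PEAK_DELAYS,
    trough: tuple = TROUGH_DELAYS,
    n_boot: int = 10000,
    seed: int | None = None,
) -> BootstrapResult:
    """One-tailed bootstrap of mean_r(peak) - mean_r(trough), resampling events within delay."""
    if n_boot < 100:
        raise InputError(f"n_boot must be >= 100, got {n_boot}")
    present = set(epochs.trial_type)
    if not (set(peak) & present) or not (set(trough) & present):
        raise InputError("both peak and trough delay groups must have events")
    rng = np.random.default_rng(seed)

    observed = delay_connectivity(epochs)
    obs_peak = float(np.mean([observed.mean_r[t] for t in peak if t in present]))
    obs_trough = float(np.mean([observed.mean_r[t] for t in trough if t in present]))

    boot_group: dict[str, np.ndarray] = {}
    for name, group in (("peak", peak), ("trough", trough)):
        per_delay = []
        for tt in group:
            if tt not in present:
                continue
            v, m = epochs.subset(tt)
            n_ev = v.shape[0]
            idx = rng.integers(0, n_ev, size=(n_boot, n_ev))
            per_delay.append(_boot_r_per_offset(v, m, idx).mean(axis=1))
        boot_group[name] = np.mean(per_delay, axis=0)
    diff = boot_group["peak"] - boot_group["trough"]
    p = (1.0 + np.sum(diff <= 0.0)) / (n_boot + 1.0)
    return BootstrapResult(
        statistic=obs_peak - obs_trough, boot_distribution=diff, p_value=float(p),
        n_boot=n_boot, seed=seed,
        group_mean_r={"peak": obs_peak, "trough": obs_trough},
    )


def trwise_connectivity_difference(
    epochs: ResidualEpochs,
    peak: tuple = PEAK_DELAYS,
    trough: tuple = TROUGH_DELAYS,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-offset (r_peak - r_trough) with bootstrap standard errors."""
    if n_boot < 100:
        raise InputError(f"n_boot must be >= 100, got {n_boot}")
    present = set(epochs.trial_type)
    rng = np.random.default_rng(seed)
    observed = delay_connectivity(epochs)

    def group_r(group: tuple) -> np.ndarray:
        return np.mean([observed.per_offset_r[t] for t in group if t in present], axis=0)

    def group_boot(group: tuple) -> np.ndarray:
        per_delay = []
        for tt in group:
            if tt not in present:
                continue
            v, m = epochs.subset(tt)
            idx = rng.integers(0, v.shape[0], size=(n_boot, v.shape[0]))
            per_delay.append(_boot_r_per_offset(v, m, idx))
        return np.mean(per_delay, axis=0)           # (n_boot, 6)

    diff = group_r(peak) - group_r(trough)
    boot_diff = group_boot(peak) - group_boot(trough)
    return pd.DataFrame(
        {"offset_s": OFFSET_TIMES_S, "r_diff": diff,
         "bootstrap_se": boot_diff.std(axis=0, ddof=1)}
    )
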