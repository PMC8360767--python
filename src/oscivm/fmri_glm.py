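"""FIR deconvolution of event-related ROI BOLD and delay-contrast statistics.

Per-run series are cleaned (initial-TR drop, linear detrend, percent signal
change), a finite-impulse-response indicator design (7 lags per event type
plus a constant) is fit by OLS over concatenated runs, and the resulting
per-lag beta curves feed an amplitude summary (mean of lags 1-4, i.e. the
3-12 s integral divided by time at TR = 3 s) with paired one-tailed
contrasts, Holm correction, and a one-way repeated-measures ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, NormalizationError, SingularFitError

TR_S = 3.0
WINDOW_TR = 7
N_DROP_TR = 6
#: lags entering the amplitude summary: 3-12 s at TR 3 s
AMPLITUDE_LAGS = (1, 2, 3, 4)
#: fixed (trough, peak) pairings; the one-tailed alternative is peak > trough
DELAY_PAIRINGS = ((70, 150), (230, 150), (230, 310), (70, 310))

TRIAL_TYPES = ("d70", "d150", "d230", "d310", "vision_only", "action_only")


@dataclass
class RoiTimeSeries:
    """One run of one ROI on a fixed TR grid."""

    roi: str
    run_id: str
    values: np.ndarray
    tr_s: float = TR_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("ROI series must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"non-finite values in series {self.roi}/{self.run_id}")


@dataclass
class FirDesign:
    matrix: np.ndarray
    labels: list  # (trial_type, lag) tuples plus "constant"
    run_ids: list
    run_slices: dict
    overlap_warnings: list = field(default_factory=list)


@dataclass
class GlmFit:
    betas: dict            # trial_type -> array of 7 lag betas
    constant: float
    residuals: dict        # run_id -> residual array
    r_squared: float
    n_timepoints: int
    labels: list


def preprocess_roi_series(raw: RoiTimeSeries, n_drop: int = N_DROP_TR) -> RoiTimeSeries:
    """Drop the first TRs, subtract the OLS linear trend, convert to % signal change."""
    v = raw.values
    if v.size <= n_drop:
        raise InputError(
            f"run {raw.run_id} has {v.size} TRs; need more than the {n_drop} dropped"
        )
    kept = v[n_drop:]
    mean = kept.mean()
    if abs(mean) < 1e-12:
        raise NormalizationError(
            f"series {raw.roi}/{raw.run_id} has zero mean; % signal change undefined"
        )
    x = np.arange(kept.size, dtype=float)
    slope, intercept = np.polyfit(x, kept, 1)
    detrended = kept - (slope * x + intercept)
    return RoiTimeSeries(
        roi=raw.roi, run_id=raw.run_id, values=100.0 * detrended / mean, tr_s=raw.tr_s
    )


def shift_events(events: pd.DataFrame, n_drop: int = N_DROP_TR, tr_s: float = TR_S) -> pd.DataFrame:
    """Re-index events onto the preprocessed (first-TRs-dropped) grid."""
    out = events.copy()
    out["event_tr"] = out["event_tr"] - n_drop
    out["onset"] = out["onset"] - n_drop * tr_s
    n_bad = int((out["event_tr"] < 0).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} event(s) that fall in the discarded initial TRs")
        out = out[out["event_tr"] >= 0].reset_index(drop=True)
    return out


def build_fir_design(
    events: pd.DataFrame,
    run_lengths: dict,
    window_tr: int = WINDOW_TR,
    trial_types: list | None = None,
) -> FirDesign:
    """Indicator FIR design over concatenated runs: one column per (type, lag) + constant.

    Entries are set to 1 (never summed); an event of type k at TR t puts ones
    at rows t..t+window-1 of the k columns.  Same-cell overlaps are flagged,
    not accumulated — events are >= 15 s apart by design, so overlap signals a
    degenerate input.
    """
    required = {"run_id", "trial_type", "event_tr"}
    if not required.issubset(events.columns):
        raise InputError(f"event table needs columns {sorted(required)}")
    if trial_types is None:
        trial_types = sorted(events["trial_type"].unique())
    run_ids = list(run_lengths.keys())
    n_total = int(sum(run_lengths.values()))
    n_cols = window_tr * len(trial_types) + 1
    X = np.zeros((n_total, n_cols))
    labels = [(tt, lag) for tt in trial_types for lag in range(window_tr)] + ["constant"]
    col_of = {lab: i for i, lab in enumerate(labels)}
    X[:, -1] = 1.0

    run_slices, offset = {}, 0
    for rid in run_ids:
        run_slices[rid] = slice(offset, offset + int(run_lengths[rid]))
        offset += int(run_lengths[rid])

    overlaps = []
    for _, ev in events.iterrows():
        rid = ev["run_id"]
        if rid not in run_slices:
            raise InputError(f"event references unknown run {rid!r}")
        n_run = int(run_lengths[rid])
        t = int(ev["event_tr"])
        if t < 0 or t + window_tr > n_run:
            raise InputError(
                f"event (run {rid}, type {ev['trial_type']}, TR {t}) is too close to "
                f"the run end for a {window_tr}-TR window"
            )
        base = run_slices[rid].start
        for lag in range(window_tr):
            row, col = base + t + lag, col_of[(ev["trial_type"], lag)]
            if X[row, col] == 1.0:
                overlaps.append((rid, ev["trial_type"], lag, t))
            X[row, col] = 1.0
    if overlaps:
        warnings.warn(f"{len(overlaps)} overlapping same-cell FIR indicator(s) flagged")
    return FirDesign(matrix=X, labels=labels, run_ids=run_ids,
                     run_slices=run_slices, overlap_warnings=overlaps)


def fit_fir_glm(series: list[RoiTimeSeries], design: FirDesign) -> GlmFit:
    """OLS fit of the FIR design to concatenated runs (one ROI)."""
    by_run = {s.run_id: s for s in series}
    if set(by_run) != set(design.run_ids):
        raise InputError(
            f"series runs {sorted(by_run)} do not match design runs {sorted(design.run_ids)}"
        )
    y = np.concatenate([by_run[rid].values for rid in design.run_ids])
    X = design.matrix
    if y.size != X.shape[0]:
        raise InputError(f"series length {y.size} does not match design rows {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (approximately) dependent columns via QR pivoting
        _, r = np.linalg.qr(X)
        bad = [design.labels[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise SingularFitError(f"rank-deficient FIR design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    lag_labels = [lab for lab in design.labels if lab != "constant"]
    window = (max(lab[1] for lab in lag_labels) + 1) if lag_labels else 0
    betas: dict[str, np.ndarray] = {}
    for i, lab in enumerate(design.labels):
        if lab == "constant":
            continue
        tt, lag = lab
        betas.setdefault(tt, np.zeros(window))[lag] = beta[i]
    residuals = {rid: resid[design.run_slices[rid]] for rid in design.run_ids}
    return GlmFit(betas=betas, constant=float(beta[-1]), residuals=residuals,
                  r_squared=r2, n_timepoints=int(y.size), labels=design.labels)


def response_amplitude(fit: GlmFit, lags: tuple = AMPLITUDE_LAGS) -> dict[str, float]:
    """Per event type, the mean beta over the 3-12 s lags (integral / time)."""
    out = {}
    for tt, b in fit.betas.items():
        if len(b) != WINDOW_TR:
            raise InputError(f"type {tt}: expected {WINDOW_TR}-lag betas, got {len(b)}")
        out[tt] = float(np.mean([b[lag] for lag in lags]))
    return out


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def paired_one_tailed_t(peak: np.ndarray, trough: np.ndarray) -> tuple[float, float, int]:
    """Paired t with the alternative peak > trough; returns (t, p, df)."""
    d = np.asarray(peak, dtype=float) - np.asarray(trough, dtype=float)
    if d.size < 2:
        raise InputError("paired t needs >= 2 subjects")
    if np.allclose(d, d[0]):
        raise InputError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(peak, trough, alternative="greater")
    return float(res.statistic), float(res.pvalue), d.size - 1


def one_sample_t(values: np.ndarray, alternative: str = "greater") -> tuple[float, float, int]:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputError("one-sample t needs >= 2 observations")
    if np.allclose(values, values[0]):
        raise InputError("zero variance; t undefined")
    res = stats.ttest_1samp(values, 0.0, alternative=alternative)
    return float(res.statistic), float(res.pvalue), values.size - 1


def delay_contrasts(
    amplitudes: pd.DataFrame, pairings: tuple = DELAY_PAIRINGS
) -> pd.DataFrame:
    """Paired one-tailed t (peak > trough) per pairing with Holm-adjusted p's.

    ``amplitudes`` is subjects x delays with integer-ms column names (or
    'd<ms>' strings).
    """
    cols = {int(str(c).lstrip("d")): c for c in amplitudes.columns}
    if len(amplitudes) < 3:
        raise InputError("need >= 3 subjects for delay contrasts")
    rows = []
    for trough_ms, peak_ms in pairings:
        if trough_ms not in cols or peak_ms not in cols:
            raise InputError(f"missing delay column for pairing ({trough_ms}, {peak_ms})")
        t, p, df = paired_one_tailed_t(
            amplitudes[cols[peak_ms]].to_numpy(), amplitudes[cols[trough_ms]].to_numpy()
        )
        rows.append({"trough_ms": trough_ms, "peak_ms": peak_ms, "t": t, "df": df, "p_raw": p})
    report = pd.DataFrame(rows)
    report["p_holm"] = holm_adjust(report["p_raw"].to_numpy())
    return report


@dataclass
class RmAnovaResult:
    f_stat: float
    df: tuple
    p_value: float
    eta_squared: float  # partial: SS_effect / (SS_effect + SS_error)


def rm_anova_delays(matrix: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA over conditions (subjects x conditions)."""
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise InputError("expected a subjects x conditions matrix")
    if not np.all(np.isfinite(a)):
        raise InputError("missing cells in the repeated-measures matrix; no imputation")
    n, k = a.shape
    if n < 3 or k < 2:
        raise InputError("need >= 3 subjects and >= 2 conditions")
    grand = a.mean()
    ss_cond = n * float(np.sum((a.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((a.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((a - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ss_cond == 0 else np.inf
    else:
        f = (ss_cond / df_cond) / ms_err
    p = float(stats.f.sf(f, df_cond, df_err)) if np.isfinite(f) else 0.0
    denom = ss_cond + ss_err
    eta = 0.0 if denom == 0 else ss_cond / denom
    return RmAnovaResult(f_stat=float(f), df=(df_cond, df_err), p_value=p, eta_squared=float(eta))


def rayleigh_uniformity(phases_rad: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns (z, p)."""
    ph = np.asarray(phases_rad, dtype=float)
    if ph.size == 0:
        raise InputError("empty phase array")
    n = ph.size
    rbar = float(np.hypot(np.cos(ph).mean(), np.sin(ph).mean()))
    z = n * rbar ** 2
    p = np.exp(-z) * (1.0 + (2.0 * z - z ** 2) / (4.0 * n))
    return float(z), float(np.clip(p, 0.0, 1.0))
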