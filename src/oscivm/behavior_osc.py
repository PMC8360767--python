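"""Rhythmic modulation of accuracy over visuo-motor delay.

Trials are binned over delay, each frequency on a grid is fit by OLS with
sine/cosine regressors, and significance of the best fit is assessed against
a permutation null in which correctness labels are shuffled across trials and
the full frequency grid is re-scanned — using all free parameters on the
surrogate data corrects for the multiple comparisons of the frequency scan.
Group-level phase consistency uses per-subject single-trial sine/cosine
regressions tested with Hotelling's T-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, SingularFitError

DEFAULT_BIN_WIDTH_MS = 20.0
DEFAULT_FREQ_GRID = (2.0, 20.0, 0.1)
SUBJECT_FREQ_RANGE = (3.5, 10.0)

_RANK_TOL = 1e-10


@dataclass
class AccuracySeries:
    """Binned proportion-correct over delay; empty bins are excluded, not interpolated."""

    bin_center_s: np.ndarray
    prop_correct: np.ndarray
    n_trials: np.ndarray
    bin_width_s: float
    n_empty_bins: int = 0


@dataclass
class SinusoidFit:
    freq_hz: float
    beta0: float
    beta1: float  # sine coefficient
    beta2: float  # cosine coefficient
    r_squared: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.beta1, self.beta2))

    @property
    def phase_rad(self) -> float:
        return float(np.arctan2(self.beta2, self.beta1))

    def predict(self, x_s: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * self.freq_hz * np.asarray(x_s, dtype=float)
        return self.beta0 + self.beta1 * np.sin(w) + self.beta2 * np.cos(w)


@dataclass
class PermutationResult:
    observed_best: SinusoidFit
    null_max_r2: np.ndarray
    p_corrected: float
    n_perm: int
    seed: int | None
    above_95th_percentile: bool


@dataclass
class HotellingResult:
    per_subject_betas: np.ndarray  # (n, 2) sine/cosine pairs
    t2: float
    f_stat: float
    df: tuple
    p_value: float


def bin_accuracy(
    trials: pd.DataFrame,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
    delay_min_ms: float = 0.0,
    delay_max_ms: float = 600.0,
) -> AccuracySeries:
    """Proportion correct in fixed non-overlapping delay bins (centers in seconds).

    The right edge is exclusive except for the final bin, which also takes
    delays equal to ``delay_max_ms`` so a [0, 600] grid yields 600/20 = 30 bins.
    """
    if trials.empty:
        raise InputError("empty trial table")
    span = delay_max_ms - delay_min_ms
    n_bins = int(round(span / bin_width_ms))
    if abs(n_bins * bin_width_ms - span) > 1e-9 or n_bins < 1:
        raise InputError(f"bin width {bin_width_ms} must divide the range {span}")
    d = trials["delay_ms"].to_numpy(dtype=float)
    if np.any((d < delay_min_ms) | (d > delay_max_ms)):
        raise InputError("delays outside the configured range")
    idx = np.minimum(((d - delay_min_ms) // bin_width_ms).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=trials["correct"].to_numpy(dtype=float), minlength=n_bins)
    centers_ms = delay_min_ms + bin_width_ms * (np.arange(n_bins) + 0.5)
    nonempty = counts > 0
    return AccuracySeries(
        bin_center_s=centers_ms[nonempty] / 1000.0,
        prop_correct=sums[nonempty] / counts[nonempty],
        n_trials=counts[nonempty],
        bin_width_s=bin_width_ms / 1000.0,
        n_empty_bins=int(n_bins - nonempty.sum()),
    )


def _design(x_s: np.ndarray, freq_hz: float) -> np.ndarray:
    w = 2.0 * np.pi * freq_hz * x_s
    return np.column_stack([np.ones_like(x_s), np.sin(w), np.cos(w)])


def fit_sinusoid_at_frequency(series: AccuracySeries, freq_hz: float) -> SinusoidFit:
    """Unweighted OLS of prop_correct on [1, sin(2 pi f x), cos(2 pi f x)]."""
    if freq_hz <= 0:
        raise InputError(f"frequency must be > 0, got {freq_hz}")
    x, y = series.bin_center_s, series.prop_correct
    if x.size < 4:
        raise InputError(f"need >= 4 non-empty bins, got {x.size}")
    X = _design(x, freq_hz)
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < _RANK_TOL * s[0]:
        raise SingularFitError(f"singular sinusoid design at f = {freq_hz:g} Hz")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # a numerically-constant series has no variance to explain
    if ss_tot <= 1e-15 * float(y @ y):
        r2 = 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return SinusoidFit(freq_hz=float(freq_hz), beta0=float(beta[0]),
                       beta1=float(beta[1]), beta2=float(beta[2]), r_squared=r2)


def frequency_grid(f_min: float, f_max: float, step: float) -> np.ndarray:
    if not (f_min < f_max) or step <= 0:
        raise InputError("need f_min < f_max and step > 0")
    n = int(round((f_max - f_min) / step))
    return f_min + step * np.arange(n + 1)


def scan_frequency_grid(
    series: AccuracySeries,
    f_min: float = DEFAULT_FREQ_GRID[0],
    f_max: float = DEFAULT_FREQ_GRID[1],
    step: float = DEFAULT_FREQ_GRID[2],
) -> tuple[SinusoidFit, np.ndarray]:
    """Exhaustive per-frequency OLS; the maximizer of R^2 wins, ties to the lowest f."""
    freqs = frequency_grid(f_min, f_max, step)
    spectrum = np.full((freqs.size, 2), np.nan)
    spectrum[:, 0] = freqs
    best: SinusoidFit | None = None
    for i, f in enumerate(freqs):
        try:
            fit = fit_sinusoid_at_frequency(series, f)
        except SingularFitError:
            continue
        spectrum[i, 1] = fit.r_squared
        if best is None or fit.r_squared > best.r_squared:
            best = fit
    if best is None:
        raise SingularFitError("all frequencies on the grid yielded singular fits")
    return best, spectrum


def _null_max_r2(
    bin_idx: np.ndarray,
    correct: np.ndarray,
    counts: np.ndarray,
    x: np.ndarray,
    freqs: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized max-over-frequencies R^2 for label-shuffled surrogates.

    For each frequency an orthonormal basis Q of [1, sin, cos] gives
    SS_res = ||y||^2 - ||Q^T y||^2, so the grid scan over all permutations is
    a single tensor contraction.
    """
    n_bins = x.size
    Q = np.empty((freqs.size, n_bins, 3))
    keep = np.ones(freqs.size, dtype=bool)
    for i, f in enumerate(freqs):
        X = _design(x, f)
        s = np.linalg.svd(X, compute_uv=False)
        if s[-1] < _RANK_TOL * s[0]:
            keep[i] = False
            continue
        Q[i], _ = np.linalg.qr(X)
    Q = Q[keep]

    Y = np.empty((n_bins, n_perm))
    perm = correct.copy()
    for j in range(n_perm):
        rng.shuffle(perm)
        Y[:, j] = np.bincount(bin_idx, weights=perm, minlength=n_bins) / counts
    ss_y = np.sum(Y ** 2, axis=0)
    ss_tot = ss_y - n_bins * Y.mean(axis=0) ** 2
    proj = np.einsum("fbk,bj->fkj", Q, Y)
    ss_fit = np.sum(proj ** 2, axis=1)            # (F, n_perm)
    ss_res = np.maximum(ss_y[None, :] - ss_fit, 0.0)
    ok = ss_tot > 1e-15 * ss_y                    # same constant-series guard as the fit
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ok[None, :], 1.0 - ss_res / ss_tot[None, :], 0.0)
    return np.maximum(r2, 0.0).max(axis=0)


def permutation_corrected_pvalue(
    trials: pd.DataFrame,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
    f_min: float = DEFAULT_FREQ_GRID[0],
    f_max: float = DEFAULT_FREQ_GRID[1],
    step: float = DEFAULT_FREQ_GRID[2],
    n_perm: int = 10000,
    seed: int | None = None,
    delay_min_ms: float = 0.0,
    delay_max_ms: float = 600.0,
) -> PermutationResult:
    """Grid-scan the observed data and a label-shuffle null; add-one p-value."""
    if n_perm < 100:
        raise InputError(f"n_perm must be >= 100, got {n_perm}")
    correct = trials["correct"].to_numpy(dtype=float)
    if np.all(correct == correct[0]):
        warnings.warn("degenerate trial table (all correct or all incorrect); p = 1")
    series = bin_accuracy(trials, bin_width_ms, delay_min_ms, delay_max_ms)
    observed, _ = scan_frequency_grid(series, f_min, f_max, step)

    # recompute the non-empty bin structure on the trial level for the null
    span = delay_max_ms - delay_min_ms
    n_bins_full = int(round(span / bin_width_ms))
    d = trials["delay_ms"].to_numpy(dtype=float)
    idx_full = np.minimum(((d - delay_min_ms) // bin_width_ms).astype(int), n_bins_full - 1)
    counts_full = np.bincount(idx_full, minlength=n_bins_full)
    nonempty = counts_full > 0
    remap = -np.ones(n_bins_full, dtype=int)
    remap[nonempty] = np.arange(nonempty.sum())
    bin_idx = remap[idx_full]

    rng = np.random.default_rng(seed)
    null = _null_max_r2(
        bin_idx, correct, counts_full[nonempty].astype(float),
        series.bin_center_s, frequency_grid(f_min, f_max, step), n_perm, rng,
    )
    p = (1.0 + np.sum(null >= observed.r_squared)) / (n_perm + 1.0)
    return PermutationResult(
        observed_best=observed,
        null_max_r2=null,
        p_corrected=float(p),
        n_perm=n_perm,
        seed=seed,
        above_95th_percentile=bool(observed.r_squared > np.percentile(null, 95)),
    )


def subject_sine_glm(trials: pd.DataFrame, freq_hz: float) -> tuple[float, float]:
    """Least-squares sine/cosine coefficients from single-trial outcomes."""
    if len(trials) < 10:
        raise InputError(f"need >= 10 trials per subject, got {len(trials)}")
    d_s = trials["delay_ms"].to_numpy(dtype=float) / 1000.0
    y = trials["correct"].to_numpy(dtype=float)
    X = _design(d_s, freq_hz)
    if np.any(X.std(axis=0)[1:] < 1e-12):
        raise SingularFitError(f"constant sine/cosine predictor at f = {freq_hz:g} Hz")
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < _RANK_TOL * s[0]:
        raise SingularFitError(f"singular single-trial design at f = {freq_hz:g} Hz")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[1]), float(beta[2])


def hotelling_t2_test(beta_pairs: np.ndarray) -> HotellingResult:
    """One-sample Hotelling T^2 of (sine, cosine) pairs against (0, 0)."""
    pairs = np.asarray(beta_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise InputError("expected an (n, 2) array of sine/cosine pairs")
    n = pairs.shape[0]
    if n < 3:
        raise InputError(f"Hotelling test needs >= 3 subjects, got {n}")
    mean = pairs.mean(axis=0)
    cov = np.cov(pairs, rowvar=False, ddof=1)
    if np.linalg.cond(cov) > 1e12:
        raise SingularFitError(
            "singular covariance of beta pairs; jitter frequencies or add subjects"
        )
    t2 = float(n * mean @ np.linalg.solve(cov, mean))
    f_stat = t2 * (n - 2) / (2.0 * (n - 1))
    p = float(stats.f.sf(f_stat, 2, n - 2))
    return HotellingResult(per_subject_betas=pairs, t2=t2, f_stat=float(f_stat),
                           df=(2, n - 2), p_value=p)
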