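# oscivm

Analysis toolkit for action-synchronized theta-range oscillations in behavior
and ROI-level BOLD, built around four stages:

1. **behavior_osc** — bin trial accuracy over visuo-motor delay, fit
   `y(x) = b0 + b1 sin(2πfx) + b2 cos(2πfx)` on a 2–20 Hz grid (0.1 Hz steps),
   and assess the best fit against a label-shuffle permutation null that
   re-scans the full grid per surrogate (automatic multiple-comparison
   correction). Group-level phase consistency via per-subject single-trial
   sine/cosine regressions and Hotelling's T².
2. **fmri_glm** — per-run preprocessing (drop 6 TRs, linear detrend, % signal
   change), FIR deconvolution with a 7-TR window per event type (4 delay types
   → 28 regressors + constant), response amplitude as the 3–12 s integral
   divided by time (mean of lags 1–4 at TR = 3 s), paired one-tailed contrasts
   with Holm correction, one-way repeated-measures ANOVA, and a Rayleigh test
   for event-timing uniformity within the TR.
3. **connectivity** — M1–V1 residual epochs at TR offsets −3…+12 s around each
   event, per-delay Pearson correlations across events averaged over offsets,
   and one-tailed bootstrap (resampling events within delay) of the
   peak (150/310 ms) vs trough (70/230 ms) difference, plus per-offset
   difference curves with bootstrap SEs.
4. **forward_model** — a toy generative model of the V1/M1 response: premotor
   ramp (−2 → −0.55 s), negative boxcar (−0.55 → +4 s), and a visual delta
   impulse, convolved with a gamma-family HRF (τ = 2 s, order 3, δ = 3 s);
   linear amplitude fitting and estimation of the delay-dependent visual gain.

A first-class **synthetic_data** module generates behavioral trials (Bernoulli
outcomes with sinusoidally modulated success probability over delay) and
two-ROI event-related BOLD runs (130 TR × 3 s, truncated-normal gaps of
19 ± 3 s, floor 15 s) with injected forward-model responses, linear drift,
independent noise, and an event-gated shared-noise component — so every stage
is testable offline with known ground truth.

## CLI

```bash
# everything, driven by a TOML config (see below)
oscivm all --config run.toml --check

# individual stages
oscivm simulate --seed 1 --out out/
oscivm behavior --trials out/sim/trials.tsv --fmin 2 --fmax 20 --step 0.1 --nperm 10000 --seed 1
oscivm glm --events out/sim/events.tsv --bold out/sim/bold.tsv --align keypress
oscivm connectivity --events out/sim/events.tsv --bold out/sim/bold.tsv --nboot 10000 --seed 1
oscivm model fit --betas out/betas.tsv --roi V1
```

Example `run.toml`:

```toml
out_dir = "out"
seed = 1
n_subjects = 5

[simulate]
n_trials = 5000
n_runs = 3
noise_sd = 0.3
shared_sd = 0.5

[behavior]
n_perm = 1000

[connectivity]
n_boot = 10000
```

`oscivm all` writes per-stage JSON/TSV outputs, a combined `summary.json`
(carrying the seed and a config hash), and `report.md`/`report.png`. Reruns
with the same config are byte-identical.

## Data formats

- `trials.tsv`: `subject_id`, `delay_ms`, `correct` (0/1)
- `events.tsv`: BIDS-style `onset` (s), `duration`, `trial_type`
  (`d70|d150|d230|d310|vision_only|action_only`), `run_id` (+ `event_tr`,
  `delay_ms`)
- `bold.tsv`: `run_id`, `tr_index`, `roi`, `value` (% BOLD)
- `ground_truth.json` / `manifest.json`: injected curves, gains, noise levels,
  seed, and config hash for fixture integrity checks
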