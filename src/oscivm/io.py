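"""Readers/writers for the plain-text interchange tables.

trials.tsv  : subject_id, delay_ms, correct
events.tsv  : onset, duration, trial_type, run_id (+ event_tr, delay_ms)
bold.tsv    : run_id, tr_index, roi, value
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .fmri_glm import RoiTimeSeries

_FLOAT_FMT = "%.17g"  # lossless float round-trip


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"subject_id", "delay_ms", "correct"} - set(df.columns)
    if missing:
        raise InputError(f"trials table missing columns: {sorted(missing)}")
    if df.empty:
        raise InputError(f"empty trials table: {path}")
    if not df["correct"].isin([0, 1]).all():
        raise InputError("trials 'correct' column must be 0/1")
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events(path: str | Path, tr_s: float = 3.0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"onset", "duration", "trial_type", "run_id"} - set(df.columns)
    if missing:
        raise InputError(f"events table missing columns: {sorted(missing)}")
    if "event_tr" not in df.columns:
        df["event_tr"] = np.floor(df["onset"] / tr_s).astype(int)
    if "delay_ms" not in df.columns:
        from .synthetic_data import trial_type_delay_ms

        df["delay_ms"] = [trial_type_delay_ms(t) for t in df["trial_type"]]
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    cols = ["onset", "duration", "trial_type", "run_id"]
    extra = [c for c in ("event_tr", "delay_ms") if c in events.columns]
    events[cols + extra].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_bold(path: str | Path, tr_s: float = 3.0) -> list[RoiTimeSeries]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"run_id", "tr_index", "roi", "value"} - set(df.columns)
    if missing:
        raise InputError(f"bold table missing columns: {sorted(missing)}")
    series = []
    for (rid, roi), grp in df.groupby(["run_id", "roi"], sort=True):
        grp = grp.sort_values("tr_index")
        idx = grp["tr_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise InputError(f"non-contiguous TR grid for {roi}/{rid}")
        series.append(RoiTimeSeries(roi=str(roi), run_id=str(rid),
                                    values=grp["value"].to_numpy(), tr_s=tr_s))
    return series


def write_bold(series: list[RoiTimeSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"run_id": s.run_id, "tr_index": np.arange(s.values.size),
             "roi": s.roi, "value": s.values}
        )
        for s in sorted(series, key=lambda s: (s.run_id, s.roi))
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
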