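"""Delimited-text file formats binding the pipeline stages together.

Every file is plain CSV with a required header row, preceded by a comment
block of ``# key = value`` lines that embeds the tool version, seed, gamma,
and configuration hash, so any output file documents the run that produced
it.  Readers skip the comment block; writers always emit one.

Formats
-------
signals    time_s, ecg, ppg              (fs inferred from the time column)
beats      beat_time_s, ptt_ms
windows    window_start_s, ptt_median_ms, n_beats
cuff       time_s, sbp_mmHg, dbp_mmHg
estimates  time_s, sbp_mmHg, dbp_mmHg, model, method
params     key = value text (calibration report)
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .calibration import PenaltyFactors
from .exceptions import DataError
from .models import ModelParams
from .signals import BeatPTTSeries, SampledSignal, WindowMedianSeries

#: Relative tolerance for time-column uniformity.
FS_UNIFORMITY_PPM = 1.0


def _header_lines(meta: Optional[Dict[str, object]]) -> str:
    items = {"pttbp_version": __version__}
    if meta:
        items.update(meta)
    return "".join(f"# {k} = {v}\n" for k, v in items.items())


def write_table(path, df: pd.DataFrame, meta: Optional[Dict[str, object]] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False)


def read_table(path, required: Tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"{path} contains no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path} lacks required column(s) {missing}; has {list(df.columns)}")
    return df


def read_header(path) -> Dict[str, str]:
    """Parse the ``# key = value`` comment block of any pipeline file."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# -- signals ---------------------------------------------------------------

def write_signals(path, ecg: SampledSignal, ppg: SampledSignal,
                  meta: Optional[Dict[str, object]] = None) -> None:
    if ecg.fs != ppg.fs or ecg.samples.size != ppg.samples.size:
        raise DataError("ECG and PPG must share fs and length")
    df = pd.DataFrame({"time_s": ecg.times, "ecg": ecg.samples, "ppg": ppg.samples})
    write_table(path, df, meta)


def read_signals(path) -> Tuple[SampledSignal, SampledSignal]:
    """Read a two-channel recording; infer fs and verify uniform sampling."""
    df = read_table(path, required=("time_s", "ecg", "ppg"))
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError(f"{path}: need at least two samples to infer fs")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise DataError(f"{path}: time column must be strictly increasing")
    if np.max(np.abs(dt - dt_med)) > FS_UNIFORMITY_PPM * 1e-6 * dt_med + 1e-12:
        raise DataError(f"{path}: non-uniform time column (tolerance 1 ppm)")
    fs = 1.0 / dt_med
    return (
        SampledSignal(df["ecg"].to_numpy(dtype=float), fs, t0=float(t[0])),
        SampledSignal(df["ppg"].to_numpy(dtype=float), fs, t0=float(t[0])),
    )


# -- beats / windows -------------------------------------------------------

def write_beats(path, beats: BeatPTTSeries, meta=None) -> None:
    write_table(path, pd.DataFrame({"beat_time_s": beats.beat_times, "ptt_ms": beats.ptt}), meta)


def read_beats(path) -> BeatPTTSeries:
    df = read_table(path, required=("beat_time_s", "ptt_ms"))
    return BeatPTTSeries(df["beat_time_s"].to_numpy(float), df["ptt_ms"].to_numpy(float))


def write_windows(path, win: WindowMedianSeries, meta=None) -> None:
    df = pd.DataFrame(
        {
            "window_start_s": win.window_start,
            "ptt_median_ms": win.ptt_median,
            "n_beats": win.n_beats,
        }
    )
    meta = dict(meta or {})
    meta.setdefault("window_s", win.window_s)
    write_table(path, df, meta)


def read_windows(path, window_s: Optional[float] = None) -> WindowMedianSeries:
    df = read_table(path, required=("window_start_s", "ptt_median_ms", "n_beats"))
    if window_s is None:
        hdr = read_header(path)
        window_s = float(hdr.get("window_s", 30.0))
    return WindowMedianSeries(
        df["window_start_s"].to_numpy(float),
        df["ptt_median_ms"].to_numpy(float),
        df["n_beats"].to_numpy(int),
        window_s,
    )


# -- cuff / estimates ------------------------------------------------------

def write_cuff(path, times, sbp, dbp, meta=None) -> None:
    write_table(
        path,
        pd.DataFrame({"time_s": times, "sbp_mmHg": sbp, "dbp_mmHg": dbp}),
        meta,
    )


def read_cuff(path) -> pd.DataFrame:
    return read_table(path, required=("time_s", "sbp_mmHg", "dbp_mmHg"))


def write_estimates(path, df: pd.DataFrame, meta=None) -> None:
    write_table(path, df, meta)


def read_estimates(path) -> pd.DataFrame:
    return read_table(path, required=("time_s", "sbp_mmHg", "dbp_mmHg", "model", "method"))


# -- calibration report ----------------------------------------------------

def write_params(
    path,
    params: ModelParams,
    method: str,
    model: str,
    n: int,
    ptt_bar: Optional[float] = None,
    factors: Optional[PenaltyFactors] = None,
    meta: Optional[Dict[str, object]] = None,
) -> None:
    """Write a calibration report as ``key = value`` text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = dict(meta or {})
    lines.update(
        {
            "method": method,
            "model": model,
            "n": n,
            "ptt_bar_ms": "" if ptt_bar is None else repr(ptt_bar),
            "alpha_ptt": "" if factors is None else repr(factors.alpha_ptt),
            "alpha_sbp": "" if factors is None else repr(factors.alpha_sbp),
            "alpha_dbp": "" if factors is None else repr(factors.alpha_dbp),
            "sbp0_mmHg": repr(params.sbp0),
            "dbp0_mmHg": repr(params.dbp0),
            "pp0_mmHg": repr(params.pp0),
            "mbp0_mmHg": repr(params.mbp0),
            "ptt0_ms": repr(params.ptt0),
            "gamma_per_mmHg": repr(params.gamma),
            "mbp_footnote_form": params.mbp_footnote_form,
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(None))
        for k, v in lines.items():
            fh.write(f"{k} = {v}\n")


def read_params(path) -> Tuple[ModelParams, Dict[str, str]]:
    """Read a calibration report back into ModelParams plus raw fields."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fields: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        params = ModelParams(
            sbp0=float(fields["sbp0_mmHg"]),
            dbp0=float(fields["dbp0_mmHg"]),
            pp0=float(fields["pp0_mmHg"]),
            mbp0=float(fields["mbp0_mmHg"]),
            ptt0=float(fields["ptt0_ms"]),
            gamma=float(fields["gamma_per_mmHg"]),
            mbp_footnote_form=fields.get("mbp_footnote_form", "False") == "True",
        )
    except KeyError as exc:
        raise DataError(f"{path}: missing calibration field {exc}") from exc
    return params, fields
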