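"""Readers, writers and run configuration.

Delimited text only (comma or tab, period decimal, UTF-8, header row).
Two time-series dialects are supported: *wide* (one ``time`` column plus
one column per variable) and *long* (``time, sample, variable, value``,
where repeated time stamps define replicate samples). Readers validate
and reject malformed input with line numbers instead of coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedding import MomentSeries

log = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesMatrix",
    "read_timeseries",
    "write_timeseries",
    "read_moment_series",
    "write_moment_series",
    "RunConfig",
]

_FLOAT_FMT = "%.17g"


@dataclass
class TimeSeriesMatrix:
    """Observed state data: T time points of n variables.

    ``values`` is (T, n), or (T, S, n) when every time point carries S
    replicate samples.
    """

    times: np.ndarray
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values disagree in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.names:
            self.names = [f"x{j + 1}" for j in range(self.values.shape[-1])]
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate variable names")

    @property
    def n_vars(self) -> int:
        return self.values.shape[-1]

    @property
    def has_replicates(self) -> bool:
        return self.values.ndim == 3

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1] if self.has_replicates else 1


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: file is empty")
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    raw_names = [c.strip() for c in header.rstrip("\n").split(sep)]
    if len(raw_names) != len(set(raw_names)):
        raise ValueError(f"{path}: duplicate column names")
    try:
        # round_trip parsing: 17-significant-digit CSVs reload bit-exactly
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header line is 1
            raise ValueError(
                f"{path}: non-numeric value {df[c][bad.idxmax()]!r} in column "
                f"{c!r} at line {row}"
            )
        out[c] = coerced
    return out


def read_timeseries(path, dialect: str = "auto") -> TimeSeriesMatrix:
    """Read a wide or long delimited time-series file.

    ``dialect='auto'`` sniffs: a ``variable``/``value`` column pair means
    long format. Long files with duplicated time stamps switch on the
    replicate axis (samples per time point must be balanced).
    """
    path = Path(path)
    df = _read_table(path)
    cols = [str(c) for c in df.columns]
    lower = [c.lower() for c in cols]
    if "time" not in lower:
        raise ValueError(f"{path}: no 'time' column (found {cols})")
    tcol = cols[lower.index("time")]
    if dialect == "auto":
        dialect = "long" if {"variable", "value"} <= set(lower) else "wide"

    if dialect == "wide":
        if len(cols) != len(set(cols)):
            raise ValueError(f"{path}: duplicate column names")
        # a column named 'p' is the control-parameter track, not a variable
        var_cols = [c for c in cols if c != tcol and c != "p"]
        if not var_cols:
            raise ValueError(f"{path}: no variable columns")
        df = _numeric(df, [tcol, *var_cols], path)
        t = df[tcol].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: time column not strictly increasing")
        return TimeSeriesMatrix(times=t, values=df[var_cols].to_numpy(),
                                names=var_cols)

    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    vcol = cols[lower.index("variable")]
    ycol = cols[lower.index("value")]
    df = _numeric(df, [tcol, ycol], path)
    names = list(dict.fromkeys(df[vcol].astype(str)))
    times = np.unique(df[tcol].to_numpy())
    counts = df.groupby([tcol, vcol]).size()
    S = int(counts.iloc[0])
    if not (counts == S).all():
        raise ValueError(f"{path}: unbalanced replicate counts per (time, variable)")
    arr = np.full((times.size, S, len(names)), np.nan)
    pos = {n: j for j, n in enumerate(names)}
    tpos = {t: i for i, t in enumerate(times)}
    counters: dict[tuple, int] = {}
    for t, v, y in zip(df[tcol], df[vcol].astype(str), df[ycol]):
        r = counters.get((t, v), 0)
        counters[(t, v)] = r + 1
        arr[tpos[t], r, pos[v]] = y
    if np.isnan(arr).any():
        raise ValueError(f"{path}: missing (time, sample, variable) combinations")
    if S == 1:
        arr = arr[:, 0, :]
    return TimeSeriesMatrix(times=times, values=arr, names=names)


def write_timeseries(ts: TimeSeriesMatrix, path, parameter_track=None):
    """Write a time series as tidy CSV (wide; long when replicated).

    Floats are printed with 17 significant digits so a round trip is
    bit-exact.
    """
    path = Path(path)
    if ts.has_replicates:
        rows = []
        for i, t in enumerate(ts.times):
            for s in range(ts.n_replicates):
                for j, nm in enumerate(ts.names):
                    rows.append((t, s, nm, ts.values[i, s, j]))
        df = pd.DataFrame(rows, columns=["time", "sample", "variable", "value"])
    else:
        df = pd.DataFrame(ts.values, columns=ts.names)
        df.insert(0, "time", ts.times)
        if parameter_track is not None:
            df.insert(1, "p", np.asarray(parameter_track, dtype=float))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def trajectory_to_timeseries(traj) -> TimeSeriesMatrix:
    return TimeSeriesMatrix(times=traj.times, values=traj.states)


def write_moment_series(ms: MomentSeries, path):
    ms.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_moment_series(path) -> MomentSeries:
    df = _read_table(path)
    df = _numeric(df, list(df.columns), path)
    return MomentSeries.from_frame(df)


@dataclass
class RunConfig:
    """Validated configuration for a CLI pipeline run."""

    input: str | None = None
    model: str | None = None
    sigma: float = 1.0
    window: int = 10
    step: int = 1
    epsilon: float = 1e-3
    min_size: int = 2
    baseline_fraction: float = 0.25
    z_threshold: float = 2.0
    seed: int | None = None
    outdir: str = "."

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self):
        if self.input is not None and not Path(self.input).exists():
            raise ValueError(f"input path does not exist: {self.input}")
        if self.window < 2 or self.step < 1:
            raise ValueError("window must be >= 2 and step >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        return self
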