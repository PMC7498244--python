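"""Epoch-level data containers, CSV I/O, cleaning and timestamp alignment.

Three series types share a dense, contiguous epoch grid anchored at
``start_time``: minute-epoch activity counts from a wrist device, 30-second
PSG sleep stages, and minute-epoch binary sleep/wake states.  Gaps in input
files are represented as *missing epochs on the grid* rather than by
shortening the series, so index arithmetic for the ±2-minute scoring kernel
stays valid across gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SLEEP",
    "WAKE",
    "STAGES",
    "ActivityEpochSeries",
    "HypnogramSeries",
    "SleepWakeSeries",
    "read_activity_csv",
    "write_activity_csv",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "read_sleepwake_csv",
    "write_sleepwake_csv",
    "clean_default_runs",
    "align_series",
]

#: Binary state codes for minute-epoch sleep/wake series.
SLEEP = 1
WAKE = 0

#: AASM stage labels accepted in hypnograms.
STAGES = ("W", "N1", "N2", "N3", "REM")

_MINUTE = pd.Timedelta(seconds=60)
_HALF_MINUTE = pd.Timedelta(seconds=30)


class EpochFormatError(ValueError):
    """Raised when an epoch CSV cannot be parsed (bad timestamp/label)."""


class EpochValidationError(ValueError):
    """Raised when parsed epoch data violates a series invariant."""


def _as_bool_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.zeros(n, dtype=bool)
    out = np.asarray(mask, dtype=bool)
    if out.shape != (n,):
        raise EpochValidationError(f"mask length {out.shape} != series length {n}")
    return out


@dataclass(frozen=True)
class ActivityEpochSeries:
    """Minute-epoch activity counts for one device-night.

    ``counts`` holds one non-negative value (device vector-magnitude units)
    per contiguous 60-s epoch starting at ``start_time``; ``missing_mask``
    flags cleaned or absent epochs.  Counts are stored as floats — device
    units are not asserted to be integral.
    """

    participant_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise EpochValidationError("counts must be a 1-d sequence of length >= 1")
        mask = _as_bool_mask(self.missing_mask, counts.size)
        if np.any(counts[~mask] < 0):
            raise EpochValidationError("non-missing activity counts must be >= 0")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "missing_mask", mask)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return self.counts.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="60s")


@dataclass(frozen=True)
class HypnogramSeries:
    """30-second PSG sleep-stage sequence (AASM stages W/N1/N2/N3/REM)."""

    participant_id: str
    start_time: pd.Timestamp
    stages: np.ndarray

    def __post_init__(self):
        stages = np.asarray(self.stages, dtype="U3")
        if stages.ndim != 1 or stages.size < 2:
            raise EpochValidationError("hypnogram must have at least 2 epochs")
        bad = ~np.isin(stages, STAGES)
        if bad.any():
            raise EpochValidationError(
                f"invalid stage label(s) {sorted(set(stages[bad]))}; expected {STAGES}"
            )
        object.__setattr__(self, "stages", stages)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return self.stages.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="30s")


@dataclass(frozen=True)
class SleepWakeSeries:
    """Minute-epoch binary sleep/wake sequence.

    ``states`` uses the module constants SLEEP=1, WAKE=0.  ``hybrid_mask``
    flags minutes whose two source 30-s PSG epochs disagreed (defined only
    for collapsed PSG series; all-false otherwise).
    """

    participant_id: str
    start_time: pd.Timestamp
    states: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    hybrid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 1 or states.size < 1:
            raise EpochValidationError("states must be a 1-d sequence of length >= 1")
        mask = _as_bool_mask(self.missing_mask, states.size)
        if not np.isin(states[~mask], (SLEEP, WAKE)).all():
            raise EpochValidationError("states must be SLEEP (1) or WAKE (0)")
        hybrid = _as_bool_mask(self.hybrid_mask, states.size)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "missing_mask", mask)
        object.__setattr__(self, "hybrid_mask", hybrid)
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))

    def __len__(self) -> int:
        return self.states.size

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq="60s")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_DEFAULT_DIALECT = {"timestamp": "timestamp", "count": "count", "stage": "stage",
                    "state": "state", "participant_id": "participant_id"}


def _parse_timestamps(raw: pd.Series, path) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise EpochFormatError(
            f"{path}: unparseable timestamp {raw.iloc[row]!r} at data row {row}"
        )
    if ts.duplicated().any():
        row = int(np.flatnonzero(ts.duplicated().to_numpy())[0])
        raise EpochValidationError(f"{path}: duplicate timestamp at data row {row}")
    return ts


def _read_epoch_table(path, dialect, value_col):
    d = dict(_DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path)
    for key in ("timestamp", value_col):
        if d[key] not in df.columns:
            raise EpochFormatError(f"{path}: missing required column {d[key]!r}")
    ts = _parse_timestamps(df[d["timestamp"]], path)
    pid = ""
    if d["participant_id"] in df.columns and len(df):
        pid = str(df[d["participant_id"]].iloc[0])
    order = np.argsort(ts.to_numpy())
    return ts.iloc[order].reset_index(drop=True), df[d[value_col]].iloc[order].reset_index(drop=True), pid


def read_activity_csv(path, dialect: dict | None = None,
                      participant_id: str | None = None) -> ActivityEpochSeries:
    """Read a minute-epoch activity CSV onto a dense, contiguous minute grid.

    Epochs between the first and last timestamp that are absent from the file
    are marked missing; count values are preserved exactly.
    """
    ts, vals, pid = _read_epoch_table(path, dialect, "count")
    counts_in = pd.to_numeric(vals, errors="raise").astype(float)
    if (counts_in < 0).any():
        row = int(np.flatnonzero((counts_in < 0).to_numpy())[0])
        raise EpochValidationError(f"{path}: negative count at data row {row}")
    grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="60s")
    off = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if np.any(off % 60 != 0):
        row = int(np.flatnonzero(off % 60 != 0)[0])
        raise EpochValidationError(
            f"{path}: timestamp at data row {row} is not on the 60-s grid"
        )
    idx = (off // 60).astype(int)
    counts = np.zeros(grid.size)
    missing = np.ones(grid.size, dtype=bool)
    counts[idx] = counts_in.to_numpy()
    missing[idx] = False
    return ActivityEpochSeries(participant_id or pid, grid[0], counts, missing)


def write_activity_csv(series: ActivityEpochSeries, path) -> None:
    keep = ~series.missing_mask
    pd.DataFrame({
        "timestamp": series.timestamps[keep].strftime("%Y-%m-%dT%H:%M:%S"),
        "count": series.counts[keep],
        "participant_id": series.participant_id,
    }).to_csv(path, index=False)


def read_hypnogram_csv(path, dialect: dict | None = None,
                       participant_id: str | None = None) -> HypnogramSeries:
    """Read a 30-s hypnogram CSV.  Stage labels are case-insensitive; "R" is
    accepted for REM.  The hypnogram grid must be gap-free."""
    ts, vals, pid = _read_epoch_table(path, dialect, "stage")
    stages = vals.astype(str).str.strip().str.upper().replace({"R": "REM"})
    off = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if not np.array_equal(off, np.arange(len(ts)) * 30.0):
        raise EpochValidationError(f"{path}: hypnogram epochs must be contiguous 30-s intervals")
    return HypnogramSeries(participant_id or pid, ts.iloc[0], stages.to_numpy())


def write_hypnogram_csv(series: HypnogramSeries, path) -> None:
    pd.DataFrame({
        "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
        "stage": series.stages,
        "participant_id": series.participant_id,
    }).to_csv(path, index=False)


_STATE_ALIASES = {"S": SLEEP, "SLEEP": SLEEP, "1": SLEEP, "W": WAKE, "WAKE": WAKE, "0": WAKE}


def read_sleepwake_csv(path, dialect: dict | None = None,
                       participant_id: str | None = None) -> SleepWakeSeries:
    """Read a minute-epoch binary sleep/wake CSV ({S,W} or {sleep,wake})."""
    ts, vals, pid = _read_epoch_table(path, dialect, "state")
    labels = vals.astype(str).str.strip().str.upper()
    bad = ~labels.isin(_STATE_ALIASES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EpochFormatError(f"{path}: unrecognized state {labels.iloc[row]!r} at data row {row}")
    grid = pd.date_range(ts.iloc[0], ts.iloc[-1], freq="60s")
    off = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if np.any(off % 60 != 0):
        raise EpochValidationError(f"{path}: timestamps not on the 60-s grid")
    idx = (off // 60).astype(int)
    states = np.zeros(grid.size, dtype=np.int8)
    missing = np.ones(grid.size, dtype=bool)
    states[idx] = labels.map(_STATE_ALIASES).to_numpy(dtype=np.int8)
    missing[idx] = False
    return SleepWakeSeries(participant_id or pid, grid[0], states, missing)


def write_sleepwake_csv(series: SleepWakeSeries, path) -> None:
    keep = ~series.missing_mask
    pd.DataFrame({
        "timestamp": series.timestamps[keep].strftime("%Y-%m-%dT%H:%M:%S"),
        "state": np.where(series.states[keep] == SLEEP, "S", "W"),
        "participant_id": series.participant_id,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning and alignment
# ---------------------------------------------------------------------------

def clean_default_runs(series: ActivityEpochSeries, default_value: float = 20.0,
                       min_run: int = 5) -> tuple[ActivityEpochSeries, int]:
    """Mark runs of the device-default output value as missing.

    Inactive devices emit long constant runs of the default value (20 units);
    every maximal run of consecutive non-missing epochs equal to
    ``default_value`` with length >= ``min_run`` is marked missing.  Isolated
    genuine counts of the default value are untouched.  Returns the cleaned
    series and the number of epochs removed.  Idempotent; never alters count
    values, only missingness.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    hit = (~series.missing_mask) & (series.counts == default_value)
    missing = series.missing_mask.copy()
    removed = 0
    # maximal runs of consecutive True in `hit`
    padded = np.concatenate(([False], hit, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            missing[start:stop] = True
            removed += int(stop - start)
    return replace(series, missing_mask=missing), removed


class AlignmentError(ValueError):
    """Raised when two epoch series share no jointly valid epochs."""


def _values_of(series):
    if isinstance(series, ActivityEpochSeries):
        return series.counts
    return series.states


def align_series(a, b, *, round_offsets: bool = False) -> pd.DataFrame:
    """Pair two minute-grid series by absolute timestamp.

    Returns a DataFrame with columns ``timestamp``, ``a``, ``b`` (and
    ``hybrid_a``/``hybrid_b`` for sleep/wake inputs) containing only epochs
    present and non-missing in both inputs, in time order.  Both inputs must
    lie on commensurate minute grids; a sub-minute offset between the two
    grids raises unless ``round_offsets`` is set, in which case ``b``'s grid
    is snapped to ``a``'s by rounding to the nearest minute.
    """
    offset_s = (pd.Timestamp(b.start_time) - pd.Timestamp(a.start_time)).total_seconds()
    frac = offset_s % 60
    if frac != 0:
        if not round_offsets:
            raise AlignmentError(
                f"series grids are offset by {frac:.0f} s within the minute; "
                "pass round_offsets=True to snap to the nearest minute"
            )
        offset_s = round(offset_s / 60) * 60
    off = int(offset_s // 60)  # b's start, in a-epochs

    ia_lo, ia_hi = max(0, off), min(len(a), off + len(b))
    if ia_lo >= ia_hi:
        raise AlignmentError(
            f"no overlap between {a.start_time}..{a.timestamps[-1]} "
            f"and {b.start_time}..{b.timestamps[-1]}"
        )
    ia = np.arange(ia_lo, ia_hi)
    ib = ia - off
    valid = ~a.missing_mask[ia] & ~b.missing_mask[ib]
    if not valid.any():
        raise AlignmentError("no jointly non-missing epochs in the overlap")
    ia, ib = ia[valid], ib[valid]
    out = pd.DataFrame({
        "timestamp": a.timestamps[ia],
        "a": _values_of(a)[ia],
        "b": _values_of(b)[ib],
    })
    if isinstance(a, SleepWakeSeries):
        out["hybrid_a"] = a.hybrid_mask[ia]
    if isinstance(b, SleepWakeSeries):
        out["hybrid_b"] = b.hybrid_mask[ib]
    return out
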