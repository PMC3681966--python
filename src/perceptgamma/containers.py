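"""Core data containers shared by every pipeline stage.

All containers validate their invariants at construction time: a
``Recording`` with duplicate channel labels, an event past the end of the
signal, or an ``EpochSet`` whose label vector does not match its trial count
is rejected immediately rather than failing obscurely three stages later.

Units: signals are microvolts (µV), sampling rates Hz, epoch times seconds
relative to the lock event (0-based sample indexing throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Recognised event classes.
EVENT_CODES = frozenset(
    {"target_face", "target_guitar", "frequent", "movie_onset", "response", "trial_end"}
)

#: Recognised per-trial condition labels.
CONDITION_LABELS = frozenset({"perceived", "unperceived", "target", "frequent"})

#: Channel kinds.  BAD channels are carried along but excluded from analysis.
CHANNEL_KINDS = frozenset({"EEG", "EOG", "BAD"})


class InvariantError(ValueError):
    """A container invariant was violated at construction."""


class FormatError(IOError):
    """A file did not conform to the expected on-disk format."""


def _as_float_array(x, name, ndim):
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise InvariantError(f"{name} must be {ndim}-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvariantError(f"{name} contains non-finite values")
    return arr


class EventTable:
    """Sorted table of (sample_index, code, trial_id) rows.

    Thin, validated wrapper around a :class:`pandas.DataFrame` with columns
    ``sample``, ``code`` and ``trial``.  Rows are sorted by sample index at
    construction.
    """

    COLUMNS = ("sample", "code", "trial")

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame({"sample": [], "code": [], "trial": []})
        df = pd.DataFrame(df)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise InvariantError(f"event table missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["sample"] = df["sample"].astype(np.int64)
        df["trial"] = df["trial"].astype(np.int64)
        df["code"] = df["code"].astype(str)
        if len(df):
            if (df["sample"] < 0).any():
                raise InvariantError("negative event sample index")
            if (df["trial"] < 0).any():
                raise InvariantError("negative trial id")
            unknown = set(df["code"]) - EVENT_CODES
            if unknown:
                raise InvariantError(f"unknown event code(s): {sorted(unknown)}")
        self.df = df.sort_values("sample", kind="stable").reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows) -> "EventTable":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def select(self, code: str) -> pd.DataFrame:
        return self.df[self.df["code"] == code]

    def check_within(self, n_samples: int):
        if len(self.df) and int(self.df["sample"].max()) >= n_samples:
            raise InvariantError("event sample index beyond end of recording")


@dataclass
class Recording:
    """Continuous multi-channel recording in µV.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    sr : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names (10-20 convention for EEG).
    channel_kinds : list of str
        One of ``EEG``/``EOG``/``BAD`` per channel.
    positions : ndarray, shape (n_channels, 2) or None
        2-D scalp coordinates on the unit head circle (NaN for non-EEG).
    events : EventTable
    """

    data: np.ndarray
    sr: float
    channel_labels: list[str]
    channel_kinds: list[str]
    positions: np.ndarray | None = None
    events: EventTable = field(default_factory=EventTable)

    def __post_init__(self):
        self.data = _as_float_array(self.data, "data", 2)
        if not self.sr > 0:
            raise InvariantError(f"sampling rate must be positive, got {self.sr}")
        self.sr = float(self.sr)
        self.channel_labels = [str(x) for x in self.channel_labels]
        self.channel_kinds = [str(x) for x in self.channel_kinds]
        n = self.data.shape[0]
        if len(self.channel_labels) != n:
            raise InvariantError(
                f"{len(self.channel_labels)} labels for {n} data rows"
            )
        if len(set(self.channel_labels)) != n:
            raise InvariantError("duplicate channel labels")
        if len(self.channel_kinds) != n:
            raise InvariantError("channel_kinds length mismatch")
        bad_kinds = set(self.channel_kinds) - CHANNEL_KINDS
        if bad_kinds:
            raise InvariantError(f"unknown channel kind(s): {sorted(bad_kinds)}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (n, 2):
                raise InvariantError("positions must be (n_channels, 2)")
            for i, kind in enumerate(self.channel_kinds):
                if kind == "EEG" and not np.all(np.isfinite(self.positions[i])):
                    raise InvariantError(
                        f"EEG channel {self.channel_labels[i]} lacks a position"
                    )
        if not isinstance(self.events, EventTable):
            self.events = EventTable(self.events)
        self.events.check_within(self.data.shape[1])

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sr

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def picks(self, kind: str = "EEG") -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.channel_kinds) if k == kind], dtype=int
        )

    def copy(self, **changes) -> "Recording":
        base = dict(
            data=self.data.copy(),
            sr=self.sr,
            channel_labels=list(self.channel_labels),
            channel_kinds=list(self.channel_kinds),
            positions=None if self.positions is None else self.positions.copy(),
            events=EventTable(self.events.df),
        )
        base.update(changes)
        return Recording(**base)


@dataclass
class EpochSet:
    """Trials × channels × time array with condition labels.

    ``tmin``/``tmax`` are epoch bounds in seconds relative to the lock
    event; the time axis has ``round((tmax - tmin) * sr) + 1`` samples and
    time zero falls on the first sample at or after the lock event.
    """

    data: np.ndarray
    sr: float
    tmin: float
    tmax: float
    lock: str
    labels: list[str]
    channel_labels: list[str]
    channel_kinds: list[str]
    positions: np.ndarray | None = None
    trial_ids: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = _as_float_array(self.data, "data", 3)
        n_trials, n_ch, n_t = self.data.shape
        if not self.sr > 0:
            raise InvariantError("sampling rate must be positive")
        expected = int(round((self.tmax - self.tmin) * self.sr)) + 1
        if abs(n_t - expected) > 1:
            raise InvariantError(
                f"time axis has {n_t} samples, expected {expected} "
                f"for ({self.tmin}, {self.tmax}) s at {self.sr} Hz"
            )
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != n_trials:
            raise InvariantError("labels length must equal trial count")
        unknown = set(self.labels) - CONDITION_LABELS
        if unknown:
            raise InvariantError(f"unknown condition label(s): {sorted(unknown)}")
        if len(self.channel_labels) != n_ch or len(self.channel_kinds) != n_ch:
            raise InvariantError("channel metadata length mismatch")
        if self.trial_ids is None:
            self.trial_ids = np.arange(n_trials, dtype=np.int64)
        else:
            self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
            if self.trial_ids.shape != (n_trials,):
                raise InvariantError("trial_ids length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sr

    def picks(self, kind: str = "EEG") -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.channel_kinds) if k == kind], dtype=int
        )

    def subset(self, trial_mask) -> "EpochSet":
        trial_mask = np.asarray(trial_mask)
        if trial_mask.dtype == bool:
            idx = np.flatnonzero(trial_mask)
        else:
            idx = trial_mask.astype(int)
        return replace(
            self,
            data=self.data[idx],
            labels=[self.labels[i] for i in idx],
            trial_ids=self.trial_ids[idx],
            provenance=list(self.provenance),
        )

    def with_provenance(self, step: str) -> "EpochSet":
        out = replace(self, provenance=list(self.provenance) + [step])
        return out


class BehaviourLog:
    """Per-trial behavioural responses.

    Columns: ``trial`` (id), ``response_time`` (s, NaN if absent),
    ``perceived`` (bool), ``correct`` (bool).
    """

    COLUMNS = ("trial", "response_time", "perceived", "correct")

    def __init__(self, df: pd.DataFrame, trial_duration: float | None = None):
        df = pd.DataFrame(df)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise InvariantError(f"behaviour log missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["trial"] = df["trial"].astype(np.int64)
        df["response_time"] = df["response_time"].astype(float)
        df["perceived"] = df["perceived"].astype(bool)
        df["correct"] = df["correct"].astype(bool)
        rt = df["response_time"]
        present = rt.notna()
        if (rt[present] <= 0).any():
            raise InvariantError("response_time must be positive when present")
        if trial_duration is not None and (rt[present] > trial_duration).any():
            raise InvariantError("response_time beyond trial duration")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def __eq__(self, other):
        return isinstance(other, BehaviourLog) and self.df.equals(other.df)

    def response_time_of(self, trial_id: int) -> float:
        row = self.df[self.df["trial"] == trial_id]
        if not len(row):
            return np.nan
        return float(row["response_time"].iloc[0])
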