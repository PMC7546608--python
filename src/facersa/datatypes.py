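"""Shared domain types for the time-resolved RSA pipeline.

The pipeline revolves around a small set of containers:

* :class:`FaceSet` — the stimulus identities (the condition axis of every
  RDM), with the person attributes and the group-average ("database")
  attractiveness rating.
* :class:`SessionBehavior` — one participant's trialwise yes/no responses
  and 1–7 attractiveness ratings.
* :class:`EpochSet` — one participant's epoched EEG (trials × channels ×
  samples) with timing metadata and a face label per trial.
* :class:`RDM` — a symmetric condition × condition dissimilarity matrix
  with an empty (NaN) diagonal; the lingua franca between the neural and
  predictor sides of the analysis.
* :class:`TimeBinGrid` — the contiguous equal-width time bins the analysis
  is resolved over.

Undefined/flagged RDM entries (e.g. correlations with a zero-variance
pattern) are stored as NaN and removed pairwise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FaceSet",
    "SessionBehavior",
    "EpochSet",
    "RDM",
    "TimeBinGrid",
]


class ValidationError(ValueError):
    """An input table or array violated a structural invariant."""


FACE_COLUMNS = ("face_id", "sex", "ethnicity", "age", "db_rating")
BEHAVIOR_COLUMNS = ("trial_index", "face_id", "yesno", "rating")


@dataclass
class FaceSet:
    """The stimulus set: one row per face identity.

    Columns: ``face_id`` (unique), ``sex`` (male/female), ``ethnicity``
    (kept verbatim; binarised only when building predictor RDMs), ``age``
    (years, > 0) and ``db_rating`` (group-average attractiveness in [1, 7]).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FACE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"face metadata missing column(s): {missing}")
        t = self.table.reset_index(drop=True)
        dup = t["face_id"][t["face_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate face_id: {sorted(set(dup))}")
        if t[list(FACE_COLUMNS)].isna().any().any():
            bad = int(t[list(FACE_COLUMNS)].isna().any(axis=1).idxmax())
            raise ValidationError(f"missing attribute in face row {bad}")
        rating = t["db_rating"].to_numpy(float)
        if ((rating < 1) | (rating > 7)).any():
            bad = t.loc[(rating < 1) | (rating > 7), "face_id"].iloc[0]
            raise ValidationError(
                f"rating out of range [1, 7] for face_id {bad!r}"
            )
        age = t["age"].to_numpy(float)
        if (age <= 0).any():
            bad = t.loc[age <= 0, "face_id"].iloc[0]
            raise ValidationError(f"non-positive age for face_id {bad!r}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def face_ids(self) -> list[str]:
        return [str(f) for f in self.table["face_id"]]

    def attribute(self, name: str) -> np.ndarray:
        """Return one attribute column aligned with :attr:`face_ids`."""
        if name not in self.table.columns:
            raise KeyError(name)
        return self.table[name].to_numpy()


@dataclass
class SessionBehavior:
    """One participant's behavioural responses, one row per trial.

    ``yesno`` uses the coding 1 = "yes, attractive", 2 = "no"; ``rating``
    is the integer 1–7 attractiveness judgment. Rows are kept sorted by
    ``trial_index``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BEHAVIOR_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"behaviour table missing column(s): {missing}")
        t = self.table.sort_values("trial_index").reset_index(drop=True)
        if len(t):
            yesno = t["yesno"].to_numpy()
            if not np.isin(yesno, (1, 2)).all():
                row = int(np.flatnonzero(~np.isin(yesno, (1, 2)))[0])
                raise ValidationError(
                    f"yesno must be 1 or 2; got {yesno[row]!r} in row {row}"
                )
            rating = t["rating"].to_numpy(float)
            ok = (rating == np.round(rating)) & (rating >= 1) & (rating <= 7)
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise ValidationError(
                    f"rating must be an integer in [1, 7]; got "
                    f"{t['rating'].iloc[row]!r} in row {row}"
                )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def face_ids(self) -> np.ndarray:
        return self.table["face_id"].to_numpy(str)


@dataclass
class EpochSet:
    """Epoched EEG for one participant.

    ``data`` is trials × channels × samples (microvolts), sampled at ``fs``
    Hz with the first sample at ``t0_ms`` relative to stimulus onset.
    ``face_label[i]`` names the face shown on trial ``i``.
    """

    participant_id: str
    data: np.ndarray
    fs: float
    t0_ms: float
    face_label: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"epoch data must be trials × channels × samples; "
                f"got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive; got {self.fs}")
        self.face_label = np.asarray(self.face_label, dtype=str)
        if self.face_label.shape != (self.data.shape[0],):
            raise ValidationError(
                f"face_label length {self.face_label.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        end = self.t0_ms + self.data.shape[2] * 1000.0 / self.fs
        if not (self.t0_ms <= 0.0 <= end):
            raise ValidationError(
                f"epoch window [{self.t0_ms}, {end}] ms does not contain "
                "stimulus onset"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass
class RDM:
    """A symmetric condition × condition dissimilarity matrix.

    The diagonal is always NaN ("empty"): self-dissimilarity is never
    estimated. Off-diagonal NaNs flag undefined entries (e.g. a
    zero-variance pattern), which downstream correlations remove pairwise.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        v = np.array(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(
                f"RDM values shape {v.shape} does not match {n} labels"
            )
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("RDM is not symmetric")
        np.fill_diagonal(v, np.nan)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def align(self, labels: list[str]) -> "RDM":
        """Return a copy reordered to ``labels`` (same label set required)."""
        labels = [str(x) for x in labels]
        if labels == self.labels:
            return self
        if sorted(labels) != sorted(self.labels):
            raise ValidationError("cannot align RDMs with different label sets")
        idx = [self.labels.index(lab) for lab in labels]
        return RDM(labels, self.values[np.ix_(idx, idx)])


@dataclass
class TimeBinGrid:
    """Contiguous equal-width time bins over the epoch.

    ``starts_ms[i] .. ends_ms[i]`` is bin ``i``'s window; each bin spans
    ``samples_per_bin`` consecutive samples at rate ``fs``.
    """

    starts_ms: np.ndarray
    ends_ms: np.ndarray
    samples_per_bin: int
    fs: float
    sample_offsets: np.ndarray = field(default=None)  # first sample index per bin

    def __post_init__(self) -> None:
        self.starts_ms = np.asarray(self.starts_ms, dtype=float)
        self.ends_ms = np.asarray(self.ends_ms, dtype=float)
        if self.sample_offsets is None:
            self.sample_offsets = np.arange(len(self.starts_ms)) * self.samples_per_bin
        self.sample_offsets = np.asarray(self.sample_offsets, dtype=int)
        widths = self.ends_ms - self.starts_ms
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValidationError("time bins must have equal width")
        if len(widths) > 1 and not np.allclose(
            self.starts_ms[1:], self.ends_ms[:-1]
        ):
            raise ValidationError("time bins must be contiguous")

    @property
    def n_bins(self) -> int:
        return len(self.starts_ms)

    def window(self, i: int) -> tuple[float, float]:
        return float(self.starts_ms[i]), float(self.ends_ms[i])

    def window_label(self, i: int) -> str:
        a, b = self.window(i)
        return f"{a:g}..{b:g} ms"
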