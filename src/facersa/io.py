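"""Readers and writers for the on-disk artifacts.

Delimited text (CSV with header row) carries the face metadata, behaviour
tables and RDMs; epoched EEG lives in one self-describing ``.npz``
container per participant (data + sampling rate + timing + labels), so the
split-half estimator can draw whole-session random splits. RDM files write
the empty diagonal as the sentinel ``NA`` to keep the invariant visible on
disk.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BEHAVIOR_COLUMNS,
    RDM,
    EpochSet,
    FaceSet,
    SessionBehavior,
    ValidationError,
)

__all__ = [
    "read_face_metadata",
    "read_behavior",
    "read_epochs",
    "write_epochs",
    "read_rdm",
    "write_rdm",
]


def read_face_metadata(path: str | Path) -> FaceSet:
    """Read a face metadata CSV (face_id, sex, ethnicity, age, db_rating).

    Ethnicity is kept verbatim; the Caucasian/non-Caucasian binarisation is
    an analysis choice applied only when building predictor RDMs.
    """
    table = pd.read_csv(path, dtype={"face_id": str})
    return FaceSet(table)


def read_behavior(path: str | Path, faces: FaceSet) -> SessionBehavior:
    """Read one participant's behaviour CSV, validated against ``faces``."""
    table = pd.read_csv(path, dtype={"face_id": str})
    if len(table) == 0:
        warnings.warn(f"behaviour table {path} is empty", stacklevel=2)
        table = pd.DataFrame({c: [] for c in BEHAVIOR_COLUMNS})
    behavior = SessionBehavior(table)
    known = set(faces.face_ids)
    unknown = sorted(set(behavior.face_ids) - known)
    if unknown:
        raise ValidationError(
            f"behaviour table references unknown face_id(s): {unknown[:5]}"
        )
    return behavior


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` to a ``.npz`` container (lossless)."""
    np.savez(
        path,
        data=epochs.data,
        fs=np.array(epochs.fs, dtype=float),
        t0_ms=np.array(epochs.t0_ms, dtype=float),
        face_label=np.asarray(epochs.face_label, dtype=str),
        channel_names=np.asarray(epochs.channel_names, dtype=str),
        participant_id=np.array(str(epochs.participant_id)),
    )


def read_epochs(path: str | Path) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs`."""
    with np.load(path, allow_pickle=False) as f:
        return EpochSet(
            participant_id=str(f["participant_id"]),
            data=f["data"],
            fs=float(f["fs"]),
            t0_ms=float(f["t0_ms"]),
            face_label=f["face_label"],
            channel_names=[str(c) for c in f["channel_names"]],
        )


def write_rdm(rdm: RDM, path: str | Path) -> None:
    """Write an RDM as CSV with a label header row/column; diagonal as NA."""
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, na_rep="NA", float_format="%.10g")


def read_rdm(path: str | Path) -> RDM:
    """Read an RDM CSV written by :func:`write_rdm`."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError(
            f"RDM file {path} is not square: shape {values.shape}"
        )
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValidationError(f"RDM file {path}: row/column labels differ")
    return RDM(labels, values)
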