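"""Predictor RDM construction.

Three families of hypothesis RDMs are built over the same face labels as
the neural RDMs:

* attractiveness — absolute differences of the group-average ("database")
  rating and of each participant's own mean yes/no response (coded 1/2)
  and mean 1–7 rating;
* person attributes — same/different sex, same/different binarised
  ethnicity, absolute age difference;
* feature activations — 1 − Pearson correlation between the activation
  vectors of two faces in one model layer (e.g. a deep network trained on
  face recognition).

Because participants can respond differently across repetitions of the
same face, trialwise responses are first averaged per face; the mean keeps
the graded information a modal response would discard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import RDM, FaceSet, SessionBehavior, ValidationError

__all__ = [
    "PerFaceResponses",
    "ActivationMatrix",
    "aggregate_responses",
    "abs_diff_rdm",
    "categorical_rdm",
    "activation_rdm",
    "binarize_ethnicity",
    "build_predictor_suite",
]


@dataclass
class PerFaceResponses:
    """Per-face summaries of one participant's responses.

    ``mean_yesno`` averages the 1/2 yes/no codes and ``mean_rating`` the
    1–7 ratings over that face's trials.
    """

    table: pd.DataFrame  # columns: face_id, mean_yesno, mean_rating, n_trials

    @property
    def face_ids(self) -> list[str]:
        return [str(f) for f in self.table["face_id"]]


@dataclass
class ActivationMatrix:
    """Faces × features activations of one model layer, in face-label order."""

    layer_name: str
    face_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.face_ids):
            raise ValidationError(
                f"activation matrix {self.layer_name}: shape "
                f"{self.values.shape} does not match {len(self.face_ids)} faces"
            )
        if self.values.shape[1] < 2:
            raise ValidationError(
                f"activation matrix {self.layer_name}: need >= 2 features"
            )


def aggregate_responses(behavior: SessionBehavior) -> PerFaceResponses:
    """Average yes/no codes and ratings per face across repetitions."""
    if len(behavior) == 0:
        raise ValidationError("cannot aggregate an empty behaviour table")
    grouped = behavior.table.groupby("face_id", sort=True)
    table = grouped.agg(
        mean_yesno=("yesno", "mean"),
        mean_rating=("rating", "mean"),
        n_trials=("rating", "size"),
    ).reset_index()
    return PerFaceResponses(table)


def abs_diff_rdm(values: np.ndarray, labels: list[str]) -> RDM:
    """RDM of absolute pairwise differences of one scalar per face."""
    v = np.asarray(values, dtype=float)
    if v.shape != (len(labels),):
        raise ValidationError(
            f"{len(labels)} labels but values of shape {v.shape}"
        )
    if not np.isfinite(v).all():
        bad = labels[int(np.flatnonzero(~np.isfinite(v))[0])]
        raise ValidationError(f"missing value for label {bad!r}")
    d = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(d, np.nan)
    return RDM(list(labels), d)


def categorical_rdm(categories: np.ndarray, labels: list[str]) -> RDM:
    """0/1 RDM: 0 when two faces share a category, 1 otherwise."""
    c = np.asarray(categories)
    if c.shape != (len(labels),):
        raise ValidationError(
            f"{len(labels)} labels but categories of shape {c.shape}"
        )
    if pd.isna(c).any():
        bad = labels[int(np.flatnonzero(pd.isna(c))[0])]
        raise ValidationError(f"missing category for label {bad!r}")
    d = (c[:, None] != c[None, :]).astype(float)
    np.fill_diagonal(d, np.nan)
    return RDM(list(labels), d)


def activation_rdm(acts: ActivationMatrix) -> RDM:
    """Correlation-distance RDM (1 − Pearson r) between activation vectors.

    Zero-variance activation vectors yield flagged (NaN) entries.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(acts.values)
    d = 1.0 - corr
    np.fill_diagonal(d, np.nan)
    return RDM(list(acts.face_ids), d)


def binarize_ethnicity(
    ethnicity: np.ndarray, reference: str = "caucasian"
) -> np.ndarray:
    """Collapse ethnicity to {reference, other} (case-insensitive match)."""
    e = np.asarray(ethnicity, dtype=str)
    return np.where(np.char.lower(e) == reference.lower(), reference, "other")


def build_predictor_suite(
    faces: FaceSet,
    responses: PerFaceResponses,
    activations: list[ActivationMatrix] | None = None,
    ethnicity_reference: str = "caucasian",
) -> dict[str, RDM]:
    """Build the full named predictor suite over the FaceSet label order.

    Keys: ``db_rating``, ``yesno``, ``rating``, ``sex``, ``ethnicity``,
    ``age``, plus one key per activation layer. All RDMs share the
    FaceSet's label order.
    """
    labels = faces.face_ids
    resp = responses.table.set_index("face_id")
    missing = [f for f in labels if f not in resp.index]
    if missing:
        raise ValidationError(
            f"responses missing for face_id(s): {missing[:5]}"
        )
    resp = resp.loc[labels]
    suite = {
        "db_rating": abs_diff_rdm(faces.attribute("db_rating"), labels),
        "yesno": abs_diff_rdm(resp["mean_yesno"].to_numpy(), labels),
        "rating": abs_diff_rdm(resp["mean_rating"].to_numpy(), labels),
        "sex": categorical_rdm(faces.attribute("sex"), labels),
        "ethnicity": categorical_rdm(
            binarize_ethnicity(faces.attribute("ethnicity"), ethnicity_reference),
            labels,
        ),
        "age": abs_diff_rdm(faces.attribute("age"), labels),
    }
    for acts in activations or []:
        if [str(f) for f in acts.face_ids] != labels:
            raise ValidationError(
                f"activation matrix {acts.layer_name}: face order does not "
                "match the FaceSet"
            )
        if acts.layer_name in suite:
            raise ValidationError(f"duplicate predictor name {acts.layer_name!r}")
        suite[acts.layer_name] = activation_rdm(acts)
    return suite
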