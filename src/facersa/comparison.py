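"""Neural–predictor RDM comparison: (partial) Spearman timecourses.

Only the lower off-diagonal triangle of each RDM enters the comparison
(the diagonal is always discarded). Plain fits are Spearman correlations
with average-rank tie handling; partial fits rank-transform all vectors,
residualise both the neural and predictor ranks on an intercept plus the
control ranks by least squares, and correlate the residuals — i.e.
correlations between the residual values after the controls have been
regressed out of both variables of interest. Correlations are Fisher
z-transformed (atanh, with rho clipped away from ±1) for group
statistics.

Flagged (NaN) RDM entries are removed pairwise, identically across every
vector of one fit, before ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import RDM, TimeBinGrid, ValidationError

__all__ = [
    "TimecourseFit",
    "vectorize_lower",
    "spearman_fit",
    "partial_spearman_fit",
    "fit_timecourse",
]

_CLIP = 1.0 - 1e-12  # keep atanh finite on degenerate (|rho| = 1) inputs


@dataclass
class TimecourseFit:
    """One predictor's per-bin (partial) correlation with the neural RDMs."""

    participant_id: str
    predictor_name: str
    control_names: tuple[str, ...]
    rho: np.ndarray  # per-bin Spearman / partial Spearman
    z: np.ndarray  # Fisher-transformed rho
    bin_starts_ms: np.ndarray
    bin_ends_ms: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.rho)


def vectorize_lower(rdm: RDM) -> np.ndarray:
    """Lower off-diagonal triangle in row-major order (n(n−1)/2 entries).

    Entry order is (1,0), (2,0), (2,1), (3,0), … — the same everywhere in
    the package. Flagged entries stay NaN and are removed pairwise
    downstream.
    """
    i, j = np.tril_indices(rdm.n, k=-1)
    return rdm.values[i, j]


def _fisher_z(rho: float) -> float:
    if not np.isfinite(rho):
        return float("nan")
    return float(np.arctanh(np.clip(rho, -_CLIP, _CLIP)))


def partial_spearman_fit(
    neural: RDM, predictor: RDM, controls: list[RDM] | tuple[RDM, ...] = ()
) -> tuple[float, float]:
    """Partial Spearman correlation of a predictor with a neural RDM.

    Returns ``(rho, z)``. With no controls this is exactly the Spearman
    correlation of the lower-triangle vectors. A constant vector after
    pairwise deletion makes the correlation undefined; ``(nan, nan)`` is
    returned. A vector fully explained by the controls (e.g. a predictor
    controlled by itself) yields ``(0.0, 0.0)``. Collinear control
    columns are harmless for the residuals
    (the projection is onto their column space) but trigger a warning.
    """
    predictor = predictor.align(neural.labels)
    vectors = [vectorize_lower(neural), vectorize_lower(predictor)]
    for c in controls:
        vectors.append(vectorize_lower(c.align(neural.labels)))
    mask = np.all(np.isfinite(vectors), axis=0)
    if mask.sum() < 3:
        return float("nan"), float("nan")
    ranks = [stats.rankdata(v[mask]) for v in vectors]
    x, y = ranks[0], ranks[1]
    sx0 = float(np.linalg.norm(x - x.mean()))
    sy0 = float(np.linalg.norm(y - y.mean()))
    if sx0 == 0.0 or sy0 == 0.0:
        return float("nan"), float("nan")
    design = np.column_stack([np.ones(mask.sum())] + ranks[2:])
    coef, _, rank, _ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "collinear control RDMs; redundant directions dropped",
            stacklevel=2,
        )
    resid = np.column_stack([x, y]) - design @ coef
    sx = float(np.sqrt(resid[:, 0] @ resid[:, 0]))
    sy = float(np.sqrt(resid[:, 1] @ resid[:, 1]))
    # a variable fully explained by the controls has no residual variance
    # left to correlate: its partial correlation is zero by convention
    if sx < 1e-8 * sx0 or sy < 1e-8 * sy0:
        return 0.0, 0.0
    rho = float(resid[:, 0] @ resid[:, 1] / (sx * sy))
    return rho, _fisher_z(rho)


def spearman_fit(neural: RDM, predictor: RDM) -> tuple[float, float]:
    """Spearman correlation (average ranks) of two RDMs' lower triangles."""
    return partial_spearman_fit(neural, predictor, ())


def fit_timecourse(
    neural_rdms: list[RDM],
    predictors: dict[str, RDM],
    analyses: list[tuple[str, tuple[str, ...]]],
    grid: TimeBinGrid,
    participant_id: str = "",
) -> list[TimecourseFit]:
    """Fit every requested (predictor, controls) pair across all time bins.

    ``analyses`` lists ``(predictor_name, control_names)`` pairs; names
    index into ``predictors``. Deterministic — no randomness is involved.
    """
    if len(neural_rdms) != grid.n_bins:
        raise ValidationError(
            f"{len(neural_rdms)} neural RDMs for {grid.n_bins} bins"
        )
    fits = []
    for predictor_name, control_names in analyses:
        if predictor_name not in predictors:
            raise ValidationError(f"unknown predictor {predictor_name!r}")
        for c in control_names:
            if c not in predictors:
                raise ValidationError(f"unknown control predictor {c!r}")
        controls = [predictors[c] for c in control_names]
        rho = np.empty(grid.n_bins)
        z = np.empty(grid.n_bins)
        for i, neural in enumerate(neural_rdms):
            rho[i], z[i] = partial_spearman_fit(
                neural, predictors[predictor_name], controls
            )
        fits.append(
            TimecourseFit(
                participant_id=participant_id,
                predictor_name=predictor_name,
                control_names=tuple(control_names),
                rho=rho,
                z=z,
                bin_starts_ms=grid.starts_ms.copy(),
                bin_ends_ms=grid.ends_ms.copy(),
            )
        )
    return fits
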