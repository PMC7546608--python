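"""Group-level inference across participants per time bin.

Per bin, the participants' Fisher-z correlations are tested against zero
with a one-sided one-sample t-test (positive correlations are the
hypothesised direction in RSA). Benjamini–Hochberg FDR correction is
applied across all time bins, pre-stimulus bins included by default.
Effect sizes use the one-sample identity d = t/√n. Summaries report the
peak bin (maximal t among FDR-significant bins) and the earliest
FDR-significant bin — the onset of reliable information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparison import TimecourseFit
from .datatypes import ValidationError

__all__ = [
    "GroupStatResult",
    "ttest_onesided",
    "cohens_d_from_t",
    "fdr_bh",
    "summarize",
]


@dataclass
class GroupStatResult:
    """Per-bin group statistics plus peak / onset summaries for one analysis."""

    predictor_name: str
    control_names: tuple[str, ...]
    bin_starts_ms: np.ndarray
    bin_ends_ms: np.ndarray
    mean_z: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    p_corr: np.ndarray
    d: np.ndarray
    significant: np.ndarray  # p_corr < alpha mask
    alpha: float
    peak_bin: int  # index of max t among significant bins (fallback: global)
    peak_is_significant: bool
    earliest_significant_bin: int | None

    @property
    def peak_window_ms(self) -> tuple[float, float]:
        return (
            float(self.bin_starts_ms[self.peak_bin]),
            float(self.bin_ends_ms[self.peak_bin]),
        )

    @property
    def earliest_window_ms(self) -> tuple[float, float] | None:
        i = self.earliest_significant_bin
        if i is None:
            return None
        return float(self.bin_starts_ms[i]), float(self.bin_ends_ms[i])


def ttest_onesided(values: np.ndarray) -> tuple[float, int, float]:
    """One-sample t-test of mean > 0. Returns ``(t, df, p)``.

    Zero-variance input yields a flagged ``(nan, df, nan)`` result.
    Near-zero variance (e.g. every participant's correlation saturated at
    the same ceiling value) legitimately produces very large t; scipy's
    precision warning for that case is suppressed.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    if n < 2:
        raise ValidationError(f"need >= 2 finite values for a t-test; got {n}")
    if np.ptp(values) == 0.0:
        return float("nan"), n - 1, float("nan")
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="Precision loss occurred", category=RuntimeWarning
        )
        res = stats.ttest_1samp(values, 0.0, alternative="greater")
    return float(res.statistic), n - 1, float(res.pvalue)


def cohens_d_from_t(t: float, n: int) -> float:
    """One-sample effect size d = t/√n (rounding happens only at reporting)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return float(t) / float(np.sqrt(n))


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment across a family of p-values.

    Returns ``(adjusted_p, significant_mask)`` with ``mask = adjusted < q``.
    NaN p-values (flagged bins) stay NaN and are never significant.
    """
    p = np.asarray(pvals, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan)
    mask = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, adj, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")
        adjusted[finite] = adj
        mask[finite] = adj < q
    return adjusted, mask


def summarize(
    fits: list[TimecourseFit], alpha: float = 0.05
) -> GroupStatResult:
    """Group statistics over participants for one (predictor, controls) pair.

    All fits must share the predictor, controls and bin grid. Per bin:
    one-sided t over the participants' z values; then BH-FDR across bins;
    d = t/√n. The peak is the maximal-t bin among FDR-significant bins
    (global maximum, flagged, when none survives).
    """
    if not fits:
        raise ValidationError("no fits supplied")
    first = fits[0]
    for f in fits[1:]:
        if (
            f.predictor_name != first.predictor_name
            or f.control_names != first.control_names
            or not np.array_equal(f.bin_starts_ms, first.bin_starts_ms)
        ):
            raise ValidationError(
                "fits mix predictors, controls or bin grids"
            )
    z = np.stack([f.z for f in fits])  # participants × bins
    n_bins = z.shape[1]
    t = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    dfs = []
    for i in range(n_bins):
        ti, dfi, pi = ttest_onesided(z[:, i])
        t[i], p[i] = ti, pi
        dfs.append(dfi)
    df = int(max(dfs))
    p_corr, sig = fdr_bh(p, q=alpha)
    n = len(fits)
    d = t / np.sqrt(n)
    if sig.any():
        candidates = np.flatnonzero(sig)
        peak = int(candidates[np.nanargmax(t[candidates])])
        peak_sig = True
        earliest = int(candidates[0])
    else:
        peak = int(np.nanargmax(t)) if np.isfinite(t).any() else 0
        peak_sig = False
        earliest = None
    return GroupStatResult(
        predictor_name=first.predictor_name,
        control_names=first.control_names,
        bin_starts_ms=first.bin_starts_ms.copy(),
        bin_ends_ms=first.bin_ends_ms.copy(),
        mean_z=np.nanmean(z, axis=0),
        t=t,
        df=df,
        p=p,
        p_corr=p_corr,
        d=d,
        significant=sig,
        alpha=alpha,
        peak_bin=peak,
        peak_is_significant=peak_sig,
        earliest_significant_bin=earliest,
    )
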