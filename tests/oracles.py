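"""Independent straight-line oracles for the estimator and statistics.

These deliberately avoid the package's code paths: PCA is done by
eigendecomposition of the feature covariance (not SVD), condition means
are formed from denoised trials (not denoised means), correlations are
explicit loops, and ranks are counted by hand. They exist only to pin the
implementations down on small instances.
"""

from __future__ import annotations

import numpy as np


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y)))


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) computed by counting, not by sorting tricks."""
    values = np.asarray(values, float)
    out = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        ties = np.sum(values == v)
        # ranks occupied by the tie group: less+1 .. less+ties
        out[i] = less + (ties + 1) / 2.0
    return out


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    return pearson(average_ranks(x), average_ranks(y))


def partial_corr_single_control(x: np.ndarray, y: np.ndarray, c: np.ndarray) -> float:
    """Closed-form first-order partial correlation on average ranks."""
    rx, ry, rc = average_ranks(x), average_ranks(y), average_ranks(c)
    r_xy = pearson(rx, ry)
    r_xc = pearson(rx, rc)
    r_yc = pearson(ry, rc)
    return (r_xy - r_xc * r_yc) / np.sqrt((1 - r_xc**2) * (1 - r_yc**2))


def split_half_pca_rdm_oracle(
    patterns: np.ndarray,
    labels: np.ndarray,
    variance_threshold: float,
    n_repetitions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Literal re-implementation of the split-half PCA RDM estimator.

    Consumes randomness exactly as documented by the estimator: per
    repetition, for each condition in sorted label order, one permutation
    of its trial indices plus one uniform draw when the count is odd.
    """
    patterns = np.asarray(patterns, float)
    labels = np.asarray(labels, str)
    conds = sorted(set(labels.tolist()))
    groups = {c: np.flatnonzero(labels == c) for c in conds}
    n_cond = len(conds)

    def half(fit_rows: list[int], test_rows: dict[str, list[int]]) -> np.ndarray:
        fit = patterns[np.array(fit_rows)]
        mean = fit.mean(axis=0)
        centred = fit - mean
        cov = centred.T @ centred  # unnormalised; ratios are what matter
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        cum = np.cumsum(eigvals) / eigvals.sum()
        k = 1
        while cum[k - 1] < variance_threshold - 1e-12:
            k += 1
        v = eigvecs[:, :k]
        means = np.empty((n_cond, patterns.shape[1]))
        for ci, c in enumerate(conds):
            rows = patterns[np.array(test_rows[c])]
            denoised = (rows - mean) @ v @ v.T + mean
            means[ci] = denoised.mean(axis=0)
        rdm = np.empty((n_cond, n_cond))
        for i in range(n_cond):
            for j in range(n_cond):
                rdm[i, j] = 1.0 - pearson(means[i], means[j])
        return rdm

    total = np.zeros((n_cond, n_cond))
    for _ in range(n_repetitions):
        a: dict[str, list[int]] = {}
        b: dict[str, list[int]] = {}
        for c in conds:
            perm = rng.permutation(groups[c])
            n_a = len(perm) // 2
            if len(perm) % 2 and rng.random() < 0.5:
                n_a += 1
            a[c] = list(perm[:n_a])
            b[c] = list(perm[n_a:])
        a_all = [i for c in conds for i in a[c]]
        b_all = [i for c in conds for i in b[c]]
        total += 0.5 * (half(a_all, b) + half(b_all, a))
    rdm = total / n_repetitions
    np.fill_diagonal(rdm, np.nan)
    return rdm


def activation_rdm_oracle(acts: np.ndarray) -> np.ndarray:
    """Double-loop 1 − Pearson over rows."""
    n = acts.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = 1.0 - pearson(acts[i], acts[j])
    return out
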