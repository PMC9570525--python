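"""Independent brute-force reference implementations used only by tests.

Everything here is written as explicit per-element loops against the
mathematical definitions, deliberately sharing no code with the package, so
that agreement with the vectorised implementations is a real check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm


def kernel_cdf_brute(x: np.ndarray) -> np.ndarray:
    """Gaussian-kernel CDF statistic by direct double summation."""
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    z = np.empty_like(x)
    for i in range(n_genes):
        s = float(np.std(x[i], ddof=1))
        if s == 0:
            z[i, :] = 0.5
            continue
        h = s / 4.0
        for j in range(n_samples):
            total = 0.0
            for k in range(n_samples):
                total += norm.cdf((x[i, j] - x[i, k]) / h)
            z[i, j] = total / n_samples
    return z


def _descending_order(values: np.ndarray) -> list[int]:
    """Indices sorted by decreasing value, ties by first occurrence."""
    return sorted(range(len(values)), key=lambda i: (-values[i], i))


def gsva_brute(x: np.ndarray, set_indices, tau: float = 1.0) -> np.ndarray:
    """Full random-walk GSVA score for one gene set, looped per sample."""
    z = kernel_cdf_brute(x)
    n_genes, n_samples = x.shape
    members = set(set_indices)
    m = len(members)
    scores = np.empty(n_samples)
    for j in range(n_samples):
        order = _descending_order(z[:, j])
        weights = [abs(n_genes / 2.0 - (p + 1)) ** tau for p in range(n_genes)]
        denom = sum(w for p, w in enumerate(weights) if order[p] in members)
        walk, best_pos, best_neg = 0.0, 0.0, 0.0
        for p, gene in enumerate(order):
            if gene in members:
                walk += weights[p] / denom if denom > 0 else 0.0
            else:
                walk -= 1.0 / (n_genes - m)
            best_pos = max(best_pos, walk)
            best_neg = min(best_neg, walk)
        scores[j] = best_pos + best_neg
    return scores


def ssgsea_brute(x: np.ndarray, set_indices, alpha: float = 0.25) -> np.ndarray:
    """Position-by-position ssGSEA summation for one gene set."""
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    members = set(set_indices)
    m = len(members)
    scores = np.empty(n_samples)
    for j in range(n_samples):
        order = _descending_order(x[:, j])
        denom = 0.0
        for p, gene in enumerate(order):
            if gene in members:
                denom += (n_genes - p) ** alpha  # rank N at the top of the list
        total, cum_in, cum_out = 0.0, 0.0, 0.0
        for p, gene in enumerate(order):
            if gene in members:
                cum_in += (n_genes - p) ** alpha / denom
            else:
                cum_out += 1.0 / (n_genes - m)
            total += cum_in - cum_out
        scores[j] = total
    return scores


def cox_loglik_brute(beta: float, time, event, x) -> float:
    """Log partial likelihood of a one-covariate Cox model (no ties)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def cox_mle_brute(time, event, x) -> float:
    """Maximise the hand-written partial likelihood over a scalar beta."""
    res = minimize_scalar(
        lambda b: -cox_loglik_brute(b, time, event, x),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def mann_whitney_auc(marker, labels) -> float:
    """AUC by exhaustive pair counting; tied markers count 1/2."""
    marker = np.asarray(marker, float)
    labels = np.asarray(labels).astype(int)
    pos = marker[labels == 1]
    neg = marker[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))
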