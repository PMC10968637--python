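"""Independent brute-force reference implementations used only by tests.

Each function is a straight-line transcription of the defining formula,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def balanced_accuracy(true, pred) -> float:
    true = list(true)
    pred = list(pred)
    recalls = []
    for cls in sorted(set(true)):
        hits = sum(1 for t, p in zip(true, pred) if t == cls and p == cls)
        total = sum(1 for t in true if t == cls)
        recalls.append(hits / total)
    return sum(recalls) / len(recalls)


def pearson(a, b) -> float:
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])


def corr_index(x_err, x_cor) -> float:
    return 1.0 - pearson(x_err, x_cor)


def f_score(pos, neg) -> float:
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    grand = np.concatenate([pos, neg]).mean()
    m_p, m_n = pos.mean(), neg.mean()
    num = (m_p - grand) ** 2 + (m_n - grand) ** 2
    b_p = float(((pos - m_p) ** 2).sum())
    b_n = float(((neg - m_n) ** 2).sum())
    denom = b_p / (len(pos) - 1) + b_n / (len(neg) - 1)
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return num / denom


def fisher_index(pos, neg) -> float:
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    num = abs(pos.mean() - neg.mean())
    denom = pos.var(ddof=1) + neg.var(ddof=1)
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return num / denom


def canonical_correlations(x, y) -> np.ndarray:
    """Canonical correlations of two d x samples matrices via the classical
    covariance-whitening route (variables = rows, observations = columns)."""
    x = np.asarray(x, float) - np.asarray(x, float).mean(axis=1, keepdims=True)
    y = np.asarray(y, float) - np.asarray(y, float).mean(axis=1, keepdims=True)
    n = x.shape[1]
    cxx = x @ x.T / (n - 1)
    cyy = y @ y.T / (n - 1)
    cxy = x @ y.T / (n - 1)
    wx = np.linalg.inv(scipy.linalg.sqrtm(cxx).real)
    wy = np.linalg.inv(scipy.linalg.sqrtm(cyy).real)
    return np.clip(np.linalg.svd(wx @ cxy @ wy, compute_uv=False), 0.0, 1.0)


def dcpm_features(trial, w, template_err, template_cor) -> dict:
    """corr/dist/cca class-contrast features from their definitions."""
    y = w.T @ trial
    y_e = w.T @ template_err
    y_c = w.T @ template_cor
    corr = pearson(y.ravel(), y_e.ravel()) - pearson(y.ravel(), y_c.ravel())
    dist = (np.linalg.norm(y - y_c) - np.linalg.norm(y - y_e)) / np.linalg.norm(y)
    d = w.shape[1]
    cca = (
        canonical_correlations(y, y_e).sum() / d
        - canonical_correlations(y, y_c).sum() / d
    )
    return {"corr": corr, "dist": dist, "cca": float(cca)}


def lda_direction(x_pos, x_neg) -> np.ndarray:
    """Fisher discriminant direction pooled-cov^{-1} (mu+ - mu-)."""
    mu_p, mu_n = x_pos.mean(axis=0), x_neg.mean(axis=0)
    dev_p = x_pos - mu_p
    dev_n = x_neg - mu_n
    pooled = (dev_p.T @ dev_p + dev_n.T @ dev_n) / (len(x_pos) + len(x_neg) - 2)
    return np.linalg.solve(pooled, mu_p - mu_n)
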