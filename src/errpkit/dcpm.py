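"""Discriminative canonical pattern matching (DCPM) for single-trial ERPs.

The classifier combines three stages:

1. *Discriminative spatial patterns* (DSP): spatial filters ``W`` maximising
   between-class over within-class scatter via the generalized eigenproblem
   ``S_b w = lambda (S_w + shrinkage * tr(S_w)/C * I) w``, suppressing
   common-mode noise.
2. *Pattern matching* of the DSP-projected trial ``Y = W^T X`` against the
   DSP-projected class templates (class-mean matrices): three scalar
   class-contrast features, each signed so positive favours "error" —

   - ``corr``: Pearson correlation of the vectorised trial with the error
     template minus with the correct template;
   - ``dist``: Frobenius-distance contrast ``(||Y - Y_c|| - ||Y - Y_e||) /
     ||Y||``;
   - ``cca``: mean canonical correlation of the trial with each template
     (components as variables, time as observations), error minus correct.
3. A Fisher linear discriminant over the standardized feature subset.

The frozen model (channels, filters, templates, feature subset, classifier,
normalisation) is the "template" applied unchanged to test trials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg

from errpkit.errors import (
    ChannelMismatchError,
    DegenerateFeaturesError,
    DimensionError,
    EmptyClassError,
)
from errpkit.io import LABEL_CORRECT, LABEL_ERROR, EpochSet
from errpkit.preprocess import class_average

FEATURE_NAMES = ("corr", "dist", "cca")


@dataclass
class ClassTemplates:
    """Class-mean matrices (channels x samples) of the training trials."""

    template_error: np.ndarray
    template_correct: np.ndarray

    def __post_init__(self) -> None:
        if self.template_error.shape != self.template_correct.shape:
            raise ValueError("templates must share one shape")


@dataclass
class DspFilter:
    """Discriminative spatial pattern filter.

    ``W`` is channels x d with columns ordered by descending generalized
    eigenvalue and sign-fixed so each column's largest-magnitude entry is
    positive.  Columns are unit-normalised in the regularized S_w metric.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    shrinkage: float
    channel_names: list[str]

    @property
    def d(self) -> int:
        return self.W.shape[1]


@dataclass
class FeatureClassifier:
    """Fisher LDA over standardized pattern-matching features."""

    feature_names: list[str]
    weights: np.ndarray
    bias: float
    norm_mean: np.ndarray
    norm_scale: np.ndarray

    def score(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.norm_mean) / self.norm_scale
        return z @ self.weights + self.bias


@dataclass
class DcpmModel:
    """Frozen DCPM template: everything needed to score unseen trials."""

    channel_subset: list[str]
    dsp: DspFilter
    templates: ClassTemplates
    feature_subset: list[str]
    classifier: FeatureClassifier
    projected_templates: dict = field(default_factory=dict)


def _class_split(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    err = epochs.class_data(LABEL_ERROR)
    cor = epochs.class_data(LABEL_CORRECT)
    if err.shape[0] == 0 or cor.shape[0] == 0:
        raise EmptyClassError("both error and correct trials are required")
    return err, cor


def scatter_matrices(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and within-class spatial scatter.

    ``S_b = (M_e - M_c)(M_e - M_c)^T`` from the class-mean matrices;
    ``S_w`` sums trialwise deviations from the own-class mean over both
    classes, normalised by the total trial count.
    """
    err, cor = _class_split(epochs)
    m_e, m_c = err.mean(axis=0), cor.mean(axis=0)
    diff = m_e - m_c
    s_b = diff @ diff.T
    n = err.shape[0] + cor.shape[0]
    s_w = np.zeros_like(s_b)
    for block, m in ((err, m_e), (cor, m_c)):
        dev = np.ascontiguousarray((block - m).transpose(1, 0, 2)).reshape(block.shape[1], -1)
        s_w += dev @ dev.T
    return s_b, s_w / n


def _fix_signs(w: np.ndarray) -> np.ndarray:
    flip = np.sign(w[np.abs(w).argmax(axis=0), np.arange(w.shape[1])])
    flip[flip == 0] = 1.0
    return w * flip


def dsp_from_scatters(
    s_b: np.ndarray,
    s_w: np.ndarray,
    d: int,
    shrinkage: float,
    channel_names: Sequence[str],
) -> DspFilter:
    """Solve the regularized generalized eigenproblem given the scatters."""
    c = s_b.shape[0]
    if not 1 <= d <= c:
        raise DimensionError(f"filter dimension {d} outside [1, {c}]")
    reg = s_w + shrinkage * (np.trace(s_w) / c) * np.eye(c)
    evals, evecs = scipy.linalg.eigh(s_b, reg)  # ascending, B-orthonormal
    order = np.argsort(evals)[::-1][:d]
    w = _fix_signs(evecs[:, order])
    return DspFilter(
        W=w,
        eigenvalues=np.clip(evals[order], 0.0, None),
        shrinkage=shrinkage,
        channel_names=list(channel_names),
    )


def fit_dsp(epochs: EpochSet, d: int, shrinkage: float = 0.05) -> DspFilter:
    """Fit a d-dimensional DSP filter on labelled training epochs.

    ``shrinkage`` adds ``shrinkage * tr(S_w)/C`` to the diagonal of ``S_w``
    before the generalized eigendecomposition; ErrP training sets are small
    (hundreds of trials, tens of channels), so a bare ``S_w`` can be
    ill-conditioned.
    """
    s_b, s_w = scatter_matrices(epochs)
    return dsp_from_scatters(s_b, s_w, d, shrinkage, epochs.channel_names)


def fit_templates(epochs: EpochSet) -> ClassTemplates:
    """Class-mean templates from training epochs (class means, not pooled,
    so unbalanced error rates do not bias either template)."""
    return ClassTemplates(
        template_error=class_average(epochs, LABEL_ERROR),
        template_correct=class_average(epochs, LABEL_CORRECT),
    )


# ---------------------------------------------------------------------------
# pattern-matching features


def _center_rows(y: np.ndarray) -> np.ndarray:
    return y - y.mean(axis=1, keepdims=True)


def _orthonormal_basis(y: np.ndarray) -> np.ndarray:
    """Orthonormal basis (samples x d) of the row space of a centered
    d x samples matrix, for canonical correlations over the time axis."""
    q, r = np.linalg.qr(_center_rows(y).T)
    # zero out directions with no variance so they contribute rho = 0
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def canonical_correlations(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Canonical correlations between two d x samples matrices, treating the
    d components as variables observed over time."""
    qy, qt = _orthonormal_basis(y), _orthonormal_basis(t)
    if qy.shape[1] == 0 or qt.shape[1] == 0:
        return np.zeros(0)
    return np.clip(np.linalg.svd(qy.T @ qt, compute_uv=False), 0.0, 1.0)


def _mean_cca(y: np.ndarray, t_basis: np.ndarray, d: int) -> float:
    qy = _orthonormal_basis(y)
    if qy.shape[1] == 0 or t_basis.shape[1] == 0:
        return 0.0
    rho = np.clip(np.linalg.svd(qy.T @ t_basis, compute_uv=False), 0.0, 1.0)
    # mean over the d nominal components; missing directions count as 0
    return float(rho.sum() / d)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def extract_features(
    trial: np.ndarray,
    dsp: DspFilter,
    templates: ClassTemplates,
    which: Iterable[str] = FEATURE_NAMES,
) -> dict[str, float]:
    """Pattern-matching features of one channels x samples trial.

    Each feature is a signed class-contrast score; positive favours the
    error class.  Only the requested families are computed.
    """
    which = list(which)
    if dsp.d == 0:
        raise DimensionError("empty DSP projection")
    w = dsp.W
    y = w.T @ trial
    y_e = w.T @ templates.template_error
    y_c = w.T @ templates.template_correct
    out: dict[str, float] = {}
    if "corr" in which:
        out["corr"] = _pearson(y.ravel(), y_e.ravel()) - _pearson(y.ravel(), y_c.ravel())
    if "dist" in which:
        denom = np.linalg.norm(y)
        if denom == 0:
            out["dist"] = 0.0
        else:
            out["dist"] = float((np.linalg.norm(y - y_c) - np.linalg.norm(y - y_e)) / denom)
    if "cca" in which:
        be = _orthonormal_basis(y_e)
        bc = _orthonormal_basis(y_c)
        out["cca"] = _mean_cca(y, be, dsp.d) - _mean_cca(y, bc, dsp.d)
    unknown = set(which) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature families {sorted(unknown)}")
    return out


def feature_matrix(
    trials: np.ndarray,
    dsp: DspFilter,
    templates: ClassTemplates,
    which: Sequence[str] = FEATURE_NAMES,
) -> np.ndarray:
    """Features for a trials x channels x samples stack; trials x |which|.

    Vectorised where possible; the per-trial QR factorisation for the cca
    family is the only loop.
    """
    which = list(which)
    if dsp.d == 0:
        raise DimensionError("empty DSP projection")
    w = dsp.W
    ys = np.einsum("cd,tcs->tds", w, trials)
    y_e = w.T @ templates.template_error
    y_c = w.T @ templates.template_correct
    n = trials.shape[0]
    cols: dict[str, np.ndarray] = {}

    flat = ys.reshape(n, -1)
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat_c, axis=1)
    safe = np.where(norms == 0, 1.0, norms)

    if "corr" in which:
        col = np.zeros(n)
        for t, sign in ((y_e, 1.0), (y_c, -1.0)):
            v = t.ravel() - t.mean()
            nv = np.linalg.norm(v)
            if nv > 0:
                col += sign * (flat_c @ v) / (safe * nv)
        col[norms == 0] = 0.0
        cols["corr"] = col
    if "dist" in which:
        raw_norms = np.linalg.norm(flat, axis=1)
        d_e = np.linalg.norm(flat - y_e.ravel(), axis=1)
        d_c = np.linalg.norm(flat - y_c.ravel(), axis=1)
        safe_raw = np.where(raw_norms == 0, 1.0, raw_norms)
        col = (d_c - d_e) / safe_raw
        col[raw_norms == 0] = 0.0
        cols["dist"] = col
    if "cca" in which:
        be = _orthonormal_basis(y_e)
        bc = _orthonormal_basis(y_c)
        col = np.empty(n)
        for i in range(n):
            qy = _orthonormal_basis(ys[i])
            if qy.shape[1] == 0:
                col[i] = 0.0
                continue
            r_e = np.clip(np.linalg.svd(qy.T @ be, compute_uv=False), 0, 1).sum() if be.size else 0.0
            r_c = np.clip(np.linalg.svd(qy.T @ bc, compute_uv=False), 0, 1).sum() if bc.size else 0.0
            col[i] = (r_e - r_c) / dsp.d
        cols["cca"] = col
    return np.column_stack([cols[k] for k in which])


# ---------------------------------------------------------------------------
# feature-space classifier


def fit_feature_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str],
) -> FeatureClassifier:
    """Fisher LDA on standardized features; score > 0 means "error".

    Zero-variance features are dropped with a warning; the weight vector is
    ``pooled-covariance^{-1} (mu_error - mu_correct)`` with the bias at the
    midpoint of the projected class means.
    """
    labels = np.asarray(labels, dtype=object)
    is_err = labels == LABEL_ERROR
    if not is_err.any() or is_err.all():
        raise EmptyClassError("both classes required to fit the classifier")
    features = np.asarray(features, dtype=float)
    names = list(feature_names)

    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    keep = scale > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance features {dropped}", stacklevel=2)
    if not keep.any():
        raise DegenerateFeaturesError("all features have zero variance")
    names = [n for n, k in zip(names, keep) if k]
    mean, scale = mean[keep], scale[keep]
    z = (features[:, keep] - mean) / scale

    z_e, z_c = z[is_err], z[~is_err]
    mu_e, mu_c = z_e.mean(axis=0), z_c.mean(axis=0)
    n_e, n_c = len(z_e), len(z_c)
    p = z.shape[1]
    pooled = np.zeros((p, p))
    for block, mu, m in ((z_e, mu_e, n_e), (z_c, mu_c, n_c)):
        if m > 1:
            dev = block - mu
            pooled += dev.T @ dev
    dof = max(n_e + n_c - 2, 1)
    pooled /= dof
    pooled += 1e-8 * max(np.trace(pooled) / p, 1e-12) * np.eye(p)
    w = np.linalg.solve(pooled, mu_e - mu_c)
    bias = -float(w @ (mu_e + mu_c) / 2)
    return FeatureClassifier(feature_names=names, weights=w, bias=bias, norm_mean=mean, norm_scale=scale)


def _cross_fitted_features(
    sub: EpochSet,
    d: int,
    features: Sequence[str],
    shrinkage: float,
    folds: int,
    seed: int,
) -> np.ndarray:
    """Out-of-fold pattern-matching features of the training trials.

    Each trial's features are computed with DSP filters and templates fit on
    the complementary folds, so the feature distribution the classifier is
    trained on matches what unseen trials produce.  Features computed with
    same-trial templates are optimistically shifted (every trial correlates
    with its own class mean), which mis-places the decision threshold.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray([1 if l == LABEL_ERROR else 0 for l in sub.labels])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    feats = np.empty((sub.n_trials, len(features)))
    for tr_idx, held_idx in skf.split(np.zeros(len(y)), y):
        part = EpochSet(
            data=sub.data[tr_idx],
            fs=sub.fs,
            t0_offset=sub.t0_offset,
            labels=sub.labels[tr_idx],
            channel_names=list(sub.channel_names),
            subject_id=sub.subject_id,
        )
        dsp_f = fit_dsp(part, d=d, shrinkage=shrinkage)
        templates_f = fit_templates(part)
        feats[held_idx] = feature_matrix(sub.data[held_idx], dsp_f, templates_f, features)
    return feats


def fit_dcpm(
    epochs: EpochSet,
    channel_subset: Sequence[str] | None = None,
    d: int = 3,
    features: Sequence[str] = FEATURE_NAMES,
    shrinkage: float = 0.05,
    cross_fit: int = 5,
    cv_seed: int = 0,
) -> DcpmModel:
    """Fit a complete DCPM template with a fixed configuration.

    Channels, filter dimension and feature subset are taken as given.  The
    DSP filter and class templates are fit on all trials; the feature-space
    LDA is trained on cross-fitted (out-of-fold) features when ``cross_fit``
    >= 2 and both classes are large enough, eliminating the resubstitution
    bias of template-matching features.  ``cross_fit=0`` gives the plain
    refit-on-everything variant.
    """
    subset = list(channel_subset) if channel_subset is not None else list(epochs.channel_names)
    sub = epochs.select_channels(subset)
    dsp = fit_dsp(sub, d=d, shrinkage=shrinkage)
    templates = fit_templates(sub)
    n_min = min(np.sum(sub.labels == LABEL_ERROR), np.sum(sub.labels == LABEL_CORRECT))
    if cross_fit >= 2 and n_min >= cross_fit:
        feats = _cross_fitted_features(sub, d, features, shrinkage, cross_fit, cv_seed)
    else:
        feats = feature_matrix(sub.data, dsp, templates, features)
    clf = fit_feature_classifier(feats, sub.labels, features)
    return DcpmModel(
        channel_subset=list(sub.channel_names),
        dsp=dsp,
        templates=templates,
        feature_subset=list(clf.feature_names),
        classifier=clf,
    )


def predict(model: DcpmModel, epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Score test epochs with a frozen template.

    Returns ``(labels, scores)``; a positive score maps to "error".
    Deterministic: the same model and data always give identical output.
    """
    try:
        sub = epochs.select_channels(model.channel_subset)
    except KeyError as exc:
        raise ChannelMismatchError(str(exc)) from exc
    feats = feature_matrix(sub.data, model.dsp, model.templates, model.feature_subset)
    scores = model.classifier.score(feats)
    labels = np.where(scores > 0, LABEL_ERROR, LABEL_CORRECT).astype(object)
    return labels, scores


def balanced_accuracy(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Mean over classes of per-class recall.

    With k classes present in the true labels: ``(1/k) sum_i TP(i)/S_i``
    where ``S_i`` is the size of class i.  Equals plain accuracy when the
    classes are balanced.
    """
    true = np.asarray(true_labels, dtype=object)
    pred = np.asarray(predicted_labels, dtype=object)
    if true.size == 0:
        raise ValueError("empty input")
    if true.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    recalls = []
    for cls in np.unique(true.astype(str)):
        sel = true.astype(str) == cls
        recalls.append(np.mean(pred[sel].astype(str) == cls))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# model persistence: model.json + arrays.npz


def save_model(model: DcpmModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "channel_subset": model.channel_subset,
        "feature_subset": model.feature_subset,
        "shrinkage": model.dsp.shrinkage,
        "classifier": {
            "feature_names": model.classifier.feature_names,
            "bias": model.classifier.bias,
        },
    }
    (path / "model.json").write_text(json.dumps(meta, indent=1))
    np.savez(
        path / "arrays.npz",
        W=model.dsp.W,
        eigenvalues=model.dsp.eigenvalues,
        template_error=model.templates.template_error,
        template_correct=model.templates.template_correct,
        weights=model.classifier.weights,
        norm_mean=model.classifier.norm_mean,
        norm_scale=model.classifier.norm_scale,
    )


def load_model(path: str | Path) -> DcpmModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    arr = np.load(path / "arrays.npz")
    dsp = DspFilter(
        W=arr["W"],
        eigenvalues=arr["eigenvalues"],
        shrinkage=meta["shrinkage"],
        channel_names=meta["channel_subset"],
    )
    clf = FeatureClassifier(
        feature_names=meta["classifier"]["feature_names"],
        weights=arr["weights"],
        bias=meta["classifier"]["bias"],
        norm_mean=arr["norm_mean"],
        norm_scale=arr["norm_scale"],
    )
    return DcpmModel(
        channel_subset=meta["channel_subset"],
        dsp=dsp,
        templates=ClassTemplates(arr["template_error"], arr["template_correct"]),
        feature_subset=meta["feature_subset"],
        classifier=clf,
    )
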