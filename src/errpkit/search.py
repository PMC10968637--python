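"""Cross-validated traversal of DCPM model configurations.

The improvement over the fixed-configuration classifier is a triple-nested,
5-fold cross-validated search over

- the lead subset, as top-k prefixes of a Fisher-separability ranking of
  the channels (k in {4, 8, 12, 16, 24, all} by default),
- the spatial-filter dimension (1..6 by default), and
- the pattern-matching feature combination (all 7 nonempty subsets of
  {corr, dist, cca}),

maximising the mean held-out balanced accuracy.  The winning triple is
refit on the full training set and frozen as the template.  Channel ranking
and feature-normalisation statistics are computed inside each training fold,
so no information from a held-out fold leaks into model selection; the
leakier variant (ranking on all training data) is available behind a flag
for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from errpkit.dcpm import (
    FEATURE_NAMES,
    ClassTemplates,
    DcpmModel,
    balanced_accuracy,
    dsp_from_scatters,
    feature_matrix,
    fit_dcpm,
    fit_feature_classifier,
    scatter_matrices,
)
from errpkit.errors import ConfigError, DegenerateFeaturesError, StratificationError
from errpkit.io import LABEL_CORRECT, LABEL_ERROR, EpochSet
from errpkit.screening import _class_trials, _fisher_per_sample


def _lexicographic_subsets(names: tuple[str, ...]) -> list[tuple[str, ...]]:
    subsets = [
        tuple(names[i] for i in comb)
        for r in range(1, len(names) + 1)
        for comb in itertools.combinations(range(len(names)), r)
    ]
    return sorted(subsets, key=lambda s: tuple(names.index(n) for n in s))


@dataclass
class SearchSpace:
    """The traversal grid.  ``channel_counts`` entries may include the string
    ``"all"``; dimensions larger than a given k are skipped for that k."""

    channel_counts: list = field(default_factory=lambda: [4, 8, 12, 16, 24, "all"])
    dims: list[int] = field(default_factory=lambda: list(range(1, 7)))
    feature_subsets: list[tuple[str, ...]] = field(
        default_factory=lambda: _lexicographic_subsets(FEATURE_NAMES)
    )
    folds: int = 5
    seed: int = 0
    shrinkage: float = 0.05
    leaky_ranking: bool = False

    def resolve_counts(self, n_channels: int) -> list[int]:
        counts = []
        for k in self.channel_counts:
            k = n_channels if k == "all" else int(k)
            if not 1 <= k <= n_channels:
                raise ConfigError(f"channel count {k} outside [1, {n_channels}]")
            if k not in counts:
                counts.append(k)
        return counts

    def validate(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not self.channel_counts or not self.dims or not self.feature_subsets:
            raise ConfigError("empty search space")
        for s in self.feature_subsets:
            if not s or set(s) - set(FEATURE_NAMES):
                raise ConfigError(f"invalid feature subset {s}")


@dataclass
class SearchResult:
    """Outcome of the traversal: the full evaluation table, the winning
    (k, dim, subset) triple, and the final model refit on all trials."""

    table: pd.DataFrame
    best: dict
    final_model: DcpmModel
    channel_ranking: pd.Series


def rank_channels_fisher(epochs: EpochSet) -> pd.Series:
    """Channels ordered by max-over-time Fisher separability.

    Score per channel = max over samples of ``|u1-u2|/(s1+s2)`` computed
    across trials; descending order, ties broken by montage position.
    """
    err, cor = _class_trials(epochs)
    scores = _fisher_per_sample(err, cor).max(axis=1)
    order = np.argsort(-scores, kind="stable")
    return pd.Series(scores[order], index=[epochs.channel_names[i] for i in order])


def _score_with(clf, feats: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    cols = [names.index(n) for n in clf.feature_names]
    return clf.score(feats[:, cols])


def cross_validated_search(epochs: EpochSet, space: SearchSpace | None = None) -> SearchResult:
    """Traverse (lead count, filter dimension, feature subset) by stratified
    k-fold cross-validation and refit the argmax triple on all trials.

    Ties on mean balanced accuracy go to the smaller k, then the smaller
    dimension, then the earlier feature subset in lexicographic
    (corr, dist, cca) order — the simplest template wins.
    """
    space = space or SearchSpace()
    space.validate()
    counts = space.resolve_counts(epochs.n_channels)
    dims = sorted(set(space.dims))
    subsets = list(space.feature_subsets)

    y = np.asarray([1 if l == LABEL_ERROR else 0 for l in epochs.labels])
    n_min = min(np.sum(y == 1), np.sum(y == 0))
    if n_min < space.folds:
        raise StratificationError(
            f"minority class has {n_min} trials; cannot stratify {space.folds} folds"
        )
    skf = StratifiedKFold(n_splits=space.folds, shuffle=True, random_state=space.seed)

    full_ranking = rank_channels_fisher(epochs)
    accs: dict[tuple, list[float]] = {}
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = replace(epochs, data=epochs.data[tr_idx], labels=epochs.labels[tr_idx])
        val_data = epochs.data[va_idx]
        val_labels = epochs.labels[va_idx]
        ranking = full_ranking if space.leaky_ranking else rank_channels_fisher(train)

        s_b, s_w = scatter_matrices(train)
        m_e = train.class_data(LABEL_ERROR).mean(axis=0)
        m_c = train.class_data(LABEL_CORRECT).mean(axis=0)
        name_to_idx = {n.lower(): i for i, n in enumerate(epochs.channel_names)}

        for k in counts:
            top = list(ranking.index[:k])
            idx = [name_to_idx[n.lower()] for n in top]
            sub = np.ix_(idx, idx)
            templates = ClassTemplates(m_e[idx], m_c[idx])
            train_k = train.data[:, idx, :]
            val_k = val_data[:, idx, :]
            for dim in dims:
                if dim > k:
                    continue
                dsp = dsp_from_scatters(s_b[sub], s_w[sub], dim, space.shrinkage, top)
                f_tr = feature_matrix(train_k, dsp, templates, FEATURE_NAMES)
                f_va = feature_matrix(val_k, dsp, templates, FEATURE_NAMES)
                for subset in subsets:
                    cols = [FEATURE_NAMES.index(s) for s in subset]
                    try:
                        clf = fit_feature_classifier(f_tr[:, cols], train.labels, subset)
                    except DegenerateFeaturesError:
                        accs.setdefault((k, dim, subset), []).append(0.0)
                        continue
                    pred = np.where(_score_with(clf, f_va, FEATURE_NAMES) > 0, LABEL_ERROR, LABEL_CORRECT)
                    accs.setdefault((k, dim, subset), []).append(
                        balanced_accuracy(val_labels, pred.astype(object))
                    )

    rows = []
    for (k, dim, subset), fold_accs in accs.items():
        row = {"k": k, "dim": dim, "subset": "+".join(subset), "mean": float(np.mean(fold_accs))}
        row.update({f"fold_{i}": a for i, a in enumerate(fold_accs)})
        rows.append(row)
    table = pd.DataFrame(rows)

    def sort_key(item):
        (k, dim, subset), fold_accs = item
        return (-np.mean(fold_accs), k, dim, subsets.index(subset))

    (best_k, best_dim, best_subset), best_accs = min(accs.items(), key=sort_key)
    best = {
        "k": best_k,
        "dim": best_dim,
        "subset": best_subset,
        "mean_balanced_accuracy": float(np.mean(best_accs)),
    }
    final_model = fit_dcpm(
        epochs,
        channel_subset=list(full_ranking.index[:best_k]),
        d=best_dim,
        features=best_subset,
        shrinkage=space.shrinkage,
    )
    return SearchResult(table=table, best=best, final_model=final_model, channel_ranking=full_ranking)


def evaluate(model: DcpmModel, test: EpochSet) -> dict:
    """Test-set report: balanced accuracy, accuracy, error-class TPR, and the
    confusion table (rows = true, columns = predicted)."""
    from errpkit.dcpm import predict

    pred, _ = predict(model, test)
    true = test.labels
    classes = [LABEL_ERROR, LABEL_CORRECT]
    confusion = pd.DataFrame(
        [[int(np.sum((true == t) & (pred == p))) for p in classes] for t in classes],
        index=classes,
        columns=classes,
    )
    n_err = confusion.loc[LABEL_ERROR].sum()
    return {
        "balanced_accuracy": balanced_accuracy(true, pred),
        "accuracy": float(np.mean(true == pred)),
        "tpr": float(confusion.loc[LABEL_ERROR, LABEL_ERROR] / n_err) if n_err else float("nan"),
        "confusion": confusion,
    }
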