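"""Subject-screening indices and ERN/Pe morphology extraction.

Three formula-defined indices quantify how strongly a lead expresses the
error-related potential, each computed from the preprocessed (0-500 ms,
zero-meaned) trials:

- *Pearson contrast*: ``1 - corr(x_err, x_corr)`` between the class-average
  waveforms of a lead (0 when the averages coincide, up to 2 when they are
  anti-correlated).
- *F-score* per time sample, using trials as samples:
  ``F = [(m+ - m)^2 + (m- - m)^2] / [B+/(n+-1) + B-/(n--1)]`` with ``m`` the
  grand mean, ``m+-`` the class means and ``B+-`` the class sums of squared
  deviations; aggregated per lead as mean and max over time.
- *Fisher separability* per time sample: ``|u1 - u2| / (s1 + s2)`` with
  per-class means ``u`` and per-class *variances* ``s`` (variances, not
  standard deviations — this sets the scale on which the 0.15 screening
  threshold lives); aggregated as mean and max.

A subject passes screening when the maximum Fisher index over the
cerebellar electrodes (CB1/CBZ/CB2) reaches the threshold (default 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from errpkit.errors import EmptyClassError, RegionMissingError, UndefinedCorrelationError
from errpkit.io import LABEL_CORRECT, LABEL_ERROR, EpochSet
from errpkit.montage import region_map
from errpkit.preprocess import class_average

INDEX_COLUMNS = ("corr_index", "fscore_mean", "fscore_max", "fisher_mean", "fisher_max")


@dataclass
class ScreeningReport:
    """Per-channel and per-region index values plus the screening decision.

    ``per_region`` aggregates each index by the max over the region's member
    channels.  ``decision`` is the pass/fail outcome of ``criterion`` at
    ``threshold``.
    """

    per_channel: pd.DataFrame
    per_region: pd.DataFrame
    criterion: str
    threshold: float
    decision: bool


# ---------------------------------------------------------------------------
# scalar index formulas


def corr_index(epochs: EpochSet, channel: str) -> float:
    """Pearson-contrast index of one lead: 1 - corr of the class averages."""
    i = epochs.channel_index(channel)
    x_e = class_average(epochs, LABEL_ERROR)[i]
    x_c = class_average(epochs, LABEL_CORRECT)[i]
    a = x_e - x_e.mean()
    b = x_c - x_c.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError(f"zero-variance class average on {channel}")
    return float(1.0 - a @ b / (na * nb))


def f_score(values_pos: np.ndarray, values_neg: np.ndarray) -> float:
    """F-score of one feature from positive- and negative-class samples."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per class")
    return float(_f_per_sample(pos[:, None], neg[:, None])[0])


def fisher_index(values_pos: np.ndarray, values_neg: np.ndarray) -> float:
    """Fisher separability of one feature: |u1 - u2| / (s1 + s2), s = variances."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per class")
    return float(_fisher_per_sample(pos[:, None], neg[:, None])[0])


def _ratio(num: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """num/denom with the degenerate convention: 0/0 -> 0, x/0 -> +inf."""
    out = np.full(num.shape, np.inf)
    np.divide(num, denom, out=out, where=denom > 0)
    out[(denom <= 0) & (num == 0)] = 0.0
    return out


def _f_per_sample(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Vectorised F-score over the last axes; pos/neg are trials x ...."""
    m_p, m_n = pos.mean(axis=0), neg.mean(axis=0)
    grand = np.concatenate([pos, neg]).mean(axis=0)
    num = (m_p - grand) ** 2 + (m_n - grand) ** 2
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    return _ratio(num, denom)


def _fisher_per_sample(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    num = np.abs(pos.mean(axis=0) - neg.mean(axis=0))
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    return _ratio(num, denom)


def _class_trials(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    err = epochs.class_data(LABEL_ERROR)
    cor = epochs.class_data(LABEL_CORRECT)
    if err.shape[0] < 2 or cor.shape[0] < 2:
        raise EmptyClassError("need >= 2 trials of each class")
    return err, cor


def fisher_per_channel(epochs: EpochSet) -> pd.DataFrame:
    """Fisher index at every time sample, aggregated per lead (mean, max)."""
    err, cor = _class_trials(epochs)
    per_sample = _fisher_per_sample(err, cor)  # channels x samples
    return pd.DataFrame(
        {"fisher_mean": per_sample.mean(axis=1), "fisher_max": per_sample.max(axis=1)},
        index=list(epochs.channel_names),
    )


def fscore_per_channel(epochs: EpochSet) -> pd.DataFrame:
    """F-score at every time sample, aggregated per lead (mean, max)."""
    err, cor = _class_trials(epochs)
    per_sample = _f_per_sample(err, cor)
    return pd.DataFrame(
        {"fscore_mean": per_sample.mean(axis=1), "fscore_max": per_sample.max(axis=1)},
        index=list(epochs.channel_names),
    )


# ---------------------------------------------------------------------------
# report, screening decision


def compute_screening_report(
    epochs: EpochSet,
    criterion: str = "fisher_max",
    threshold: float = 0.15,
    regions: dict[str, list[str]] | None = None,
) -> ScreeningReport:
    """All indices per channel and per region, plus the screening decision.

    The decision applies ``criterion`` (a column of the index table) to the
    cerebellar region's aggregate, pass iff >= ``threshold``.
    """
    err, cor = _class_trials(epochs)
    m_e, m_c = err.mean(axis=0), cor.mean(axis=0)
    v_sum = err.var(axis=0, ddof=1) + cor.var(axis=0, ddof=1)
    n_e, n_c = err.shape[0], cor.shape[0]
    grand = (n_e * m_e + n_c * m_c) / (n_e + n_c)

    fisher = _ratio(np.abs(m_e - m_c), v_sum)
    fscore = _ratio((m_e - grand) ** 2 + (m_c - grand) ** 2, v_sum)
    a = m_e - m_e.mean(axis=1, keepdims=True)
    b = m_c - m_c.mean(axis=1, keepdims=True)
    na, nb = np.linalg.norm(a, axis=1), np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise UndefinedCorrelationError("zero-variance class average")
    per_channel = pd.DataFrame(
        {
            "corr_index": 1.0 - np.einsum("cs,cs->c", a, b) / (na * nb),
            "fscore_mean": fscore.mean(axis=1),
            "fscore_max": fscore.max(axis=1),
            "fisher_mean": fisher.mean(axis=1),
            "fisher_max": fisher.max(axis=1),
        },
        index=list(epochs.channel_names),
    )

    regions = regions if regions is not None else region_map(epochs.channel_names)
    per_region = pd.DataFrame(
        {region: per_channel.loc[members].max(axis=0) for region, members in regions.items()}
    ).T[list(INDEX_COLUMNS)]

    report = ScreeningReport(
        per_channel=per_channel,
        per_region=per_region,
        criterion=criterion,
        threshold=threshold,
        decision=False,
    )
    report.decision = screen_subject(report, criterion=criterion, threshold=threshold)
    return report


def screen_subject(report: ScreeningReport, criterion: str = "fisher_max", threshold: float = 0.15) -> bool:
    """Pass iff the cerebellar-region aggregate of ``criterion`` >= threshold."""
    if "CB" not in report.per_region.index:
        raise RegionMissingError("no cerebellar (CB) channels in the report")
    return bool(report.per_region.loc["CB", criterion] >= threshold)


# ---------------------------------------------------------------------------
# ERN / Pe morphology


def extract_erp_peaks(
    class_avg: np.ndarray,
    fs: float,
    t0_offset: float = 0.0,
    channel_names: list[str] | None = None,
    ern_window: tuple[float, float] = (0.2, 0.4),
    pe_window: tuple[float, float] = (0.25, 0.5),
) -> pd.DataFrame:
    """ERN and Pe peak amplitude and latency per channel of a class average.

    The ERN is the minimum of the waveform in ``ern_window`` (seconds
    post-press), the Pe the maximum in ``pe_window``; latencies are reported
    in ms post-press.  A flat trace yields amplitude 0 with the latency
    pinned to the window start and the ``flat`` flag set.
    """
    class_avg = np.asarray(class_avg, dtype=float)
    n_ch, n_s = class_avg.shape
    times = t0_offset + np.arange(n_s) / fs

    def window_idx(win: tuple[float, float]) -> np.ndarray:
        idx = np.flatnonzero((times >= win[0]) & (times <= win[1]))
        if idx.size == 0:
            raise ValueError(f"window {win} outside the epoch span")
        return idx

    ern_idx = window_idx(ern_window)
    pe_idx = window_idx(pe_window)
    rows = []
    for c in range(n_ch):
        trace = class_avg[c]
        flat = bool(np.ptp(trace) == 0)
        if flat:
            rows.append((0.0, ern_window[0] * 1e3, 0.0, pe_window[0] * 1e3, True))
            continue
        e = ern_idx[np.argmin(trace[ern_idx])]
        p = pe_idx[np.argmax(trace[pe_idx])]
        rows.append((trace[e], times[e] * 1e3, trace[p], times[p] * 1e3, False))
    index = channel_names if channel_names is not None else list(range(n_ch))
    return pd.DataFrame(
        rows,
        index=index,
        columns=["ern_amplitude", "ern_latency_ms", "pe_amplitude", "pe_latency_ms", "flat"],
    )


# ---------------------------------------------------------------------------
# cohort-level index-vs-performance correlation


def correlate_indices_with_performance(
    region_tables: list[pd.DataFrame],
    balanced_accuracies: np.ndarray,
) -> pd.DataFrame:
    """Pearson correlation of every (region, index) with subject performance.

    ``region_tables`` holds one per-region index table per subject (as in
    :class:`ScreeningReport.per_region`).  Constant columns yield NaN.
    """
    acc = np.asarray(balanced_accuracies, dtype=float)
    if len(region_tables) != len(acc):
        raise ValueError("one region table per accuracy value required")
    if len(acc) < 3:
        raise ValueError("need >= 3 subjects")
    ref = region_tables[0]
    out = pd.DataFrame(index=ref.index, columns=ref.columns, dtype=float)
    b = acc - acc.mean()
    nb = np.linalg.norm(b)
    for region in ref.index:
        for col in ref.columns:
            vals = np.array([t.loc[region, col] for t in region_tables], dtype=float)
            a = vals - vals.mean()
            na = np.linalg.norm(a)
            out.loc[region, col] = np.nan if (na == 0 or nb == 0) else a @ b / (na * nb)
    return out
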