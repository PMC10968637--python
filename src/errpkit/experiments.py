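"""Self-contained simulation studies over the synthetic generator.

These drivers reproduce the package's headline behaviours end to end:
single-subject signal detection, the configuration-search improvement over
the fixed-configuration classifier, and the cohort-level cerebellar
screening analysis.  Every run is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from errpkit.dcpm import fit_dcpm
from errpkit.io import split_epochs
from errpkit.pipeline import condition_epochs
from errpkit.preprocess import bandpass, baseline_zero_mean
from errpkit.screening import compute_screening_report, correlate_indices_with_performance
from errpkit.search import SearchSpace, cross_validated_search, evaluate
from errpkit.synth import GeneratorConfig, focal_config, generate_cohort, generate_epochs

_MOD = 2**31


def _sub_seed(seed: int, stride: int, i: int) -> int:
    return int((seed * stride + i) % _MOD)


def detection_accuracies(
    n_seeds: int = 10,
    amplitude_scale: float = 1.0,
    seed: int = 0,
    d: int = 3,
) -> np.ndarray:
    """Test balanced accuracy of the fixed-configuration classifier.

    One subject per seed at generator defaults (scaled by
    ``amplitude_scale``), conditioned with the standard chain, split
    within-subject 60/40, fixed configuration: all channels, d spatial
    filters, all three features.
    """
    out = []
    for i in range(n_seeds):
        cfg = GeneratorConfig(seed=_sub_seed(seed, 1009, i), amplitude_scale=amplitude_scale)
        epochs, _ = generate_epochs(cfg)
        conditioned = condition_epochs(epochs)
        train, test = split_epochs(conditioned, 0.4, seed=i)
        model = fit_dcpm(train, d=d)
        out.append(evaluate(model, test)["balanced_accuracy"])
    return np.asarray(out)


def improvement_experiment(
    condition: str = "defaults",
    n_seeds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-configuration DCPM vs the cross-validated configuration search.

    ``condition="defaults"`` uses generator defaults with the full
    conditioning chain.  ``condition="focal"`` confines the discriminative
    signal to four channels over spatially independent noise
    (:func:`errpkit.synth.focal_config`) and conditions without the average
    reference, which would smear the confined signal across all leads.
    """
    rows = []
    for i in range(n_seeds):
        s = _sub_seed(seed, 2003, i)
        if condition == "defaults":
            cfg = GeneratorConfig(seed=s)
            conditioned = condition_epochs(generate_epochs(cfg)[0])
        elif condition == "focal":
            cfg = focal_config(seed=s)
            conditioned = baseline_zero_mean(bandpass(generate_epochs(cfg)[0]))
        else:
            raise ValueError(f"unknown condition {condition!r}")
        train, test = split_epochs(conditioned, 0.4, seed=i)
        fixed = evaluate(fit_dcpm(train, d=3), test)["balanced_accuracy"]
        result = cross_validated_search(train, SearchSpace(seed=i))
        improved = evaluate(result.final_model, test)["balanced_accuracy"]
        rows.append(
            {
                "seed": s,
                "fixed": fixed,
                "improved": improved,
                "best_k": result.best["k"],
                "best_dim": result.best["dim"],
                "best_subset": "+".join(result.best["subset"]),
            }
        )
    return pd.DataFrame(rows)


def cohort_screening_experiment(cohort_seed: int = 0, n_subjects: int = 20) -> dict:
    """One cohort pass of the cerebellar screening analysis.

    Generates a cohort whose cerebellar component scale sweeps 0..2,
    computes per-subject screening reports (on the full calibration
    session) and fixed-configuration balanced accuracies (within-subject
    split), then correlates each (region, index) with performance.
    """
    subjects, table = generate_cohort(n_subjects, seed=cohort_seed)
    region_tables, accuracies, passes = [], [], []
    for i, epochs in enumerate(subjects):
        conditioned = condition_epochs(epochs)
        report = compute_screening_report(conditioned)
        region_tables.append(report.per_region)
        passes.append(report.decision)
        train, test = split_epochs(conditioned, 0.4, seed=i)
        model = fit_dcpm(train, d=3)
        accuracies.append(evaluate(model, test)["balanced_accuracy"])
    accuracies = np.asarray(accuracies)
    passes = np.asarray(passes)
    correlations = correlate_indices_with_performance(region_tables, accuracies)
    return {
        "cohort": table,
        "correlations": correlations,
        "balanced_accuracies": accuracies,
        "passes": passes,
        "cb_fisher_max_correlation": float(correlations.loc["CB", "fisher_max"]),
        "cb_wins": bool(correlations["fisher_max"].idxmax() == "CB"),
    }


def screening_gain(results: list[dict]) -> tuple[float, float]:
    """Pooled mean balanced accuracy of screened-in vs screened-out subjects
    over several cohort runs."""
    bas = np.concatenate([r["balanced_accuracies"] for r in results])
    passes = np.concatenate([r["passes"] for r in results])
    if passes.all() or not passes.any():
        return float("nan"), float("nan")
    return float(bas[passes].mean()), float(bas[~passes].mean())
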