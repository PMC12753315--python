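"""Regression metrics, multi-run aggregation, and model comparison.

Performance is summarized per model as the median RMSE and Pearson
correlation over independent runs (default five), with the interquartile
range as dispersion.  Model pairs are compared with Mann–Whitney U tests
(exact null distribution for small untied samples, normal approximation
with tie correction otherwise), families of more than two groups with
Kruskal–Wallis, and p-values are adjusted across each comparison family by
Benjamini–Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ValidationError

__all__ = [
    "RunResult",
    "rmse",
    "pcc",
    "aggregate_runs",
    "compare_models",
    "kruskal_groups",
    "results_frame",
]

DEFAULT_N_RUNS = 5


@dataclass(frozen=True)
class RunResult:
    """Metrics of one trained model evaluated on one test partition."""

    model_name: str
    run_seed: int
    rmse: float
    pcc: float
    n_test: int

    def __post_init__(self):
        if self.rmse < 0:
            raise ValidationError("rmse must be non-negative")
        if not -1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12:
            raise ValidationError("pcc must lie in [-1, 1]")
        if self.n_test < 1:
            raise ValidationError("n_test must be positive")


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("rmse needs equal, nonzero-length vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValidationError("pcc needs equal vectors of length >= 2")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValidationError("pcc undefined for a constant vector")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def evaluate_predictions(model_name: str, run_seed: int, y_true: np.ndarray,
                         y_pred: np.ndarray) -> RunResult:
    return RunResult(model_name=model_name, run_seed=run_seed,
                     rmse=rmse(y_true, y_pred), pcc=pcc(y_true, y_pred),
                     n_test=len(np.asarray(y_true)))


def results_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    """Tidy (model, seed, metric, value) frame."""
    rows = []
    for r in results:
        rows.append({"model": r.model_name, "seed": r.run_seed,
                     "metric": "rmse", "value": r.rmse})
        rows.append({"model": r.model_name, "seed": r.run_seed,
                     "metric": "pcc", "value": r.pcc})
    return pd.DataFrame(rows)


def aggregate_runs(results: Sequence[RunResult],
                   n_runs: int = DEFAULT_N_RUNS) -> pd.DataFrame:
    """Per-model median and IQR of RMSE and PCC over ``n_runs`` runs."""
    by_model: dict[str, list[RunResult]] = {}
    for r in results:
        by_model.setdefault(r.model_name, []).append(r)
    rows = []
    for model, rs in sorted(by_model.items()):
        if len(rs) != n_runs:
            raise ValidationError(
                f"model {model!r} has {len(rs)} runs, expected {n_runs}")
        rmses = np.array([r.rmse for r in rs])
        pccs = np.array([r.pcc for r in rs])
        rows.append({
            "model": model,
            "median_rmse": float(np.median(rmses)),
            "iqr_rmse": float(np.percentile(rmses, 75) - np.percentile(rmses, 25)),
            "median_pcc": float(np.median(pccs)),
            "iqr_pcc": float(np.percentile(pccs, 75) - np.percentile(pccs, 25)),
            "n_runs": len(rs),
        })
    return pd.DataFrame(rows).set_index("model")


def _mwu_p(a: np.ndarray, b: np.ndarray, sided: str, alternative: str) -> float:
    """Mann–Whitney U p-value; exact for small untied samples, otherwise
    normal approximation with average ranks and tie-corrected variance."""
    alt = alternative if sided == "one" else "two-sided"
    res = stats.mannwhitneyu(a, b, alternative=alt, method="auto")
    return float(res.pvalue)


def compare_models(comparisons: Mapping[str, tuple[Sequence[float], Sequence[float]]],
                   sided: str = "one",
                   alternative: str = "less") -> pd.DataFrame:
    """Pairwise Mann–Whitney U tests with Benjamini–Hochberg adjustment.

    ``comparisons`` maps a label to a pair of metric-sample vectors
    (a, b); the family for the BH step-up is exactly this mapping.  With
    ``sided='one'``, ``alternative`` states the direction for sample a
    relative to b ('less' or 'greater').
    """
    if not comparisons:
        raise ValidationError("comparison family is empty")
    if sided not in ("one", "two"):
        raise ValidationError("sided must be 'one' or 'two'")
    labels, raw = [], []
    for label, (a, b) in comparisons.items():
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValidationError(f"comparison {label!r} has an empty group")
        labels.append(label)
        raw.append(_mwu_p(a, b, sided, alternative))
    adjusted = multipletests(raw, method="fdr_bh")[1]
    return pd.DataFrame({"comparison": labels, "p_raw": raw,
                         "p_adjusted": adjusted,
                         "sided": sided,
                         "alternative": alternative if sided == "one" else ""})


def kruskal_groups(groups: Mapping[str, Sequence[float]]) -> float:
    """Kruskal–Wallis p-value across k > 2 groups."""
    if len(groups) < 3:
        raise ValidationError("kruskal_groups expects more than two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group in Kruskal-Wallis family")
    return float(stats.kruskal(*arrays).pvalue)
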