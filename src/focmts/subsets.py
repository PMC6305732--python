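"""Exhaustive measurement-subset search for the classifier and the regression.

Every size-k subset of the canonical measures is enumerated in lexicographic
order (by canonical measure position) and scored: FDA subsets by the fitted
C-statistic of their training discriminant scores — model selection uses the
fitted statistic, with cross-validation reserved for the chosen model — and
KPLS predictor subsets by leave-one-out cross-validated R^2.  A frequency
analysis over the qualifying models (criterion above a threshold) reports how
often each measure appears, which is how variable importance beyond the
single best model is judged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fda, kpls
from .preprocessing import MEASURES, zscore_fit, zscore_apply


@dataclass(frozen=True)
class SubsetResult:
    subset: tuple[str, ...]
    criterion: str          # "c_statistic" | "cv_r2"
    value: float
    degenerate: bool = False


@dataclass
class FrequencyReport:
    threshold: float
    n_qualifying: int
    n_total: int
    percentages: dict[str, float]   # per-measure appearance share, 0-100


def enumerate_subsets(measures: list[str] | int, k: int) -> list[tuple[str, ...]]:
    """All C(m, k) size-k subsets in lexicographic (canonical) order."""
    if isinstance(measures, int):
        measures = list(MEASURES[:measures]) if measures <= len(MEASURES) else [
            f"m{i}" for i in range(measures)
        ]
    m = len(measures)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    return list(itertools.combinations(measures, k))


def _rank_results(results: list[SubsetResult]) -> list[SubsetResult]:
    # descending by value; ties broken lexicographically by subset for determinism
    return sorted(results, key=lambda r: (-r.value, r.subset))


def search_fda(table: pd.DataFrame, k: int,
               measures: list[str] | None = None) -> list[SubsetResult]:
    """Score every size-k subset by the fitted C-statistic of an FDA model.

    The table holds raw panels; z-score normalization is fit once on all
    samples (model fitting uses the full case-control set as training data).
    Degenerate subsets score 0.5 and are flagged rather than dropped, keeping
    the exhaustive sweep total.
    """
    measures = list(measures) if measures is not None else [
        m for m in MEASURES if m in table.columns
    ]
    norm = zscore_fit(table, measures)
    ztab = zscore_apply(table, norm)
    results = []
    for subset in enumerate_subsets(measures, k):
        try:
            model = fda.fit_fda(ztab, list(subset), norm)
            value = fda.c_statistic(model.t_asd, model.t_td)
            results.append(SubsetResult(subset, "c_statistic", value))
        except fda.DegenerateFitError:
            results.append(SubsetResult(subset, "c_statistic", 0.5, degenerate=True))
    return _rank_results(results)


def best_per_size(table: pd.DataFrame, k_max: int,
                  measures: list[str] | None = None) -> pd.DataFrame:
    """Maximum fitted C-statistic for each subset size 1..k_max."""
    rows = []
    for k in range(1, k_max + 1):
        ranked = search_fda(table, k, measures=measures)
        rows.append({"k": k, "max_c_statistic": ranked[0].value,
                     "best_subset": ",".join(ranked[0].subset)})
    return pd.DataFrame(rows)


def search_kpls(deltas: pd.DataFrame, y: np.ndarray, k: int,
                measures: list[str] | None = None,
                n_components: int | str = "auto",
                width: float | str = "median",
                kernel: str = "gaussian") -> list[SubsetResult]:
    """Score every size-k predictor subset by LOO cross-validated R^2."""
    measures = list(measures) if measures is not None else [
        m for m in MEASURES if m in deltas.columns
    ]
    results = []
    for subset in enumerate_subsets(measures, k):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = kpls.loo_r2(deltas, y, subset=list(subset),
                                n_components=n_components, width=width, kernel=kernel)
        results.append(SubsetResult(subset, "cv_r2", value))
    return _rank_results(results)


def frequency_analysis(results: list[SubsetResult], threshold: float) -> FrequencyReport:
    """Share of qualifying subsets (criterion >= threshold) containing each measure."""
    if not results:
        raise ValueError("no subset results supplied")
    qualifying = [r for r in results if r.value >= threshold]
    if not qualifying:
        raise ValueError(f"no model meets the criterion threshold {threshold}")
    members = sorted({m for r in results for m in r.subset},
                     key=lambda m: MEASURES.index(m) if m in MEASURES else len(MEASURES))
    counts = {m: sum(m in r.subset for r in qualifying) for m in members}
    pct = {m: 100.0 * c / len(qualifying) for m, c in counts.items()}
    return FrequencyReport(threshold=threshold, n_qualifying=len(qualifying),
                           n_total=len(results), percentages=pct)
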