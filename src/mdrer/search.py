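"""Exhaustive n-locus search with cross-validation consistency model selection.

Three method variants share the same search skeleton and differ only in the
cell classifier and the error functional used to rank locus sets:

===========  =====================  =================
method       cell classifier        error functional
===========  =====================  =================
``mdr``      ratio (cases/controls) standard error
``mdr_e``    ratio                  balanced error
``mdr_er``   percentage ratio       balanced error
===========  =====================  =================

Per CV fold, every locus-set of the requested order is fitted on the training
complement and the first set attaining the minimum training error (in
lexicographic enumeration order) is kept; its prediction error is measured on
the held-out fold. The cross-validation consistency (CVC) of a set is the
number of folds that chose it; the final model takes the highest CVC, ties
broken by lowest mean prediction error, then by enumeration order, and is
refitted on the full dataset.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .dataset import CvPlan, GenotypeDataset, make_cv_plan
from .evaluation import (
    ContingencyTable,
    EvaluationError,
    ModelStats,
    apply_model,
    model_stats,
)
from .risk_model import (
    PERCENTAGE_RATIO,
    RATIO,
    RiskModel,
    count_cells,
    label_cells,
)

METHODS = ("mdr", "mdr_e", "mdr_er")
_CLASSIFIER = {"mdr": RATIO, "mdr_e": RATIO, "mdr_er": PERCENTAGE_RATIO}
_BALANCED_ERROR = {"mdr": False, "mdr_e": True, "mdr_er": True}


@dataclass(frozen=True)
class FoldResult:
    """Best locus set of one CV fold with its training and prediction errors."""

    fold_index: int
    best_locus_set: tuple[int, ...]
    training_error: float
    prediction_error: float


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one full cross-validated search."""

    method: str
    order: int
    fold_results: tuple[FoldResult, ...]
    cvc: dict
    final_locus_set: tuple[int, ...]
    final_model: RiskModel
    final_table: ContingencyTable
    final_stats: ModelStats


@dataclass(frozen=True)
class RepeatedRunResult:
    """Aggregate of repeated searches over distinct CV assignments."""

    method: str
    order: int
    n_repeats: int
    selection_counts: dict
    modal_locus_set: tuple[int, ...]
    consistency: int
    final_model: RiskModel
    final_table: ContingencyTable
    final_stats: ModelStats
    runs: tuple[SearchResult, ...]


def enumerate_locus_sets(n_snps: int, order: int) -> Iterator[tuple[int, ...]]:
    """All C(n_snps, order) index tuples in lexicographic order.

    This order defines "found first" for every tie-break in the search.
    """
    if not 1 <= order <= n_snps:
        raise ValueError(f"order must be in [1, {n_snps}], got {order}")
    return itertools.combinations(range(n_snps), order)


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _levels(*datasets: GenotypeDataset) -> np.ndarray:
    """Per-SNP number of genotype levels, pooled over the given datasets."""
    return np.max([ds.genotypes.max(axis=0) for ds in datasets], axis=0) + 1


def _encode(genotypes: np.ndarray, loci: Sequence[int], levels: np.ndarray):
    """Mixed-radix cell code per individual for one locus set."""
    code = np.zeros(genotypes.shape[0], dtype=np.int64)
    size = 1
    for j in loci:
        code = code * levels[j] + genotypes[:, j]
        size *= int(levels[j])
    return code, size


def _cell_scores(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    classifier: str,
    p_star: int,
    n_star: int,
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if classifier == RATIO:
            return case_counts / control_counts
        return (n_star * case_counts) / (p_star * control_counts)


def _train_error(
    high: np.ndarray,
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    p_star: int,
    n_star: int,
    balanced: bool,
) -> float:
    tp = int(case_counts[high].sum())
    fp = int(control_counts[high].sum())
    if balanced:
        # integer-rational form: exactly equal errors compare bitwise equal,
        # so tie-breaking is consistent with the standard error on balanced data
        return ((p_star - tp) * n_star + fp * p_star) / (2 * p_star * n_star)
    return (fp + (p_star - tp)) / (p_star + n_star)


def run_fold(
    train: GenotypeDataset,
    test: GenotypeDataset,
    order: int,
    method: str,
    threshold: float = 1.0,
    *,
    fold_index: int = 0,
    levels: np.ndarray | None = None,
) -> FoldResult:
    """Exhaustive search over one training fold plus held-out evaluation.

    Returns the lexicographically-first minimizer of the training error and
    its prediction error on the test fold; test individuals falling into
    cells unseen in training are routed to low-risk.
    """
    _check_method(method)
    if levels is None:
        levels = _levels(train, test)
    classifier = _CLASSIFIER[method]
    balanced = _BALANCED_ERROR[method]
    p_star, n_star = train.n_cases, train.n_controls
    if p_star == 0 or n_star == 0:
        raise EvaluationError("training fold needs at least one case and one control")

    case_rows = train.genotypes[train.labels == 1]
    control_rows = train.genotypes[train.labels == 0]

    best_set: tuple[int, ...] | None = None
    best_err = math.inf
    for loci in enumerate_locus_sets(train.n_snps, order):
        case_code, size = _encode(case_rows, loci, levels)
        control_code, _ = _encode(control_rows, loci, levels)
        case_counts = np.bincount(case_code, minlength=size)
        control_counts = np.bincount(control_code, minlength=size)
        scores = _cell_scores(case_counts, control_counts, classifier, p_star, n_star)
        high = scores >= threshold  # NaN (empty cell) compares False
        err = _train_error(high, case_counts, control_counts, p_star, n_star, balanced)
        if err < best_err:
            best_err = err
            best_set = loci

    assert best_set is not None
    pred_err = _prediction_error(
        train, test, best_set, classifier, balanced, threshold, levels
    )
    return FoldResult(fold_index, best_set, best_err, pred_err)


def _prediction_error(
    train: GenotypeDataset,
    test: GenotypeDataset,
    loci: tuple[int, ...],
    classifier: str,
    balanced: bool,
    threshold: float,
    levels: np.ndarray,
) -> float:
    p_star, n_star = train.n_cases, train.n_controls
    train_code, size = _encode(train.genotypes, loci, levels)
    case_counts = np.bincount(train_code[train.labels == 1], minlength=size)
    control_counts = np.bincount(train_code[train.labels == 0], minlength=size)
    scores = _cell_scores(case_counts, control_counts, classifier, p_star, n_star)
    high = scores >= threshold  # unseen cells (NaN score) stay low-risk

    test_code, _ = _encode(test.genotypes, loci, levels)
    is_case = test.labels == 1
    tp = int(high[test_code[is_case]].sum())
    fp = int(high[test_code[~is_case]].sum())
    n_case = int(is_case.sum())
    n_control = test.n_individuals - n_case
    if balanced:
        if n_case == 0:
            raise EvaluationError("balanced prediction error undefined: no cases in test fold")
        if n_control == 0:
            raise EvaluationError("balanced prediction error undefined: no controls in test fold")
        return ((n_case - tp) * n_control + fp * n_case) / (2 * n_case * n_control)
    if n_case + n_control == 0:
        raise EvaluationError("empty test fold")
    return (fp + (n_case - tp)) / (n_case + n_control)


def run_search(
    dataset: GenotypeDataset,
    order: int,
    method: str,
    cv_plan: CvPlan,
    threshold: float = 1.0,
) -> SearchResult:
    """Cross-validated exhaustive search with CVC model selection.

    The final locus set maximizes CVC, ties broken by lowest mean prediction
    error (over the folds that chose the set), then by enumeration order. It
    is refitted on the full dataset and its statistics reported there.
    """
    _check_method(method)
    levels = _levels(dataset)
    fold_results = []
    for k, train_idx, test_idx in cv_plan.folds():
        fold_results.append(
            run_fold(
                dataset.subset(train_idx),
                dataset.subset(test_idx),
                order,
                method,
                threshold,
                fold_index=k,
                levels=levels,
            )
        )
    cvc = Counter(fr.best_locus_set for fr in fold_results)
    mean_pred = {
        s: float(np.mean([fr.prediction_error for fr in fold_results
                          if fr.best_locus_set == s]))
        for s in cvc
    }
    final_set = min(cvc, key=lambda s: (-cvc[s], mean_pred[s], s))
    final_model = label_cells(
        count_cells(dataset, final_set), _CLASSIFIER[method], threshold
    )
    final_table = apply_model(final_model, dataset)
    return SearchResult(
        method=method,
        order=order,
        fold_results=tuple(fold_results),
        cvc=dict(cvc),
        final_locus_set=final_set,
        final_model=final_model,
        final_table=final_table,
        final_stats=model_stats(final_table),
    )


def repeated_runs(
    dataset: GenotypeDataset,
    order: int,
    method: str,
    n_repeats: int,
    base_seed: int = 0,
    *,
    n_folds: int = 10,
    stratified: bool = False,
    threshold: float = 1.0,
) -> RepeatedRunResult:
    """Repeat the search over ``n_repeats`` distinct random CV assignments.

    Reports each locus set's selection frequency and the modal ("best
    candidate") model with its statistics on the full dataset; the modal
    frequency is the Consistency figure (e.g. 66/100).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    runs = tuple(
        run_search(
            dataset, order, method,
            make_cv_plan(dataset, n_folds, seed=base_seed + i, stratified=stratified),
            threshold,
        )
        for i in range(n_repeats)
    )
    counts = Counter(r.final_locus_set for r in runs)
    modal = min(counts, key=lambda s: (-counts[s], s))
    final_model = label_cells(
        count_cells(dataset, modal), _CLASSIFIER[method], threshold
    )
    final_table = apply_model(final_model, dataset)
    return RepeatedRunResult(
        method=method,
        order=order,
        n_repeats=n_repeats,
        selection_counts=dict(counts),
        modal_locus_set=modal,
        consistency=counts[modal],
        final_model=final_model,
        final_table=final_table,
        final_stats=model_stats(final_table),
        runs=runs,
    )


def model_landscape(
    dataset: GenotypeDataset,
    order: int,
    method: str,
    n_samples: int = 100,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Systematic sample of the full model landscape, sorted by balanced error.

    Every locus set of the given order is fitted and evaluated on the full
    dataset; sets are sorted by balanced error (ascending, enumeration order
    breaking ties) and ``n_samples`` of them taken at equal stride. Each
    record carries TP, TN, their log10 percentage-of-class values (NaN when
    the count is zero), the balanced error, and the high/low-risk cell counts.
    """
    _check_method(method)
    levels = _levels(dataset)
    classifier = _CLASSIFIER[method]
    p_star, n_star = dataset.n_cases, dataset.n_controls
    case_rows = dataset.genotypes[dataset.labels == 1]
    control_rows = dataset.genotypes[dataset.labels == 0]

    records = []
    for loci in enumerate_locus_sets(dataset.n_snps, order):
        case_code, size = _encode(case_rows, loci, levels)
        control_code, _ = _encode(control_rows, loci, levels)
        case_counts = np.bincount(case_code, minlength=size)
        control_counts = np.bincount(control_code, minlength=size)
        observed = (case_counts + control_counts) > 0
        scores = _cell_scores(case_counts, control_counts, classifier, p_star, n_star)
        high = scores >= threshold
        tp = int(case_counts[high].sum())
        fp = int(control_counts[high].sum())
        tn = n_star - fp
        err = ((p_star - tp) * n_star + fp * p_star) / (2 * p_star * n_star)
        records.append(
            (loci, tp, tn, err, int(high.sum()), int((observed & ~high).sum()))
        )
    n_models = len(records)
    if n_models < n_samples:
        raise ValueError(
            f"cannot sample {n_samples} models from {n_models} locus sets"
        )
    records.sort(key=lambda r: (r[3], r[0]))
    idx = (np.arange(n_samples) * n_models) // n_samples
    sampled = [records[i] for i in idx]
    df = pd.DataFrame(
        sampled, columns=["locus_set", "tp", "tn", "error", "n_high_cells", "n_low_cells"]
    )
    with np.errstate(divide="ignore"):
        df["log10_tp_pct"] = np.log10(100.0 * df["tp"] / p_star).replace(-np.inf, np.nan)
        df["log10_tn_pct"] = np.log10(100.0 * df["tn"] / n_star).replace(-np.inf, np.nan)
    return df[
        ["locus_set", "tp", "tn", "log10_tp_pct", "log10_tn_pct",
         "error", "n_high_cells", "n_low_cells"]
    ]
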