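"""Scoring a risk model against a dataset.

Routing every individual through its genotype cell's high/low label gives a
2x2 contingency table (TP/FP/FN/TN). Two error functionals are available:

* the standard misclassification error ``(FP + FN) / total``;
* the balanced error ``1 - (sensitivity + specificity) / 2``, which weighs
  the two classes equally and is algebraically identical to the standard
  error when cases and controls are equally numerous.

Odds ratios carry a Woolf (log-OR) 95% confidence interval; significance is a
Pearson chi-square test (1 df, no continuity correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import GenotypeDataset
from .risk_model import HIGH, RiskModel

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """A statistic is undefined for the given contingency table."""


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN of a risk model against a dataset.

    ``unseen_cell_individuals`` counts test individuals whose genotype cell
    was never observed in training; they are routed to low-risk.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    unseen_cell_individuals: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class ModelStats:
    """Derived statistics of a contingency table."""

    error_standard: float
    error_balanced: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    chi2_p: float

    def as_dict(self) -> dict:
        return {
            "error_standard": self.error_standard,
            "error_balanced": self.error_balanced,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "chi2_p": self.chi2_p,
        }


def apply_model(model: RiskModel, dataset: GenotypeDataset) -> ContingencyTable:
    """Route every individual through the model's cell labels.

    Cases in high-risk cells are TP, controls there FP; cases in low-risk
    cells FN, controls TN. Individuals whose cell the model never saw are
    treated as low-risk and counted in ``unseen_cell_individuals``.
    """
    loci = model.locus_set
    if max(loci) >= dataset.n_snps:
        raise ValueError(
            f"model locus set {loci} out of range for {dataset.n_snps} SNPs"
        )
    sub = dataset.genotypes[:, loci]
    tp = fp = fn = tn = unseen = 0
    labels = model.labels
    for row, is_case in zip(sub, dataset.labels):
        key = tuple(int(g) for g in row)
        label = labels.get(key)
        if label is None:
            unseen += 1
            label = "low"
        if label == HIGH:
            if is_case:
                tp += 1
            else:
                fp += 1
        else:
            if is_case:
                fn += 1
            else:
                tn += 1
    return ContingencyTable(tp, fp, fn, tn, unseen)


def error_standard(ct: ContingencyTable) -> float:
    """Misclassification rate (FP + FN) / total."""
    if ct.total == 0:
        raise EvaluationError("cannot compute an error on an empty table")
    return (ct.fp + ct.fn) / ct.total


def error_balanced(ct: ContingencyTable) -> float:
    """Balanced error: 1 - (sensitivity + specificity) / 2."""
    if ct.n_cases == 0:
        raise EvaluationError("balanced error undefined: no cases evaluated")
    if ct.n_controls == 0:
        raise EvaluationError("balanced error undefined: no controls evaluated")
    # integer-rational form of 1 - (sens + spec)/2; exact for integer counts
    return (ct.fn * ct.n_controls + ct.fp * ct.n_cases) / (
        2 * ct.n_cases * ct.n_controls
    )


def odds_ratio_ci(
    ct: ContingencyTable, z: float = 1.96
) -> tuple[float, float, float]:
    """Odds ratio with a Woolf log-OR confidence interval.

    When any cell is zero the Haldane-Anscombe +0.5 correction is applied to
    all four cells (and logged).
    """
    a, b, c, d = ct.tp, ct.fp, ct.fn, ct.tn
    if min(a, b, c, d) == 0:
        logger.info("zero cell in table (%d,%d,%d,%d): applying +0.5 correction", a, b, c, d)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


def chi_square_p(ct: ContingencyTable) -> float:
    """Pearson chi-square p-value (1 df, no continuity correction).

    Returns NaN when a margin is zero (the test is undefined there).
    """
    table = np.array([[ct.tp, ct.fn], [ct.fp, ct.tn]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def cell_chi_square_p(cell_table) -> float:
    """Chi-square test on the raw genotype-cell x case/control table.

    Unlike :func:`chi_square_p` applied after high/low labelling — which is
    anti-conservative because the split is chosen from the same data — this
    tests association between the multi-locus genotype and status directly
    (df = observed cells - 1) and is properly calibrated under the null.
    """
    arr = np.array(
        [v for v in cell_table.cells.values() if v[0] + v[1] > 0], dtype=float
    )
    if arr.shape[0] < 2 or (arr.sum(axis=0) == 0).any():
        return math.nan
    _, p, _, _ = stats.chi2_contingency(arr)
    return float(p)


def model_stats(ct: ContingencyTable) -> ModelStats:
    """All derived statistics of a contingency table in one record."""
    err_bal = error_balanced(ct)
    or_, lo, hi = odds_ratio_ci(ct)
    return ModelStats(
        error_standard=error_standard(ct),
        error_balanced=err_bal,
        sensitivity=ct.tp / ct.n_cases,
        specificity=ct.tn / ct.n_controls,
        balanced_accuracy=1.0 - err_bal,
        odds_ratio=or_,
        or_ci_low=lo,
        or_ci_high=hi,
        chi2_p=chi_square_p(ct),
    )
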