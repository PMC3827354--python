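"""High/low-risk genotype-cell classification.

A *cell* is one multi-locus genotype combination; for a chosen locus set the
individuals partition into cells, each holding a count of cases and a count
of controls. A cell is labelled high-risk when its score reaches a threshold
T (default 1) under one of two classifiers:

``ratio``
    The classic MDR score, ``cases / controls`` within the cell.

``percentage_ratio``
    The imbalance-corrected score: the cell's share of all training cases
    divided by its share of all training controls,
    ``(cases / P*) / (controls / N*)``, where P* and N* are the training-set
    case and control totals. With balanced data (P* = N*) the two classifiers
    coincide; under imbalance the percentage ratio re-centres the decision so
    that a cell is high-risk when it is enriched for cases *relative to the
    base rate*, not in absolute count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dataset import GenotypeDataset

RATIO = "ratio"
PERCENTAGE_RATIO = "percentage_ratio"
CLASSIFIERS = (RATIO, PERCENTAGE_RATIO)

HIGH = "high"
LOW = "low"

DEFAULT_THRESHOLD = 1.0

GenotypeTuple = tuple[int, ...]


class UndefinedCellError(ValueError):
    """Raised when scoring a (0, 0) cell, which carries no information."""


@dataclass(frozen=True)
class CellTable:
    """Per-cell case/control counts for one locus set.

    ``cells`` maps each *observed* genotype tuple to ``(case_count,
    control_count)``; ``train_cases``/``train_controls`` are the P*/N* totals
    of the dataset the table was counted on.
    """

    locus_set: tuple[int, ...]
    cells: Mapping[GenotypeTuple, tuple[int, int]]
    train_cases: int
    train_controls: int

    def __post_init__(self) -> None:
        total_cases = sum(c for c, _ in self.cells.values())
        total_controls = sum(k for _, k in self.cells.values())
        if total_cases != self.train_cases or total_controls != self.train_controls:
            raise ValueError(
                "cell counts do not sum to the training totals: "
                f"{total_cases}/{total_controls} vs "
                f"{self.train_cases}/{self.train_controls}"
            )
        n = len(self.locus_set)
        for key, (c, k) in self.cells.items():
            if len(key) != n:
                raise ValueError(f"cell key {key} has wrong length (expected {n})")
            if c < 0 or k < 0:
                raise ValueError(f"negative count in cell {key}")


@dataclass(frozen=True)
class RiskModel:
    """A locus set plus the high/low-risk label of every observed cell."""

    locus_set: tuple[int, ...]
    classifier: str
    threshold: float
    scores: Mapping[GenotypeTuple, float]
    labels: Mapping[GenotypeTuple, str]

    @property
    def n_high_cells(self) -> int:
        return sum(1 for v in self.labels.values() if v == HIGH)

    @property
    def n_low_cells(self) -> int:
        return sum(1 for v in self.labels.values() if v == LOW)

    def to_dict(self) -> dict:
        """JSON-serializable representation (genotype tuples become strings)."""
        return {
            "locus_set": list(self.locus_set),
            "classifier": self.classifier,
            "threshold": self.threshold,
            "cells": {
                ",".join(map(str, key)): {
                    "score": self.scores[key] if math.isfinite(self.scores[key]) else "inf",
                    "label": label,
                }
                for key, label in sorted(self.labels.items())
            },
        }


def validate_locus_set(locus_set, n_snps: int) -> tuple[int, ...]:
    loci = tuple(int(i) for i in locus_set)
    if not loci:
        raise ValueError("locus set must contain at least one locus")
    if any(b <= a for a, b in zip(loci, loci[1:])):
        raise ValueError(f"locus indices must be strictly increasing: {loci}")
    if loci[0] < 0 or loci[-1] >= n_snps:
        raise ValueError(f"locus index out of range for {n_snps} SNPs: {loci}")
    return loci


def count_cells(dataset: GenotypeDataset, locus_set) -> CellTable:
    """Tally cases and controls in each observed genotype cell."""
    loci = validate_locus_set(locus_set, dataset.n_snps)
    sub = dataset.genotypes[:, loci]
    keys, inverse = np.unique(sub, axis=0, return_inverse=True)
    case_counts = np.bincount(inverse[dataset.labels == 1], minlength=len(keys))
    control_counts = np.bincount(inverse[dataset.labels == 0], minlength=len(keys))
    cells = {
        tuple(int(g) for g in key): (int(c), int(k))
        for key, c, k in zip(keys, case_counts, control_counts)
    }
    return CellTable(loci, cells, dataset.n_cases, dataset.n_controls)


def score_cell_ratio(case_count: int, control_count: int) -> float:
    """Classic MDR cell score: cases / controls.

    Returns ``inf`` for a non-empty all-case cell and ``0`` for an all-control
    cell; an empty cell is undefined.
    """
    if case_count < 0 or control_count < 0:
        raise ValueError("cell counts must be non-negative")
    if case_count == 0 and control_count == 0:
        raise UndefinedCellError("cannot score an empty (0, 0) cell")
    if control_count == 0:
        return math.inf
    return case_count / control_count


def score_cell_percentage_ratio(
    case_count: int, control_count: int, p_star: int, n_star: int
) -> float:
    """Imbalance-corrected score: (cases/P*) / (controls/N*).

    Equivalently ``(N* x cases) / (P* x controls)``; zero/infinity conventions
    match :func:`score_cell_ratio`, and the two agree whenever P* = N*.
    """
    if p_star < 1 or n_star < 1:
        raise ValueError("training totals P* and N* must be at least 1")
    if case_count < 0 or control_count < 0:
        raise ValueError("cell counts must be non-negative")
    if case_count == 0 and control_count == 0:
        raise UndefinedCellError("cannot score an empty (0, 0) cell")
    if control_count == 0:
        return math.inf
    return (n_star * case_count) / (p_star * control_count)


def label_cells(
    cell_table: CellTable,
    classifier: str = PERCENTAGE_RATIO,
    threshold: float = DEFAULT_THRESHOLD,
) -> RiskModel:
    """Label every observed cell high-risk (score >= T) or low-risk (score < T)."""
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    scores: dict[GenotypeTuple, float] = {}
    labels: dict[GenotypeTuple, str] = {}
    for key, (c, k) in cell_table.cells.items():
        if c == 0 and k == 0:
            continue  # unobserved padding cell; carries no label
        if classifier == RATIO:
            score = score_cell_ratio(c, k)
        else:
            score = score_cell_percentage_ratio(
                c, k, cell_table.train_cases, cell_table.train_controls
            )
        scores[key] = score
        labels[key] = HIGH if score >= threshold else LOW
    return RiskModel(cell_table.locus_set, classifier, threshold, scores, labels)
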