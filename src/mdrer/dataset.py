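"""Case-control genotype datasets: loading, validation, CV splitting, resampling.

The on-disk representation is the de-facto MDR flat-file convention: a
tab-delimited (or comma-delimited) text file whose header row names each SNP
followed by the class column, and whose data rows hold small integer genotype
codes (typically 0/1/2 copies of the minor allele) followed by the class,
coded 1 for cases and 0 for controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SEPARATORS = {"mdr-tab": "\t", "csv": ","}

DEFAULT_CLASS_NAME = "class"
DEFAULT_MISSING_TOKEN = "NA"


class DatasetError(ValueError):
    """A dataset violates a structural invariant (e.g. a class is empty)."""


class FileFormatError(DatasetError):
    """A flat file could not be parsed into a genotype dataset."""


@dataclass(frozen=True)
class GenotypeDataset:
    """A genotype matrix with case/control labels.

    Parameters
    ----------
    snp_names
        Unique identifier per SNP column.
    genotypes
        Integer matrix, rows = individuals, columns = SNPs; codes are
        non-negative small integers (conventionally 0, 1, 2).
    labels
        Per-individual class: 1 = case, 0 = control.
    """

    snp_names: tuple[str, ...]
    genotypes: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        geno = np.asarray(self.genotypes, dtype=np.int64)
        labels = np.asarray(self.labels, dtype=np.int64)
        names = tuple(str(s) for s in self.snp_names)
        if geno.ndim != 2:
            raise DatasetError("genotypes must be a 2-D matrix")
        if geno.shape[1] == 0 or len(names) == 0:
            raise DatasetError("dataset must contain at least one SNP")
        if geno.shape[1] != len(names):
            raise DatasetError(
                f"{len(names)} SNP names for {geno.shape[1]} genotype columns"
            )
        if len(set(names)) != len(names):
            raise DatasetError("SNP names must be unique")
        if labels.ndim != 1 or labels.shape[0] != geno.shape[0]:
            raise DatasetError("labels must be one value per genotype row")
        if not np.isin(labels, (0, 1)).all():
            raise DatasetError("labels must be 0 (control) or 1 (case)")
        if geno.size and geno.min() < 0:
            raise DatasetError("genotype codes must be non-negative integers")
        object.__setattr__(self, "snp_names", names)
        object.__setattr__(self, "genotypes", geno)
        object.__setattr__(self, "labels", labels)

    # -- basic shape ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(self.n_individuals - self.labels.sum())

    @property
    def control_case_ratio(self) -> float:
        """Controls per case (the imbalance ratio, e.g. 3.65 for 704:193)."""
        return self.n_controls / self.n_cases

    def subset(self, rows: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        """Row-subset of the dataset (e.g. one CV fold)."""
        idx = np.asarray(rows, dtype=np.int64)
        return GenotypeDataset(self.snp_names, self.genotypes[idx], self.labels[idx])

    def to_dataframe(self, class_name: str = DEFAULT_CLASS_NAME) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=list(self.snp_names))
        df[class_name] = self.labels
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snp_names == other.snp_names
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.labels, other.labels)
        )

    def __hash__(self) -> int:  # frozen dataclass convenience
        return hash((self.snp_names, self.genotypes.tobytes(), self.labels.tobytes()))


@dataclass(frozen=True)
class CvPlan:
    """An assignment of every individual to one of ``n_folds`` CV folds."""

    n_folds: int
    assignments: np.ndarray
    seed: int
    stratified: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "assignments", np.asarray(self.assignments, dtype=np.int64)
        )

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def folds(self):
        """Yield ``(fold, train_indices, test_indices)`` triples."""
        for k in range(self.n_folds):
            yield k, self.train_indices(k), self.test_indices(k)


def read_mdr_file(
    path,
    dialect: str = "mdr-tab",
    *,
    class_column: str | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    missing_policy: str = "drop",
) -> GenotypeDataset:
    """Read a genotype dataset from an MDR flat file.

    ``missing_policy='drop'`` removes rows containing the missing token
    (the removed count is logged); ``'category'`` instead recodes the token
    as one extra genotype level per affected SNP.
    """
    sep = _separator(dialect)
    _check_field_counts(path, sep)
    df = pd.read_csv(
        path, sep=sep, na_values=[missing_token], keep_default_na=False
    )
    if df.shape[0] == 0:
        raise FileFormatError(f"{path}: no data rows")
    if class_column is None:
        class_column = df.columns[-1]
    elif class_column not in df.columns:
        raise FileFormatError(f"{path}: class column {class_column!r} not found")

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        if missing_policy == "drop":
            df = df.dropna()
            logger.warning(
                "%s: dropped %d row(s) containing missing token %r",
                path, n_missing, missing_token,
            )
        elif missing_policy == "category":
            for col in df.columns:
                if df[col].isna().any():
                    df[col] = df[col].fillna(df[col].max() + 1)
            logger.warning(
                "%s: recoded missing token %r as an extra genotype category "
                "in %d row(s)", path, missing_token, n_missing,
            )
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

    try:
        labels = df[class_column].astype(np.int64).to_numpy()
        genotypes = df.drop(columns=[class_column]).astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise FileFormatError(f"{path}: non-integer genotype or class value ({exc})")
    if not np.isin(labels, (0, 1)).all():
        raise FileFormatError(f"{path}: class values must be 0 or 1")
    snp_names = tuple(c for c in df.columns if c != class_column)
    ds = GenotypeDataset(snp_names, genotypes, labels)
    if ds.n_cases == 0 or ds.n_controls == 0:
        raise DatasetError(f"{path}: dataset needs at least one case and one control")
    return ds


def write_mdr_file(
    dataset: GenotypeDataset,
    path,
    dialect: str = "mdr-tab",
    *,
    class_name: str = DEFAULT_CLASS_NAME,
) -> None:
    """Write a dataset so that :func:`read_mdr_file` recovers it exactly."""
    sep = _separator(dialect)
    dataset.to_dataframe(class_name).to_csv(path, sep=sep, index=False)


def make_cv_plan(
    dataset: GenotypeDataset,
    n_folds: int = 10,
    seed: int = 0,
    stratified: bool = False,
) -> CvPlan:
    """Randomly deal individuals into ``n_folds`` near-equal folds.

    The default (non-stratified) split permutes all individuals uniformly and
    deals them round-robin, so the case:control ratio fluctuates from fold to
    fold exactly as random group assignment would produce. ``stratified=True``
    deals cases and controls separately, pinning the per-fold ratio.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    n = dataset.n_individuals
    if n < n_folds:
        raise DatasetError(f"cannot split {n} rows into {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    if stratified:
        for cls in (0, 1):
            idx = np.flatnonzero(dataset.labels == cls)
            perm = rng.permutation(idx)
            assignments[perm] = np.arange(perm.size) % n_folds
    else:
        perm = rng.permutation(n)
        assignments[perm] = np.arange(n) % n_folds
    plan = CvPlan(n_folds, assignments, seed, stratified)
    for k in range(n_folds):
        train_labels = dataset.labels[plan.train_indices(k)]
        if train_labels.sum() == 0 or train_labels.sum() == train_labels.size:
            raise DatasetError(
                f"training complement of fold {k} has no "
                f"{'cases' if train_labels.sum() == 0 else 'controls'}; "
                "use stratified=True or a larger dataset"
            )
    return plan


def undersample(
    dataset: GenotypeDataset, target_ratio: float, seed: int = 0
) -> GenotypeDataset:
    """Subsample controls to ``floor(n_cases * target_ratio)`` per case.

    All cases are retained; controls are drawn uniformly without replacement.
    ``target_ratio`` is expressed as controls per case and must not exceed the
    current ratio (up-sampling is not supported).
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    n_keep = int(np.floor(dataset.n_cases * target_ratio))
    if n_keep > dataset.n_controls:
        raise DatasetError(
            f"target ratio {target_ratio} exceeds current ratio "
            f"{dataset.control_case_ratio:.2f}; up-sampling is not supported"
        )
    rng = np.random.default_rng(seed)
    control_idx = np.flatnonzero(dataset.labels == 0)
    kept_controls = rng.choice(control_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(dataset.labels == 1), kept_controls]))
    return dataset.subset(keep)


def _separator(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_SEPARATORS)}"
        ) from None


def _check_field_counts(path, sep: str) -> None:
    # one cheap pass so ragged rows fail with the offending line number
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FileFormatError(f"{path}: missing header row")
        expected = len(header.rstrip("\r\n").split(sep))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            found = len(line.rstrip("\r\n").split(sep))
            if found != expected:
                raise FileFormatError(
                    f"{path}: line {lineno}: expected {expected} fields, found {found}"
                )
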