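"""Model/Results interface over the cross-validated MDR search.

``MDR`` is constructed from a :class:`~mdrer.dataset.GenotypeDataset` (or a
DataFrame via :meth:`MDR.from_dataframe`); ``fit`` runs one cross-validated
exhaustive search and returns an :class:`MDRResults`, ``fit_repeated`` runs
the search over many random CV assignments and returns a
:class:`RepeatedMDRResults` whose Consistency figure is the modal model's
selection frequency.

Example
-------
>>> from mdrer import MDR, synthetic
>>> spec = synthetic.study_profile(seed=3, n_snps=10,
...                                penetrance=synthetic.carrier_penetrance(0.05, 0.5))
>>> ds = synthetic.generate(spec)
>>> res = MDR(ds, order=2, method="mdr_er").fit(n_folds=10, seed=1)
>>> res.locus_set
(0, 1)
"""

from __future__ import annotations

import pandas as pd

from . import search as _search
from .dataset import GenotypeDataset, make_cv_plan
from .risk_model import DEFAULT_THRESHOLD


class MDR:
    """Multifactor dimensionality reduction over a case-control dataset.

    Parameters
    ----------
    dataset
        The genotype dataset.
    order
        Number of loci per candidate model (2-5 in typical use).
    method
        ``"mdr"`` (ratio classifier, standard error), ``"mdr_e"`` (ratio
        classifier, balanced error) or ``"mdr_er"`` (percentage-ratio
        classifier, balanced error; the imbalance-robust variant).
    threshold
        High-risk threshold T applied to the cell score (default 1).
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        order: int = 2,
        method: str = "mdr_er",
        threshold: float = DEFAULT_THRESHOLD,
    ) -> None:
        _search._check_method(method)
        if not 1 <= order <= dataset.n_snps:
            raise ValueError(f"order must be in [1, {dataset.n_snps}]")
        self.dataset = dataset
        self.order = order
        self.method = method
        self.threshold = threshold

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        class_column: str | None = None,
        **kwargs,
    ) -> "MDR":
        """Build from a DataFrame whose class column (default: last) holds
        1 = case / 0 = control and all other columns hold genotype codes."""
        if class_column is None:
            class_column = df.columns[-1]
        labels = df[class_column].to_numpy()
        geno = df.drop(columns=[class_column])
        dataset = GenotypeDataset(tuple(geno.columns), geno.to_numpy(), labels)
        return cls(dataset, **kwargs)

    def fit(
        self, n_folds: int = 10, seed: int = 0, stratified: bool = False
    ) -> "MDRResults":
        """One cross-validated search under a seeded random fold assignment."""
        plan = make_cv_plan(self.dataset, n_folds, seed=seed, stratified=stratified)
        result = _search.run_search(
            self.dataset, self.order, self.method, plan, self.threshold
        )
        return MDRResults(self, result)

    def fit_repeated(
        self,
        n_repeats: int = 100,
        base_seed: int = 0,
        n_folds: int = 10,
        stratified: bool = False,
    ) -> "RepeatedMDRResults":
        """Repeat :meth:`fit` over ``n_repeats`` CV seeds and aggregate."""
        result = _search.repeated_runs(
            self.dataset,
            self.order,
            self.method,
            n_repeats,
            base_seed,
            n_folds=n_folds,
            stratified=stratified,
            threshold=self.threshold,
        )
        return RepeatedMDRResults(self, result)

    def landscape(self, n_samples: int = 100) -> pd.DataFrame:
        """Systematic sample of all models sorted by balanced error."""
        return _search.model_landscape(
            self.dataset, self.order, self.method, n_samples, self.threshold
        )


class MDRResults:
    """Results of one cross-validated search."""

    def __init__(self, model: MDR, result: _search.SearchResult) -> None:
        self.model = model
        self._result = result

    @property
    def locus_set(self) -> tuple[int, ...]:
        return self._result.final_locus_set

    @property
    def snp_names(self) -> tuple[str, ...]:
        return tuple(self.model.dataset.snp_names[i] for i in self.locus_set)

    @property
    def cvc(self) -> int:
        """Cross-validation consistency of the selected set (folds out of k)."""
        return self._result.cvc[self.locus_set]

    @property
    def fold_results(self):
        return self._result.fold_results

    @property
    def risk_model(self):
        return self._result.final_model

    @property
    def contingency(self):
        return self._result.final_table

    @property
    def stats(self):
        return self._result.final_stats

    def _consistency_text(self) -> str:
        return f"{self.cvc}/{len(self.fold_results)} folds (CVC)"

    def to_frame(self) -> pd.DataFrame:
        """One summary row mirroring the standard MDR report table."""
        s, ct = self.stats, self.contingency
        return pd.DataFrame(
            [
                {
                    "method": self._result.method,
                    "order": self._result.order,
                    "model": ", ".join(self.snp_names),
                    "consistency": self._consistency_text().split(" ")[0],
                    "tp": ct.tp,
                    "tn": ct.tn,
                    "accuracy": round(s.balanced_accuracy, 2),
                    "odds_ratio": round(s.odds_ratio, 2),
                    "or_ci_low": round(s.or_ci_low, 2),
                    "or_ci_high": round(s.or_ci_high, 2),
                    "chi2_p": s.chi2_p,
                }
            ]
        )

    def summary(self) -> str:
        """Human-readable report of the selected model and its statistics."""
        s, ct = self.stats, self.contingency
        lines = [
            "MDR search results",
            "==================",
            f"method:            {self._result.method}",
            f"order:             {self._result.order}",
            f"dataset:           {self.model.dataset.n_cases} cases / "
            f"{self.model.dataset.n_controls} controls / "
            f"{self.model.dataset.n_snps} SNPs",
            f"best model:        {', '.join(self.snp_names)}  "
            f"(columns {self.locus_set})",
            f"consistency:       {self._consistency_text()}",
            f"TP / FP / FN / TN: {ct.tp} / {ct.fp} / {ct.fn} / {ct.tn}",
            f"sensitivity:       {s.sensitivity:.3f}",
            f"specificity:       {s.specificity:.3f}",
            f"balanced accuracy: {s.balanced_accuracy:.2f}",
            f"balanced error:    {s.error_balanced:.2f}",
            f"odds ratio:        {s.odds_ratio:.2f} "
            f"(95% CI {s.or_ci_low:.2f}-{s.or_ci_high:.2f})",
            f"chi-square p:      {s.chi2_p:.3g}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MDRResults {self._result.method} order={self._result.order} "
            f"model={self.snp_names}>"
        )


class RepeatedMDRResults(MDRResults):
    """Results aggregated over repeated random CV assignments."""

    def __init__(self, model: MDR, result: _search.RepeatedRunResult) -> None:
        self.model = model
        self._result = result

    @property
    def locus_set(self) -> tuple[int, ...]:
        return self._result.modal_locus_set

    @property
    def consistency(self) -> int:
        """Selection frequency of the modal model over the repeats."""
        return self._result.consistency

    @property
    def n_repeats(self) -> int:
        return self._result.n_repeats

    @property
    def selection_counts(self) -> dict:
        return self._result.selection_counts

    @property
    def fold_results(self):
        return tuple(fr for run in self._result.runs for fr in run.fold_results)

    @property
    def runs(self):
        return self._result.runs

    def _consistency_text(self) -> str:
        return f"{self.consistency}/{self.n_repeats} runs (modal model)"
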