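"""Exhaustive CV search: enumeration, fold search, CVC selection, landscape.

The brute-force oracle below re-implements the per-fold search with plain
dictionaries and no code shared with the engine; agreement on random
instances is the main correctness check for all three method variants.
"""

import itertools
import math

import numpy as np
import pytest

from mdrer import GenotypeDataset, make_cv_plan, synthetic
from mdrer.search import (
    METHODS,
    enumerate_locus_sets,
    model_landscape,
    repeated_runs,
    run_fold,
    run_search,
)

from conftest import CELLS_40_56, random_dataset


# ---------------------------------------------------------------------------
# independent oracle: dict-of-counts, no numpy vectorization, no shared code
# ---------------------------------------------------------------------------

def oracle_best_fold(train, test, order, method, threshold=1.0):
    p_star = int(sum(train.labels))
    n_star = len(train.labels) - p_star

    def cell_counts(data, loci):
        counts = {}
        for row, label in zip(data.genotypes.tolist(), data.labels.tolist()):
            key = tuple(row[i] for i in loci)
            c, k = counts.get(key, (0, 0))
            counts[key] = (c + label, k + (1 - label))
        return counts

    def high_cells(counts):
        high = set()
        for key, (c, k) in counts.items():
            if method == "mdr_er":
                score = math.inf if k == 0 else (c / p_star) / (k / n_star)
            else:
                score = math.inf if k == 0 else c / k
            if score >= threshold:
                high.add(key)
        return high

    def error(counts, high, n_case, n_control):
        tp = sum(c for key, (c, k) in counts.items() if key in high)
        fp = sum(k for key, (c, k) in counts.items() if key in high)
        if method == "mdr":
            return (fp + (n_case - tp)) / (n_case + n_control)
        return 1 - 0.5 * (tp / n_case + (n_control - fp) / n_control)

    best, best_err = None, None
    for loci in itertools.combinations(range(train.n_snps), order):
        counts = cell_counts(train, loci)
        err = error(counts, high_cells(counts), p_star, n_star)
        if best_err is None or err < best_err - 1e-12:
            best, best_err = loci, err

    train_counts = cell_counts(train, best)
    high = high_cells(train_counts)
    test_counts = cell_counts(test, best)
    n_case_test = int(sum(test.labels))
    n_control_test = len(test.labels) - n_case_test
    seen = {key for key in test_counts if key in train_counts}
    pred_counts = {key: v for key, v in test_counts.items() if key in seen}
    # unseen cells are low-risk: they contribute FN/TN only, which the error
    # formulas below account for via the class totals
    pred_err = None
    tp = sum(c for key, (c, k) in pred_counts.items() if key in high)
    fp = sum(k for key, (c, k) in pred_counts.items() if key in high)
    if method == "mdr":
        pred_err = (fp + (n_case_test - tp)) / (n_case_test + n_control_test)
    else:
        pred_err = 1 - 0.5 * (tp / n_case_test + (n_control_test - fp) / n_control_test)
    return best, best_err, pred_err


class TestEnumeration:
    def test_lexicographic_pairs(self):
        assert list(enumerate_locus_sets(4, 2)) == [
            (0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)
        ]

    def test_counts(self):
        assert sum(1 for _ in enumerate_locus_sets(77, 2)) == 2926
        assert list(enumerate_locus_sets(3, 3)) == [(0, 1, 2)]

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            list(enumerate_locus_sets(4, 5))
        with pytest.raises(ValueError):
            list(enumerate_locus_sets(4, 0))


class TestRunFold:
    def test_separable_single_snp(self):
        genotypes = np.array([[0], [0], [0], [1], [1], [1]])
        labels = np.array([1, 1, 1, 0, 0, 0])
        ds = GenotypeDataset(("S0",), genotypes, labels)
        fr = run_fold(ds, ds, 1, "mdr")
        assert fr.best_locus_set == (0,)
        assert fr.training_error == 0.0
        assert fr.prediction_error == 0.0

    @pytest.mark.parametrize("method", METHODS)
    def test_matches_oracle_on_random_instances(self, method):
        """Engine equals the brute-force oracle on >=70 random instances per
        method (>=210 in total across the parametrized cases)."""
        for seed in range(70):
            ds = random_dataset(seed, n_rows=60, n_snps=6,
                                case_fraction=0.25 + 0.5 * (seed % 3) / 2)
            plan = make_cv_plan(ds, 3, seed=seed, stratified=True)
            train = ds.subset(plan.train_indices(0))
            test = ds.subset(plan.test_indices(0))
            fr = run_fold(train, test, 2, method)
            o_set, o_err, o_pred = oracle_best_fold(train, test, 2, method)
            assert fr.best_locus_set == o_set, f"seed {seed}"
            assert fr.training_error == pytest.approx(o_err)
            assert fr.prediction_error == pytest.approx(o_pred)

    def test_mdr_and_mdr_e_agree_on_balanced_data(self):
        """With equal class sizes the standard and balanced errors coincide,
        so mdr and mdr_e rank every locus set identically."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genotypes = rng.integers(0, 3, size=(60, 5))
            labels = np.repeat([1, 0], 30)
            ds = GenotypeDataset(tuple(f"S{i}" for i in range(5)), genotypes, labels)
            plan = make_cv_plan(ds, 3, seed=seed, stratified=True)
            train, test = ds.subset(plan.train_indices(0)), ds.subset(plan.test_indices(0))
            a = run_fold(train, test, 2, "mdr")
            b = run_fold(train, test, 2, "mdr_e")
            assert a.best_locus_set == b.best_locus_set
            assert a.training_error == pytest.approx(b.training_error)


class TestRunSearch:
    def test_strong_effect_recovered_with_full_cvc(self):
        spec = synthetic.PenetranceSpec(
            causal_loci=(2, 5),
            penetrance=synthetic.carrier_penetrance(0.02, 0.6),
            mafs=(0.3,) * 10,
            n_cases=80,
            n_controls=320,
            seed=42,
        )
        ds = synthetic.generate(spec)
        plan = make_cv_plan(ds, 10, seed=0)
        res = run_search(ds, 2, "mdr_er", plan)
        assert res.final_locus_set == (2, 5)
        assert res.cvc[(2, 5)] == 10

    def test_two_fold_toy(self):
        ds = random_dataset(3, n_rows=20, n_snps=4)
        plan = make_cv_plan(ds, 2, seed=1, stratified=True)
        res = run_search(ds, 2, "mdr", plan)
        assert len(res.fold_results) == 2
        assert sum(res.cvc.values()) == 2

    def test_deterministic(self):
        ds = random_dataset(4, n_rows=50, n_snps=5)
        plan = make_cv_plan(ds, 5, seed=7, stratified=True)
        a = run_search(ds, 2, "mdr_er", plan)
        b = run_search(ds, 2, "mdr_er", plan)
        assert a.final_locus_set == b.final_locus_set
        assert a.cvc == b.cvc
        assert a.fold_results == b.fold_results
        assert a.final_stats == b.final_stats


class TestRepeatedRuns:
    def test_single_repeat_reduces_to_run_search(self):
        ds = random_dataset(5, n_rows=60, n_snps=5)
        agg = repeated_runs(ds, 2, "mdr_er", 1, base_seed=3,
                            n_folds=5, stratified=True)
        single = run_search(ds, 2, "mdr_er",
                            make_cv_plan(ds, 5, seed=3, stratified=True))
        assert agg.modal_locus_set == single.final_locus_set
        assert agg.consistency == 1
        assert agg.final_stats == single.final_stats

    def test_strong_effect_modal_frequency(self):
        spec = synthetic.PenetranceSpec(
            causal_loci=(1, 3),
            penetrance=synthetic.carrier_penetrance(0.02, 0.6),
            mafs=(0.3,) * 8,
            n_cases=60,
            n_controls=240,
            seed=11,
        )
        ds = synthetic.generate(spec)
        agg = repeated_runs(ds, 2, "mdr_er", 20, base_seed=0)
        assert agg.modal_locus_set == (1, 3)
        assert agg.consistency == 20

    def test_selection_frequencies_conserved(self):
        ds = random_dataset(6, n_rows=80, n_snps=5)
        agg = repeated_runs(ds, 2, "mdr_e", 7, base_seed=1,
                            n_folds=5, stratified=True)
        assert sum(agg.selection_counts.values()) == 7


@pytest.fixture(scope="module")
def fixture_16():
    # Table-3 cells in columns (0,1) plus 14 noise SNPs: 120 pair models
    return synthetic.fixture_from_cells(CELLS_40_56, n_pad_snps=14, seed=0)


class TestModelLandscape:
    def test_published_log10_proportion(self, fixture_16):
        """TP=131 of 193 cases is 67.88%, whose log10 is 1.83."""
        df = model_landscape(fixture_16, 2, "mdr_er", n_samples=120)
        row = df[df["locus_set"].map(lambda t: t == (0, 1))].iloc[0]
        assert row["tp"] == 131 and row["tn"] == 307
        assert round(row["log10_tp_pct"], 2) == 1.83
        assert round(float(np.log10(100 * 131 / 193)), 2) == 1.83

    def test_sorted_and_sampled(self, fixture_16):
        df = model_landscape(fixture_16, 2, "mdr_er", n_samples=40)
        assert len(df) == 40
        assert (df["error"].diff().dropna() >= -1e-12).all()

    def test_zero_tp_gives_nan(self, fixture_16):
        df = model_landscape(fixture_16, 2, "mdr_e", n_samples=120)
        zero_tp = df[df["tp"] == 0]
        assert len(zero_tp) > 0  # most pair models label everything low
        assert zero_tp["log10_tp_pct"].isna().all()

    def test_too_many_samples_rejected(self, fixture_16):
        with pytest.raises(ValueError, match="sample"):
            model_landscape(fixture_16, 2, "mdr_er", n_samples=1000)
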