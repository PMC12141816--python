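"""Balanced accuracy, the CV benchmark harness, significance testing, and
the silhouette fidelity score."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenoaug import (
    AugmentConfig,
    BenchmarkResult,
    ExpressionDataset,
    FixtureSpec,
    balanced_accuracy,
    build_plan,
    augment_dataset,
    make_cv_splits,
    run_benchmark,
    significance_tests,
    silhouette_difference,
    simulate_cohort,
)
from phenoaug.evaluate import IN_DOMAIN, prepare_training_arm


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        assert balanced_accuracy(["A", "B", "A"], ["A", "B", "A"]) == 1.0

    def test_hand_confusion_matrix(self):
        """recalls {A: 1/2, B: 1} -> 0.75."""
        assert balanced_accuracy(["A", "A", "B", "B"], ["A", "B", "B", "B"]) == 0.75

    def test_constant_predictor_on_balanced_classes_scores_one_over_k(self):
        y = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        assert balanced_accuracy(y, ["A"] * 30) == pytest.approx(1 / 3)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])
        with pytest.raises(ValueError):
            balanced_accuracy(["A"], ["A", "B"])


# ---------------------------------------------------------------------------
# Wilcoxon + BH oracles
# ---------------------------------------------------------------------------

def _brute_force_wilcoxon(x, y):
    """Exact signed-rank p-values by enumerating all 2^n sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    assert np.all(d != 0) and len(set(np.abs(d))) == len(d)  # no zeros/ties
    ranks = stats.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.asarray(dist, dtype=float)
    p_less = np.mean(dist <= t_plus)
    p_greater = np.mean(dist >= t_plus)
    p_two = min(1.0, 2 * min(p_less, p_greater))
    return t_plus, p_less, p_two


def _records(method_scores: dict[str, np.ndarray]) -> BenchmarkResult:
    rows = []
    for m, scores in method_scores.items():
        for i, s in enumerate(scores):
            rows.append({"method": m, "classifier": "clf", "repeat": i, "fold": 0,
                         "role": IN_DOMAIN, "balanced_accuracy": float(s)})
    n = len(next(iter(method_scores.values())))
    return BenchmarkResult(records=pd.DataFrame(rows),
                           metadata={"n_repeats": n, "n_folds": 1})


def test_wilcoxon_matches_brute_force_on_ten_pairs():
    rng = np.random.default_rng(0)
    x = rng.normal(0.7, 0.05, 10)
    y = x + rng.normal(0.02, 0.03, 10)
    t_plus, p_less, p_two = _brute_force_wilcoxon(x, y)
    sp = stats.wilcoxon(x, y, alternative="less", method="exact")
    assert sp.pvalue == pytest.approx(p_less, abs=1e-12)
    sp2 = stats.wilcoxon(x, y, method="exact")
    assert sp2.pvalue == pytest.approx(p_two, abs=1e-12)
    # and through the pairwise harness
    result = _records({"a": x, "b": y})
    pairs, _ = significance_tests(result)
    assert pairs.iloc[0]["p_value"] == pytest.approx(p_two, abs=1e-12)


def test_bh_adjustment_matches_hand_computation():
    """BH: p_(i) * m / i, cumulative minimum from the largest rank."""
    rng = np.random.default_rng(1)
    base = rng.normal(0.7, 0.05, 12)
    scores = {
        "a": base,
        "b": base + rng.normal(0.08, 0.02, 12),   # clearly shifted
        "c": base + rng.normal(0.0, 0.03, 12),    # null
        "d": base + rng.normal(0.04, 0.03, 12),
    }
    pairs, _ = significance_tests(_records(scores))
    p = pairs["p_value"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    np.testing.assert_allclose(pairs["p_adjusted"].to_numpy(), adj, rtol=1e-12)


def test_method_compared_with_itself_is_not_significant():
    x = np.linspace(0.5, 0.9, 10)
    pairs, flags = significance_tests(_records({"a": x, "b": x.copy()}))
    assert pairs.iloc[0]["p_value"] == 1.0
    assert not flags["better_than_unaugmented"].any()


def test_large_constant_shift_is_flagged_significant():
    rng = np.random.default_rng(2)
    base = rng.normal(0.6, 0.02, 25)
    result = _records({
        "unaugmented": base,
        "shifted": base + 0.2 + rng.normal(0, 0.005, 25),
    })
    pairs, flags = significance_tests(result)
    assert pairs.iloc[0]["significant"]
    row = flags.set_index("method")
    assert row.loc["shifted", "better_than_unaugmented"]
    assert row.loc["shifted", "better_than_all"]
    assert not row.loc["unaugmented", "better_than_all"]

def test_unpaired_inputs_rejected():
    result = _records({"a": np.linspace(0, 1, 10), "b": np.linspace(0, 1, 10)})
    result.records = result.records.iloc[:-1]  # break the pairing
    with pytest.raises(ValueError, match="unpaired"):
        significance_tests(result)


# ---------------------------------------------------------------------------
# Splits and harness
# ---------------------------------------------------------------------------

class TestSplits:
    def test_folds_are_a_pure_function_of_labels_and_seed(self, cms_fixture):
        ds, _, _ = cms_fixture
        a = make_cv_splits(ds.labels, 5, 5, seed=3)
        b = make_cv_splits(ds.labels, 5, 5, seed=3)
        assert len(a) == 25
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)

    def test_folds_are_stratified(self, cms_fixture):
        ds, _, _ = cms_fixture
        labels = np.asarray(ds.labels, dtype=object)
        for _, te in make_cv_splits(ds.labels, 1, 5, seed=0):
            counts = pd.Series(labels[te]).value_counts()
            # each class's share of the fold ~ its share of the cohort
            assert set(counts.index) == set(ds.classes)

    def test_class_smaller_than_fold_count_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_cv_splits(["A"] * 10 + ["B"] * 3, 1, 5)


@pytest.fixture(scope="module")
def tiny_benchmark():
    spec = FixtureSpec(n_classes=3, genes_per_signature=4,
                       class_sizes=(40, 12, 8), rng_seed=31)
    ds, sigs, lengths = simulate_cohort(spec)
    ood = None
    from sklearn.linear_model import LogisticRegression

    result = run_benchmark(
        ds, sigs, methods=["intra", "replacement"], plan="max",
        classifiers={"logistic": lambda: LogisticRegression(max_iter=2000)},
        n_repeats=2, n_folds=4, lengths=lengths, seed=31,
        config=AugmentConfig(subset_size=4),
    )
    return result


class TestBenchmarkHarness:
    def test_record_count_matches_protocol_arithmetic(self, tiny_benchmark):
        tiny_benchmark.check_completeness()
        df = tiny_benchmark.records
        assert len(df) == 3 * 1 * 2 * 4  # methods(+unaug) x clf x repeats x folds
        assert set(df["method"]) == {"unaugmented", "intra", "replacement"}

    def test_scores_are_valid_probabilities(self, tiny_benchmark):
        s = tiny_benchmark.records["balanced_accuracy"]
        assert ((s >= 0) & (s <= 1)).all()

    def test_strongly_separated_fixture_scores_high(self):
        """On well-separated classes every arm classifies nearly perfectly."""
        from sklearn.linear_model import LogisticRegression

        spec = FixtureSpec(n_classes=3, genes_per_signature=5,
                           class_sizes=(30, 30, 30), fold_change=8.0,
                           dispersion=20.0, rng_seed=32)
        ds, sigs, lengths = simulate_cohort(spec)
        result = run_benchmark(
            ds, sigs, methods=["inter"], plan="max",
            classifiers={"logistic": lambda: LogisticRegression(max_iter=2000)},
            n_repeats=1, n_folds=3, lengths=lengths, seed=32,
        )
        assert (result.mean_scores() >= 0.95).all()


def test_training_artifacts_ignore_poisoned_test_rows(cms_fixture):
    """Leakage guard: corrupting held-out rows leaves every train-fitted
    artifact (augmented data, normalization output) bit-identical."""
    ds, sigs, lengths = cms_fixture
    tr, te = make_cv_splits(ds.labels, 1, 5, seed=1)[0]

    def artifacts(cohort):
        train = cohort.subset(tr)
        out = {}
        for method in (None, "intra", "mod_gp", "replacement"):
            ready, _ = prepare_training_arm(
                train, sigs, method, "max", None, lengths,
                AugmentConfig(rng_seed=17, subset_size=5),
            )
            out[method] = ready.matrix
        return out

    poisoned = ds.copy()
    poisoned.matrix[te] = 10**9  # still valid counts, wildly out of range
    clean, dirty = artifacts(ds), artifacts(poisoned)
    for method in clean:
        np.testing.assert_array_equal(clean[method], dirty[method])


# ---------------------------------------------------------------------------
# Silhouette difference
# ---------------------------------------------------------------------------

class TestSilhouetteDifference:
    def test_identity_gives_zero(self, cms_fixture):
        ds, _, _ = cms_fixture
        assert silhouette_difference(ds, ds) == 0.0

    def test_copies_preserve_geometry(self, cms_fixture):
        """Random oversampling duplicates real points: near-zero difference."""
        ds, sigs, _ = cms_fixture
        plan = build_plan(ds.labels, "fixed", 80)
        aug = augment_dataset(ds, sigs, "replacement", plan, AugmentConfig(rng_seed=1))
        synth = aug.dataset.subset(np.flatnonzero(aug.is_synthetic))
        assert silhouette_difference(ds, synth) < 0.1

    def test_label_shuffling_destroys_geometry(self, cms_fixture):
        ds, _, _ = cms_fixture
        shuffled = ds.copy()
        rng = np.random.default_rng(3)
        shuffled.labels = [shuffled.labels[i]
                           for i in rng.permutation(ds.n_samples)]
        assert silhouette_difference(ds, shuffled) > 0.15

    def test_degenerate_class_structure_rejected(self, cms_fixture):
        ds, _, _ = cms_fixture
        single = ds.subset(ds.class_indices("C1"))
        with pytest.raises(ValueError, match=">= 2 classes"):
            silhouette_difference(ds, single)

    def test_differing_panels_rejected(self, cms_fixture):
        ds, _, _ = cms_fixture
        other = ds.copy()
        other.gene_ids = list(reversed(other.gene_ids))
        with pytest.raises(ValueError, match="panel"):
            silhouette_difference(ds, other)
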