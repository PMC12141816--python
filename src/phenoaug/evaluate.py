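"""Benchmarking protocol: repeated stratified CV, balanced accuracy,
paired Wilcoxon + Benjamini-Hochberg significance, and the silhouette-
difference fidelity score.

Augmentation is applied to the training fold only; held-out and
out-of-domain samples are never augmented and never feed any train-fitted
statistic.  Fold assignments are a pure function of ``(labels, seed)`` and
are shared across all method arms, giving the paired design the Wilcoxon
signed-rank test requires.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score, silhouette_score
from sklearn.model_selection import RepeatedStratifiedKFold
from statsmodels.stats.multitest import multipletests

from .core_data import COUNTS, ExpressionDataset, SignatureSet
from .normalization import GeneLengthTable, fit_transform_train_test
from .planning import AugmentConfig, augment_dataset, build_plan

IN_DOMAIN = "in_domain_test"
OUT_OF_DOMAIN = "out_of_domain"


# ---------------------------------------------------------------------------
# Metric
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall."""
    y_true, y_pred = list(y_true), list(y_pred)
    if not y_true:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    return float(balanced_accuracy_score(y_true, y_pred))


# ---------------------------------------------------------------------------
# Classifier bank
# ---------------------------------------------------------------------------

def default_classifiers(seed: int = 0, include_ebm: bool = False) -> dict:
    """The four mandatory classifiers (sklearn defaults apart from LR's
    iteration cap); the Explainable Boosting Machine is optional because it
    needs the ``interpret`` package."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    bank = {
        "logistic": lambda: LogisticRegression(max_iter=2000),
        "knn": lambda: KNeighborsClassifier(),
        "svm_rbf": lambda: SVC(random_state=seed),
        "rf": lambda: RandomForestClassifier(random_state=seed),
    }
    if include_ebm:
        try:
            from interpret.glassbox import ExplainableBoostingClassifier
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "the EBM classifier requires the optional 'interpret' package"
            ) from exc
        bank["ebm"] = lambda: ExplainableBoostingClassifier(random_state=seed)
    return bank


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def make_cv_splits(
    labels, n_repeats: int = 5, n_folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified repeated K-fold assignments — a pure function of
    ``(labels, seed)``, reused identically by every method arm."""
    labels = np.asarray([str(l) for l in labels], dtype=object)
    counts = pd.Series(labels).value_counts()
    if counts.min() < n_folds:
        small = counts[counts < n_folds].index.tolist()
        raise ValueError(
            f"every class needs >= {n_folds} members for {n_folds}-fold "
            f"stratified CV; too small: {small}"
        )
    rskf = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in rskf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkResult:
    """Tidy per-(method, classifier, repeat, fold, role) balanced accuracies."""

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def mean_scores(self, role: str = IN_DOMAIN) -> pd.Series:
        df = self.records[self.records["role"] == role]
        return df.groupby("method")["balanced_accuracy"].mean().sort_values(ascending=False)

    def check_completeness(self) -> None:
        counts = self.records.groupby(["method", "classifier", "role"]).size()
        expected = self.metadata["n_repeats"] * self.metadata["n_folds"]
        if not (counts == expected).all():
            raise AssertionError(f"expected {expected} records per cell, got:\n{counts}")


def prepare_training_arm(
    train: ExpressionDataset,
    signatures: SignatureSet | None,
    method: str | None,
    plan_mode: str,
    fixed_size: int | None,
    lengths: GeneLengthTable | None,
    config: AugmentConfig,
):
    """Augment (unless ``method`` is None) and normalize one training fold.

    Returns ``(train_ready, normalize_eval)`` where ``normalize_eval`` maps
    any evaluation dataset through the same normalization path without
    touching training statistics other than those already fitted.
    """
    if method is None:
        augmented = train
    else:
        plan = build_plan(train.labels, plan_mode, fixed_size)
        augmented = augment_dataset(train, signatures, method, plan, config).dataset
    force = train.scale == COUNTS and augmented.scale != COUNTS
    if train.scale == COUNTS:
        train_ready, _ = fit_transform_train_test(
            augmented, augmented, lengths=lengths, force=force
        )

        def normalize_eval(ds: ExpressionDataset) -> ExpressionDataset:
            _, out = fit_transform_train_test(augmented, ds, lengths=lengths, force=force)
            return out
    else:
        train_ready = augmented.copy()

        def normalize_eval(ds: ExpressionDataset) -> ExpressionDataset:
            return ds.copy()

    return train_ready, normalize_eval


def run_benchmark(
    dataset: ExpressionDataset,
    signatures: SignatureSet | None,
    methods: list[str],
    plan: str | int = "max",
    classifiers: dict | None = None,
    n_repeats: int = 5,
    n_folds: int = 5,
    ood: ExpressionDataset | None = None,
    lengths: GeneLengthTable | None = None,
    config: AugmentConfig | None = None,
    seed: int = 0,
    include_unaugmented: bool = True,
) -> BenchmarkResult:
    """Run the full protocol: for each of ``n_repeats x n_folds`` stratified
    splits, augment the training fold per method, normalize (FPKM + log2 for
    counts), train every classifier, and score balanced accuracy on the
    held-out fold and the optional out-of-domain cohort.

    ``plan`` is ``"max"`` (lift minorities to the majority size of the
    training fold) or an integer fixed class size.
    """
    config = config or AugmentConfig()
    classifiers = classifiers or default_classifiers(seed)
    plan_mode, fixed_size = ("fixed", plan) if isinstance(plan, int) else (plan, None)
    splits = make_cv_splits(dataset.labels, n_repeats, n_folds, seed)

    arms: list[str | None] = ([None] if include_unaugmented else []) + list(methods)
    rows = []
    for split_idx, (tr, te) in enumerate(splits):
        rep, fold = divmod(split_idx, n_folds)
        train, test = dataset.subset(tr), dataset.subset(te)
        for arm_idx, method in enumerate(arms):
            arm_seed = int(
                np.random.SeedSequence([seed, split_idx, arm_idx]).generate_state(1)[0]
                % (2**31)
            )
            arm_cfg = AugmentConfig(
                rng_seed=arm_seed, subset_size=config.subset_size,
                smote_k=config.smote_k, overlap_adaptation=config.overlap_adaptation,
                continuous_input=config.continuous_input,
            )
            train_ready, normalize_eval = prepare_training_arm(
                train, signatures, method, plan_mode, fixed_size, lengths, arm_cfg
            )
            eval_sets = [(IN_DOMAIN, normalize_eval(test), test.labels)]
            if ood is not None:
                eval_sets.append((OUT_OF_DOMAIN, normalize_eval(ood), ood.labels))
            name = method or "unaugmented"
            for clf_name, factory in classifiers.items():
                clf = factory()
                clf.fit(train_ready.matrix, train_ready.labels)
                for role, ds_eval, y_true in eval_sets:
                    rows.append({
                        "method": name, "classifier": clf_name, "repeat": rep,
                        "fold": fold, "role": role,
                        "balanced_accuracy": balanced_accuracy(
                            y_true, clf.predict(ds_eval.matrix)
                        ),
                    })
    result = BenchmarkResult(
        records=pd.DataFrame(rows),
        metadata={
            "n_repeats": n_repeats, "n_folds": n_folds, "plan": plan, "seed": seed,
            "methods": [m or "unaugmented" for m in arms],
            "classifiers": list(classifiers),
            "subset_size": config.subset_size, "smote_k": config.smote_k,
        },
    )
    result.check_completeness()
    return result


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

def _paired_vectors(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per method: balanced accuracies sorted by (classifier, repeat, fold)
    so that entries are paired across methods."""
    out = {}
    for m, g in df.groupby("method"):
        g = g.sort_values(["classifier", "repeat", "fold"])
        out[m] = g["balanced_accuracy"].to_numpy()
    sizes = {len(v) for v in out.values()}
    if len(sizes) != 1:
        raise ValueError("unpaired records: methods have unequal record counts")
    return out


def significance_tests(
    result: BenchmarkResult,
    alpha: float = 0.05,
    role: str = IN_DOMAIN,
    baseline: str = "unaugmented",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise two-sided Wilcoxon signed-rank tests on split-and-classifier
    paired balanced accuracies (pooled across classifiers), BH-adjusted
    across all pairs.

    Returns ``(pairs, flags)``: per-pair statistics and, per method, the two
    headline flags — significantly better than the unaugmented arm, and
    significantly better than every other method.
    """
    df = result.records[result.records["role"] == role]
    vectors = _paired_vectors(df)
    methods = sorted(vectors)
    pairs = list(itertools.combinations(methods, 2))
    pvals = []
    for a, b in pairs:
        d = vectors[a] - vectors[b]
        if np.all(d == 0):
            pvals.append(1.0)
        else:
            pvals.append(float(stats.wilcoxon(vectors[a], vectors[b]).pvalue))
    if pairs:
        _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        p_adj = np.array([])
    pair_df = pd.DataFrame({
        "method_a": [a for a, _ in pairs], "method_b": [b for _, b in pairs],
        "mean_a": [vectors[a].mean() for a, _ in pairs],
        "mean_b": [vectors[b].mean() for _, b in pairs],
        "p_value": pvals, "p_adjusted": p_adj,
        "significant": p_adj < alpha if len(pairs) else [],
    })

    def _better(m: str, other: str) -> bool:
        row = pair_df[((pair_df.method_a == m) & (pair_df.method_b == other))
                      | ((pair_df.method_a == other) & (pair_df.method_b == m))]
        if row.empty:
            return False
        r = row.iloc[0]
        mean_m = r.mean_a if r.method_a == m else r.mean_b
        mean_o = r.mean_b if r.method_a == m else r.mean_a
        return bool(r.significant and mean_m > mean_o)

    flags = pd.DataFrame({
        "method": methods,
        "better_than_unaugmented": [
            m != baseline and baseline in vectors and _better(m, baseline)
            for m in methods
        ],
        "better_than_all": [
            all(_better(m, o) for o in methods if o != m) for m in methods
        ],
    })
    return pair_df, flags


# ---------------------------------------------------------------------------
# Fidelity
# ---------------------------------------------------------------------------

def silhouette_difference(real: ExpressionDataset, synthetic: ExpressionDataset) -> float:
    """|silhouette(real) - silhouette(synthetic)| under cosine distance with
    class labels as cluster assignments; lower means the synthetic data
    preserve the class geometry better."""
    if real.gene_ids != synthetic.gene_ids:
        raise ValueError("datasets must share the gene panel")
    for name, ds in (("real", real), ("synthetic", synthetic)):
        counts = ds.class_counts()
        if len(counts) < 2 or min(counts.values()) < 2:
            raise ValueError(
                f"{name} dataset needs >= 2 classes with >= 2 members each"
            )
    s_real = silhouette_score(real.matrix, real.labels, metric="cosine")
    s_syn = silhouette_score(synthetic.matrix, synthetic.labels, metric="cosine")
    return float(abs(s_real - s_syn))
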