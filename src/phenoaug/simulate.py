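"""Synthetic cohort generator: imbalanced, signature-block-structured counts.

Emulates the structure of a subtype-labelled tumour expression cohort reduced
to its signature panel: each class owns a block of signature genes whose
negative-binomial mean is up-regulated (``baseline_mean * fold_change``) in
samples of that class and at ``baseline_mean`` elsewhere.  Optionally, the
first two classes share ``overlap_genes`` genes that are *up*-regulated in
the second designated class and *down*-regulated (``baseline_mean /
fold_change``) in the first — the overlapping-signature situation of e.g.
the Luminal A / Luminal B PAM50 blocks.

Counts are drawn as a Gamma-Poisson mixture, i.e. exactly negative binomial
with mean ``m`` and size (dispersion) ``r``: ``lambda ~ Gamma(r, scale=m/r)``
then ``y ~ Poisson(lambda)``, giving ``Var = m + m^2/r``.  A paired
out-of-domain cohort applies an independent per-gene multiplicative
log-normal batch shift to the design means, standing in for a
different-study validation cohort.

Defaults portray a mid-size colorectal-style cohort: 4 classes x 10 genes,
class sizes (75, 220, 70, 145), baseline mean 50, fold change 3, size 2
(i.e. dispersion phi = 0.5, a noisy bulk-tumour level of over-dispersion).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import COUNTS, ExpressionDataset, SignatureSet
from .normalization import GeneLengthTable


@dataclass
class FixtureSpec:
    """Design of a simulated cohort; see module docstring for semantics."""

    n_classes: int = 4
    genes_per_signature: int = 10
    class_sizes: tuple[int, ...] = (75, 220, 70, 145)
    baseline_mean: float = 50.0
    fold_change: float = 3.0
    dispersion: float = 2.0  # NB size parameter r; Var = m + m^2/r
    overlap_genes: int = 0
    batch_shift: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.genes_per_signature < 1:
            raise ValueError("need at least 1 gene per signature")
        if len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes must have one entry per class")
        if any(s < 1 for s in self.class_sizes):
            raise ValueError("class sizes must all be >= 1")
        if not self.baseline_mean > 0:
            raise ValueError("baseline_mean must be > 0")
        if not self.fold_change > 1:
            raise ValueError("fold_change must be > 1")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.overlap_genes < self.genes_per_signature:
            raise ValueError("overlap_genes must be in [0, genes_per_signature)")
        if self.batch_shift < 0:
            raise ValueError("batch_shift must be >= 0")

    # -- derived design -----------------------------------------------------

    @property
    def class_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_classes)]

    def signature_set(self) -> SignatureSet:
        names = self.class_names
        blocks: dict[str, list[str]] = {}
        shared = [f"OVL_g{j:02d}" for j in range(self.overlap_genes)]
        for i, c in enumerate(names):
            own = self.genes_per_signature - (self.overlap_genes if i < 2 else 0)
            genes = [f"{c}_g{j:02d}" for j in range(own)]
            if i < 2 and self.overlap_genes:
                genes += shared
            blocks[c] = genes
        return SignatureSet(classes=names, blocks=blocks)

    def design_means(self) -> tuple[list[str], np.ndarray]:
        """(gene order, class x gene matrix of NB means)."""
        sigs = self.signature_set()
        genes = sigs.all_genes
        names = self.class_names
        m = np.full((self.n_classes, len(genes)), self.baseline_mean)
        gidx = {g: j for j, g in enumerate(genes)}
        for i, c in enumerate(names):
            for g in sigs.blocks[c]:
                if g.startswith("OVL_"):
                    continue
                m[i, gidx[g]] = self.baseline_mean * self.fold_change
        # shared genes: up in the second designated class, down in the first
        for g in genes:
            if g.startswith("OVL_"):
                m[1, gidx[g]] = self.baseline_mean * self.fold_change
                m[0, gidx[g]] = self.baseline_mean / self.fold_change
        return genes, m


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam).astype(np.float64)


def _labels_and_means(spec: FixtureSpec) -> tuple[list[str], np.ndarray]:
    genes, design = spec.design_means()
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for i, c in enumerate(spec.class_names):
        for _ in range(spec.class_sizes[i]):
            labels.append(c)
            rows.append(design[i])
    return labels, np.vstack(rows)


def simulate_cohort(
    spec: FixtureSpec,
) -> tuple[ExpressionDataset, SignatureSet, GeneLengthTable]:
    """Simulate the in-domain cohort plus its signature set and gene lengths.

    Gene lengths are log-uniform in [500, 5000] bp so FPKM normalization is
    non-trivially gene-dependent.  Deterministic under ``spec.rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 0]))
    genes, _ = spec.design_means()
    labels, means = _labels_and_means(spec)
    matrix = _nb_draw(rng, means, spec.dispersion)
    ds = ExpressionDataset(
        matrix=matrix,
        sample_ids=[f"S{i:04d}" for i in range(len(labels))],
        gene_ids=genes, labels=labels, scale=COUNTS,
    )
    len_rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 2]))
    lengths = np.exp(len_rng.uniform(np.log(500.0), np.log(5000.0), size=len(genes)))
    table = GeneLengthTable(lengths={g: float(np.round(l)) for g, l in zip(genes, lengths)})
    return ds, spec.signature_set(), table


def simulate_ood_cohort(spec: FixtureSpec) -> ExpressionDataset:
    """Fresh cohort with the same class-conditional design but per-gene
    multiplicative batch shift: mean_j -> mean_j * exp(batch_shift * z_j),
    z_j ~ N(0, 1).  ``batch_shift=0`` gives an i.i.d. replica."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
    genes, _ = spec.design_means()
    labels, means = _labels_and_means(spec)
    factor = np.exp(spec.batch_shift * rng.standard_normal(len(genes)))
    matrix = _nb_draw(rng, means * factor[None, :], spec.dispersion)
    return ExpressionDataset(
        matrix=matrix,
        sample_ids=[f"T{i:04d}" for i in range(len(labels))],
        gene_ids=genes, labels=labels, scale=COUNTS,
    )
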