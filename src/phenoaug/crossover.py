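"""Signature-dependent augmentation: intra- and inter-class crossover.

A synthetic patient is assembled by concatenating whole signature blocks
copied verbatim from real donors, under class constraints:

* intra-class: every block (all classes' blocks) is copied from a donor drawn
  uniformly, independently per block, from the samples of the *target* class
  only.  Expression of the non-target blocks is therefore typical of the
  target phenotype.
* inter-class: the target class's own (label-predictive) block must come from
  a target-class donor; every other class-c' block is copied from a donor
  drawn over the whole cohort *excluding* samples labelled c', preventing
  ambiguous labels.

Blocks are atomic — the methods never split within a block.  Donors are drawn
with replacement and independently across blocks and generated samples, and
always from real data only.  When two classes' signatures share genes, the
pairwise-overlap adaptation (:func:`assign_overlap_blocks`) resolves, per
generated sample, which block the shared genes travel with.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import (
    OVERLAPPING,
    ExpressionDataset,
    SignatureSet,
    SyntheticSample,
    block_partition,
)


@dataclass
class CrossoverConfig:
    """Configuration shared by both crossover samplers.

    ``overlap_adaptation`` must be switched on explicitly to augment with
    overlapping signatures; the shared genes are then re-assigned per
    generated sample (label-predictive block keeps them when it owns any,
    otherwise one of the two overlapping blocks is chosen uniformly at
    random).  Generation is bit-reproducible given identical seed, dataset,
    signatures and target.
    """

    rng_seed: int = 0
    overlap_adaptation: bool = False


def assign_overlap_blocks(
    signatures: SignatureSet, target_class: str, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Effective (disjoint) block partition for generating one sample.

    For each group of genes shared by exactly two blocks: if the target
    class's block is one of the pair, the shared genes stay with the target
    (label-predictive) block and are removed from the other; otherwise one of
    the two overlapping blocks is chosen uniformly at random and the shared
    genes travel with it, so their values come from the same donor as that
    block, keeping the expression pattern internally consistent.

    For disjoint signatures this is the identity.  Genes shared by more than
    two blocks are rejected at :class:`SignatureSet` construction.
    """
    effective = {c: list(signatures.blocks[c]) for c in signatures.classes}
    for (a, b), genes in signatures.overlap_pairs().items():
        if target_class in (a, b):
            keeper = target_class
        else:
            keeper = (a, b)[int(rng.integers(2))]
        loser = b if keeper == a else a
        effective[loser] = [g for g in effective[loser] if g not in genes]
    return effective


def _check_inputs(
    dataset: ExpressionDataset,
    signatures: SignatureSet,
    target_class: str,
    config: CrossoverConfig,
) -> None:
    if target_class not in signatures.classes:
        raise KeyError(f"target class {target_class!r} has no signature block")
    if signatures.overlap_policy == OVERLAPPING and not config.overlap_adaptation:
        raise ValueError(
            "signatures overlap; enable CrossoverConfig.overlap_adaptation to "
            "resolve shared genes per sample via assign_overlap_blocks"
        )
    block_partition(dataset, signatures)  # raises if signature genes missing
    uncovered = set(dataset.gene_ids) - set(signatures.all_genes)
    if uncovered:
        raise ValueError(
            "crossover requires every dataset gene to belong to a signature "
            f"block; restrict_to_panel first (uncovered: {sorted(uncovered)[:5]}...)"
        )
    if len(dataset.class_indices(target_class)) == 0:
        raise ValueError(f"target class {target_class!r} has no observed samples")


def _generate(
    dataset: ExpressionDataset,
    signatures: SignatureSet,
    target_class: str,
    n: int,
    config: CrossoverConfig,
    pools: dict[str, np.ndarray],
    method: str,
) -> list[SyntheticSample]:
    rng = np.random.default_rng(config.rng_seed)
    gene_idx = dataset.gene_index()
    static_partition = None
    if signatures.overlap_policy != OVERLAPPING:
        static_partition = {c: signatures.blocks[c] for c in signatures.classes}

    out: list[SyntheticSample] = []
    for _ in range(n):
        if static_partition is None:
            partition = assign_overlap_blocks(signatures, target_class, rng)
        else:
            partition = static_partition
        values = np.empty(dataset.n_genes, dtype=np.float64)
        donors: dict[str, str] = {}
        for c in signatures.classes:
            genes = partition[c]
            if not genes:
                continue
            pool = pools[c]
            donor = int(pool[rng.integers(len(pool))])
            cols = [gene_idx[g] for g in genes]
            values[cols] = dataset.matrix[donor, cols]
            donors[c] = dataset.sample_ids[donor]
        prov: dict = {"block_donors": donors}
        if static_partition is None:
            prov["effective_blocks"] = {c: list(partition[c]) for c in signatures.classes}
        out.append(
            SyntheticSample(
                values=values,
                label=target_class,
                method=method,
                provenance=prov,
                seed_state=config.rng_seed,
            )
        )
    return out


def intra_class_crossover(
    dataset: ExpressionDataset,
    signatures: SignatureSet,
    target_class: str,
    n: int,
    config: CrossoverConfig | None = None,
) -> list[SyntheticSample]:
    """Generate ``n`` samples of ``target_class`` by mixing signature blocks
    drawn exclusively from target-class donors (one independent uniform donor
    per block per sample)."""
    config = config or CrossoverConfig()
    _check_inputs(dataset, signatures, target_class, config)
    pool = dataset.class_indices(target_class)
    pools = {c: pool for c in signatures.classes}
    return _generate(dataset, signatures, target_class, n, config, pools, "intra")


def audit_provenance(
    dataset: ExpressionDataset,
    signatures: SignatureSet,
    samples: list[SyntheticSample],
) -> list[str]:
    """Verify generated samples against their recorded provenance.

    Checks, for every sample and every block, that the stored values are
    bit-identical to the named donor's values on that block, and that donor
    labels satisfy the method's class constraints (intra: every donor carries
    the target label; inter: the predictive block's donor carries the target
    label and the class-c' block's donor is not labelled c').  Returns a list
    of human-readable violations (empty when the audit passes).
    """
    violations: list[str] = []
    gene_idx = dataset.gene_index()
    row_of = {s: i for i, s in enumerate(dataset.sample_ids)}
    for k, s in enumerate(samples):
        blocks = s.provenance.get("effective_blocks") or {
            c: signatures.blocks[c] for c in signatures.classes
        }
        for c, donor_id in s.provenance["block_donors"].items():
            donor = row_of[donor_id]
            cols = [gene_idx[g] for g in blocks[c]]
            if not np.array_equal(s.values[cols], dataset.matrix[donor, cols]):
                violations.append(f"sample {k}: block {c} differs from donor {donor_id}")
            donor_label = dataset.labels[donor]
            if s.method == "intra":
                if donor_label != s.label:
                    violations.append(
                        f"sample {k}: intra donor {donor_id} labelled {donor_label}, "
                        f"expected {s.label}"
                    )
            elif s.method == "inter":
                if c == s.label and donor_label != s.label:
                    violations.append(
                        f"sample {k}: predictive-block donor {donor_id} labelled "
                        f"{donor_label}, expected {s.label}"
                    )
                if c != s.label and donor_label == c:
                    violations.append(
                        f"sample {k}: block {c} donor {donor_id} is labelled {c}"
                    )
    return violations


def inter_class_crossover(
    dataset: ExpressionDataset,
    signatures: SignatureSet,
    target_class: str,
    n: int,
    config: CrossoverConfig | None = None,
) -> list[SyntheticSample]:
    """Generate ``n`` samples of ``target_class`` mixing blocks across the
    cohort: the label-predictive block comes from a target-class donor; the
    class-c' block comes from any sample *not* labelled c'."""
    config = config or CrossoverConfig()
    _check_inputs(dataset, signatures, target_class, config)
    labels = np.asarray(dataset.labels, dtype=object)
    pools: dict[str, np.ndarray] = {}
    for c in signatures.classes:
        if c == target_class:
            pools[c] = dataset.class_indices(target_class)
        else:
            pool = np.flatnonzero(labels != c)
            if len(pool) == 0:
                raise ValueError(
                    f"donor pool for block {c!r} is empty (all samples are "
                    f"labelled {c!r}); inter-class crossover needs >=2 classes"
                )
            pools[c] = pool
    return _generate(dataset, signatures, target_class, n, config, pools, "inter")
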