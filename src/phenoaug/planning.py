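"""Class-size planning, reference augmenters, and the augmentation driver.

All augmentation methods share one registry signature::

    fn(dataset, signatures, target_class, n, config: AugmentConfig)
        -> list[SyntheticSample]

and the driver :func:`augment_dataset` applies a per-class plan, appending
synthetic samples to the untouched real rows.  Synthetic samples never serve
as donors or subset members for later synthetic samples — every method draws
from real data only, preventing drift compounding.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from . import crossover as _xo
from . import parametric as _pm
from .core_data import (
    CONTINUOUS,
    AugmentationPlan,
    ExpressionDataset,
    SignatureSet,
    SyntheticSample,
)


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

def build_plan(
    labels: Sequence[str], mode: str, fixed_size: int | None = None
) -> AugmentationPlan:
    """Derive per-class target sizes from the observed label counts.

    ``max`` mode oversamples every minority class up to the majority size;
    ``fixed`` mode lifts every class to ``fixed_size`` (which must be at
    least the largest observed class — down-sampling is never performed).
    """
    labels = [str(l) for l in labels]
    if not labels:
        raise ValueError("labels are empty")
    observed: dict[str, int] = {}
    for l in labels:
        observed[l] = observed.get(l, 0) + 1
    if mode == "max":
        target = max(observed.values())
        per_class = {c: target for c in observed}
        return AugmentationPlan(mode="max", per_class_target=per_class, observed=observed)
    if mode == "fixed":
        if fixed_size is None or fixed_size < 1:
            raise ValueError("fixed mode requires a positive fixed_size")
        big = max(observed.values())
        if fixed_size < big:
            raise ValueError(
                f"fixed_size {fixed_size} is below the largest observed class "
                f"({big}); classes are never down-sampled"
            )
        per_class = {c: fixed_size for c in observed}
        return AugmentationPlan(mode="fixed", per_class_target=per_class,
                                observed=observed, fixed_size=fixed_size)
    raise ValueError(f"unknown plan mode {mode!r}")


# ---------------------------------------------------------------------------
# Shared config
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """One configuration object threaded through every registered method.

    ``rng_seed`` seeds all randomness (child seeds are derived per class so a
    whole-dataset augmentation is reproducible bit-for-bit).  ``subset_size``
    feeds the parametric samplers, ``smote_k`` the SMOTE neighbour count, and
    ``overlap_adaptation`` enables crossover on overlapping signatures.
    """

    rng_seed: int = 0
    subset_size: int = 10
    smote_k: int = 5
    overlap_adaptation: bool = False
    continuous_input: str = "reject"


# ---------------------------------------------------------------------------
# Baseline augmenters
# ---------------------------------------------------------------------------

def random_oversample(
    dataset: ExpressionDataset,
    signatures: SignatureSet | None,
    target_class: str,
    n: int,
    config: AugmentConfig | None = None,
) -> list[SyntheticSample]:
    """Sampling with replacement: copy whole rows of uniformly drawn
    target-class samples."""
    config = config or AugmentConfig()
    pool = dataset.class_indices(target_class)
    if len(pool) == 0:
        raise ValueError(f"target class {target_class!r} has no observed samples")
    rng = np.random.default_rng(config.rng_seed)
    out = []
    for _ in range(n):
        donor = int(pool[rng.integers(len(pool))])
        out.append(SyntheticSample(
            values=dataset.matrix[donor].copy(), label=target_class,
            method="replacement",
            provenance={"source": dataset.sample_ids[donor]},
            seed_state=config.rng_seed,
        ))
    return out


def smote_oversample(
    dataset: ExpressionDataset,
    signatures: SignatureSet | None,
    target_class: str,
    n: int,
    config: AugmentConfig | None = None,
) -> list[SyntheticSample]:
    """Vanilla SMOTE: each synthetic sample lies on the segment between a
    target-class sample and one of its ``k`` nearest same-class neighbours
    (Euclidean), at a uniform random position.  Provenance records both
    endpoints and the gap."""
    config = config or AugmentConfig()
    k = config.smote_k
    pool = dataset.class_indices(target_class)
    if len(pool) < k + 1:
        raise ValueError(
            f"SMOTE needs at least k+1 = {k + 1} samples in class "
            f"{target_class!r} (found {len(pool)}); lower smote_k"
        )
    X = dataset.matrix[pool]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(config.rng_seed)
    out = []
    for _ in range(n):
        i = int(rng.integers(len(pool)))
        j = int(neigh[i, rng.integers(k)])
        gap = float(rng.random())
        values = X[i] + gap * (X[j] - X[i])
        out.append(SyntheticSample(
            values=values, label=target_class, method="smote",
            provenance={
                "endpoints": [dataset.sample_ids[pool[i]], dataset.sample_ids[pool[j]]],
                "gap": gap,
            },
            seed_state=config.rng_seed,
        ))
    return out


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _intra(ds, sigs, cls, n, cfg: AugmentConfig):
    xc = _xo.CrossoverConfig(rng_seed=cfg.rng_seed, overlap_adaptation=cfg.overlap_adaptation)
    return _xo.intra_class_crossover(ds, sigs, cls, n, xc)


def _inter(ds, sigs, cls, n, cfg: AugmentConfig):
    xc = _xo.CrossoverConfig(rng_seed=cfg.rng_seed, overlap_adaptation=cfg.overlap_adaptation)
    return _xo.inter_class_crossover(ds, sigs, cls, n, xc)


def _parametric(fn) -> Callable:
    def wrapped(ds, sigs, cls, n, cfg: AugmentConfig):
        pc = _pm.ParametricConfig(subset_size=cfg.subset_size, rng_seed=cfg.rng_seed,
                                  continuous_input=cfg.continuous_input)
        return fn(ds, cls, n, pc)
    return wrapped


METHODS: dict[str, Callable] = {
    "intra": _intra,
    "inter": _inter,
    "mod_gp": _parametric(_pm.modified_gamma_poisson),
    "mod_poisson": _parametric(_pm.modified_poisson),
    "classic_gp": _parametric(_pm.classic_gamma_poisson),
    "classic_poisson": _parametric(_pm.classic_poisson),
    "replacement": random_oversample,
    "smote": smote_oversample,
}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class AugmentedDataset:
    """Real samples plus plan-mandated synthetic samples.

    ``dataset`` holds the combined matrix (real rows first, bit-identical to
    the input); ``is_synthetic`` marks the appended rows and ``provenance``
    carries one record per synthetic sample.
    """

    dataset: ExpressionDataset
    is_synthetic: np.ndarray
    provenance: list[dict]
    method: str
    plan: AugmentationPlan = field(repr=False)

    @property
    def n_synthetic(self) -> int:
        return int(self.is_synthetic.sum())


def _child_seed(seed: int, index: int) -> int:
    """Deterministic per-class seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def augment_dataset(
    dataset: ExpressionDataset,
    signatures: SignatureSet | None,
    method: str,
    plan: AugmentationPlan,
    config: AugmentConfig | None = None,
) -> AugmentedDataset:
    """Apply one registered method class-by-class until every class reaches
    its planned target size.  Real rows pass through untouched; synthetic ids
    are ``{method}_{class}_{index:05d}``."""
    if method not in METHODS:
        raise KeyError(f"unknown method {method!r}; available: {sorted(METHODS)}")
    config = config or AugmentConfig()
    fn = METHODS[method]

    # class ordering follows the signature file when available
    if signatures is not None:
        order = [c for c in signatures.classes if c in plan.per_class_target]
        order += [c for c in plan.per_class_target if c not in order]
    else:
        order = list(plan.per_class_target)

    synth: list[SyntheticSample] = []
    for pos, cls in enumerate(order):
        n_c = plan.per_class_target[cls] - plan.observed.get(cls, 0)
        if n_c <= 0:
            continue
        sub_cfg = AugmentConfig(
            rng_seed=_child_seed(config.rng_seed, pos),
            subset_size=config.subset_size, smote_k=config.smote_k,
            overlap_adaptation=config.overlap_adaptation,
            continuous_input=config.continuous_input,
        )
        synth.extend(fn(dataset, signatures, cls, n_c, sub_cfg))

    if synth:
        add = np.vstack([s.values for s in synth])
        matrix = np.vstack([dataset.matrix, add])
        new_ids = []
        counters: dict[str, int] = {}
        for s in synth:
            i = counters.get(s.label, 0)
            counters[s.label] = i + 1
            new_ids.append(f"{method}_{s.label}_{i:05d}")
        labels = list(dataset.labels) + [s.label for s in synth]
        sample_ids = list(dataset.sample_ids) + new_ids
        integral = bool(np.all(add == np.rint(add)) and np.all(add >= 0))
        scale = dataset.scale if (dataset.scale == CONTINUOUS or integral) else CONTINUOUS
    else:
        matrix = dataset.matrix.copy()
        labels, sample_ids, scale = list(dataset.labels), list(dataset.sample_ids), dataset.scale

    combined = ExpressionDataset(matrix=matrix, sample_ids=sample_ids,
                                 gene_ids=list(dataset.gene_ids), labels=labels,
                                 scale=scale)
    flags = np.zeros(combined.n_samples, dtype=bool)
    flags[dataset.n_samples:] = True
    provenance = [
        {"sample_id": sid, "label": s.label, "method": s.method,
         "seed_state": s.seed_state, **s.provenance}
        for sid, s in zip(sample_ids[dataset.n_samples:], synth)
    ]
    return AugmentedDataset(dataset=combined, is_synthetic=flags,
                            provenance=provenance, method=method, plan=plan)
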