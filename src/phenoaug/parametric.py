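"""Signature-independent augmentation: Gamma-Poisson and Poisson resampling.

The modified samplers re-estimate distribution parameters for *every*
generated observation from a freshly drawn subset ``S`` of same-class
samples, producing a mixture over subsets that injects between-subset
diversity while preserving class characteristics.  Per gene ``j``:

* modified Gamma-Poisson: method-of-moments on the subset —
  ``mu = mean(S)``, ``sigma2 = var(S)`` (unbiased, divisor ``|S|-1``),
  ``alpha = mu^2/sigma2`` (shape), ``beta = mu/sigma2`` (rate); then
  ``lambda_j ~ Gamma(alpha_j, rate=beta_j)`` and ``y_j ~ Poisson(lambda_j)``.
  Marginally over the Gamma this is a negative binomial with mean ``mu`` and
  variance ``mu + sigma2``.
* modified Poisson: ``lambda_j = mean(S)``, ``y_j ~ Poisson(lambda_j)``.

The classic variants estimate parameters once from the whole target class;
every generated sample then shares that single parameter set.  Setting
``subset_size`` equal to the class size makes the modified samplers
distributionally identical to the classic ones.

The Gamma is parameterized by shape and *rate* so that its mean is
``alpha/beta = mu`` and its variance ``alpha/beta^2 = sigma2`` — asserted by
a self-check property test, because shape/scale confusion is the classic bug.
Genes with zero subset variance or zero mean, where the moment estimator is
undefined, fall back to a pure ``Poisson(mu)`` draw (``Poisson(0)`` handles
all-zero genes naturally).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import CONTINUOUS, ExpressionDataset, SyntheticSample

logger = logging.getLogger(__name__)


@dataclass
class ParametricConfig:
    """Hyperparameters for the parametric samplers.

    ``subset_size`` (|S|) is the user hyperparameter controlling subset
    diversity; it must be >= 2 so the sample variance exists.  Continuous
    (e.g. RMA microarray) input is rejected unless explicitly allowed —
    estimation then runs on the continuous values but the outputs are still
    integer Poisson draws, which changes the data scale (see docs).
    """

    subset_size: int = 10
    rng_seed: int = 0
    continuous_input: str = "reject"  # or "allow"
    zero_variance_fallback: str = "poisson_at_mean"

    def __post_init__(self) -> None:
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2 (sample variance needs |S|-1 >= 1)")
        if self.continuous_input not in ("reject", "allow"):
            raise ValueError("continuous_input must be 'reject' or 'allow'")
        if self.zero_variance_fallback != "poisson_at_mean":
            raise ValueError("only the 'poisson_at_mean' fallback is implemented")


@dataclass
class GammaPoissonParams:
    """Per-gene method-of-moments Gamma parameters for one estimating subset.

    ``fallback`` flags genes where ``sigma2 == 0`` or ``mu == 0`` (shape/rate
    undefined); those genes are drawn ``Poisson(mu)`` instead.
    """

    mean: np.ndarray
    variance: np.ndarray
    shape: np.ndarray
    rate: np.ndarray
    fallback: np.ndarray


def estimate_gp_params(subset: np.ndarray) -> GammaPoissonParams:
    """Method-of-moments Gamma parameters from a samples x genes sub-matrix."""
    subset = np.asarray(subset, dtype=np.float64)
    if subset.ndim != 2 or subset.shape[0] < 2:
        raise ValueError("parameter estimation needs a 2-D subset with >= 2 rows")
    mu = subset.mean(axis=0)
    sigma2 = subset.var(axis=0, ddof=1)
    fallback = (sigma2 == 0) | (mu == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = np.where(fallback, np.nan, mu**2 / sigma2)
        rate = np.where(fallback, np.nan, mu / sigma2)
    return GammaPoissonParams(mean=mu, variance=sigma2, shape=shape, rate=rate,
                              fallback=fallback)


def _draw_gamma_poisson(params: GammaPoissonParams, rng: np.random.Generator) -> np.ndarray:
    lam = params.mean.copy()
    ok = ~params.fallback
    lam[ok] = rng.gamma(shape=params.shape[ok], scale=1.0 / params.rate[ok])
    return rng.poisson(lam).astype(np.float64)


def _class_pool(
    dataset: ExpressionDataset, target_class: str, config: ParametricConfig
) -> tuple[np.ndarray, int]:
    if dataset.scale == CONTINUOUS and config.continuous_input == "reject":
        raise ValueError(
            "parametric samplers expect count data; set "
            "ParametricConfig.continuous_input='allow' to force (output will "
            "be integer draws on the input's scale)"
        )
    pool = dataset.class_indices(target_class)
    if len(pool) < 2:
        raise ValueError(
            f"target class {target_class!r} has {len(pool)} sample(s); "
            "parametric estimation needs at least 2"
        )
    size = config.subset_size
    if size > len(pool):
        logger.warning(
            "subset_size %d exceeds class %r size %d; clamping (sampler "
            "reverts toward its classic behaviour)", size, target_class, len(pool)
        )
        size = len(pool)
    return pool, size


def modified_gamma_poisson(
    dataset: ExpressionDataset,
    target_class: str,
    n: int,
    config: ParametricConfig | None = None,
) -> list[SyntheticSample]:
    """Draw ``n`` samples, re-estimating Gamma parameters per observation from
    a fresh uniformly drawn same-class subset of size ``subset_size``."""
    config = config or ParametricConfig()
    pool, size = _class_pool(dataset, target_class, config)
    rng = np.random.default_rng(config.rng_seed)
    out = []
    for _ in range(n):
        subset_idx = rng.choice(pool, size=size, replace=False)
        params = estimate_gp_params(dataset.matrix[subset_idx])
        values = _draw_gamma_poisson(params, rng)
        out.append(SyntheticSample(
            values=values, label=target_class, method="mod_gp",
            provenance={"subset": [dataset.sample_ids[i] for i in subset_idx]},
            seed_state=config.rng_seed,
        ))
    return out


def modified_poisson(
    dataset: ExpressionDataset,
    target_class: str,
    n: int,
    config: ParametricConfig | None = None,
) -> list[SyntheticSample]:
    """Draw ``n`` samples; per observation the Poisson rate is the mean of a
    freshly drawn same-class subset."""
    config = config or ParametricConfig()
    pool, size = _class_pool(dataset, target_class, config)
    rng = np.random.default_rng(config.rng_seed)
    out = []
    for _ in range(n):
        subset_idx = rng.choice(pool, size=size, replace=False)
        lam = dataset.matrix[subset_idx].mean(axis=0)
        values = rng.poisson(lam).astype(np.float64)
        out.append(SyntheticSample(
            values=values, label=target_class, method="mod_poisson",
            provenance={"subset": [dataset.sample_ids[i] for i in subset_idx]},
            seed_state=config.rng_seed,
        ))
    return out


def classic_gamma_poisson(
    dataset: ExpressionDataset,
    target_class: str,
    n: int,
    config: ParametricConfig | None = None,
) -> list[SyntheticSample]:
    """Gamma-Poisson sampling with parameters estimated once from *all*
    target-class samples; all ``n`` draws share that parameter set."""
    config = config or ParametricConfig()
    pool, _ = _class_pool(dataset, target_class, config)
    rng = np.random.default_rng(config.rng_seed)
    params = estimate_gp_params(dataset.matrix[pool])
    subset_ids = [dataset.sample_ids[i] for i in pool]
    return [
        SyntheticSample(
            values=_draw_gamma_poisson(params, rng), label=target_class,
            method="classic_gp", provenance={"subset": subset_ids},
            seed_state=config.rng_seed,
        )
        for _ in range(n)
    ]


def classic_poisson(
    dataset: ExpressionDataset,
    target_class: str,
    n: int,
    config: ParametricConfig | None = None,
) -> list[SyntheticSample]:
    """Poisson sampling at the whole-class mean rate."""
    config = config or ParametricConfig()
    pool, _ = _class_pool(dataset, target_class, config)
    rng = np.random.default_rng(config.rng_seed)
    lam = dataset.matrix[pool].mean(axis=0)
    subset_ids = [dataset.sample_ids[i] for i in pool]
    return [
        SyntheticSample(
            values=rng.poisson(lam).astype(np.float64), label=target_class,
            method="classic_poisson", provenance={"subset": subset_ids},
            seed_state=config.rng_seed,
        )
        for _ in range(n)
    ]
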