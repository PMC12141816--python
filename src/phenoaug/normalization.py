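"""Post-augmentation normalization: FPKM + log2 for counts, passthrough
otherwise.

FPKM for sample ``i`` and gene ``j``::

    FPKM_ij = counts_ij * 1e9 / (library_size_i * length_j)

with ``library_size_i`` summed over the working gene panel (the matrix has
already been reduced to signature genes, so transcriptome-wide library sizes
are unavailable; panel-relative FPKM therefore differs from transcriptome
FPKM by a per-sample constant — invariances and classifier inputs are
unaffected, but absolute values should not be compared across panels).
The transform then applies ``log2(FPKM + pseudocount)``.

Continuous-mode data (e.g. RMA-normalized microarray intensities) pass
through unchanged.  An optional z-score standardization can be fitted on the
training split and applied to held-out splits.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import CONTINUOUS, COUNTS, ExpressionDataset


@dataclass
class GeneLengthTable:
    """Effective gene lengths in base pairs (> 0), keyed by gene id."""

    lengths: dict[str, float]

    def __post_init__(self) -> None:
        self.lengths = {str(g): float(v) for g, v in self.lengths.items()}
        bad = [g for g, v in self.lengths.items() if not (v > 0 and np.isfinite(v))]
        if bad:
            raise ValueError(f"non-positive gene lengths for: {sorted(bad)[:5]}")

    def vector(self, gene_ids: list[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.lengths]
        if missing:
            raise KeyError(f"gene lengths missing for: {sorted(missing)[:5]}")
        return np.asarray([self.lengths[g] for g in gene_ids], dtype=np.float64)


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length_bp"])
    return GeneLengthTable(lengths=dict(zip(df["gene_id"].astype(str), df["length_bp"])))


def write_gene_lengths(table: GeneLengthTable, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(table.lengths), "length_bp": list(table.lengths.values())}
    ).to_csv(path, sep="\t", header=False, index=False)


def fpkm_log_transform(
    counts: ExpressionDataset,
    lengths: GeneLengthTable,
    pseudocount: float = 1.0,
    force: bool = False,
) -> ExpressionDataset:
    """log2(FPKM + pseudocount) per cell; library size per sample over the
    panel.

    ``force=True`` admits nonnegative non-integer matrices (e.g. SMOTE
    interpolations of counts, which are marked continuous) — the formula is
    unchanged.
    """
    if counts.scale != COUNTS and not force:
        raise ValueError("fpkm_log_transform expects counts-mode data (or force=True)")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if np.any(counts.matrix < 0):
        raise ValueError("negative values cannot be FPKM-normalized")
    lib = counts.matrix.sum(axis=1)
    if np.any(lib == 0):
        i = int(np.argmin(lib))
        raise ValueError(f"sample {counts.sample_ids[i]!r} has zero library size")
    length = lengths.vector(counts.gene_ids)
    fpkm = counts.matrix * 1e9 / (lib[:, None] * length[None, :])
    return ExpressionDataset(
        matrix=np.log2(fpkm + pseudocount),
        sample_ids=list(counts.sample_ids),
        gene_ids=list(counts.gene_ids),
        labels=list(counts.labels),
        scale=CONTINUOUS,
    )


@dataclass
class TrainFittedScaler:
    """Per-gene z-score statistics fitted on the training split only."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, ds: ExpressionDataset) -> ExpressionDataset:
        out = ds.copy()
        out.matrix = (out.matrix - self.mean[None, :]) / self.std[None, :]
        out.scale = CONTINUOUS
        return out


def fit_transform_train_test(
    train: ExpressionDataset,
    test: ExpressionDataset,
    lengths: GeneLengthTable | None = None,
    pseudocount: float = 1.0,
    standardize: bool = False,
    force: bool = False,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Apply the normalization path to paired splits.

    FPKM+log is a per-sample transform, so both splits use the same formula
    independently; the optional standardization is the only dataset-level
    statistic and it is fitted on the (augmented) training split only, never
    reading test rows or labels.  Continuous training data pass through.
    """
    if train.gene_ids != test.gene_ids:
        raise ValueError("train and test gene panels differ")
    if train.scale == COUNTS or force:
        if lengths is None:
            raise ValueError("count data require a gene-length table")
        train_t = fpkm_log_transform(train, lengths, pseudocount, force=force)
        test_t = fpkm_log_transform(test, lengths, pseudocount, force=True)
    else:
        train_t, test_t = train.copy(), test.copy()
    if standardize:
        std = train_t.matrix.std(axis=0, ddof=0)
        std = np.where(std == 0, 1.0, std)
        scaler = TrainFittedScaler(mean=train_t.matrix.mean(axis=0), std=std)
        train_t, test_t = scaler.apply(train_t), scaler.apply(test_t)
    return train_t, test_t
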