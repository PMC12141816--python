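"""Domain types and plain-text I/O for labelled expression cohorts.

The working object throughout the package is a dense samples x genes matrix
with per-sample phenotype labels (:class:`ExpressionDataset`) together with a
:class:`SignatureSet` mapping each phenotype class to an ordered gene list.
Signature blocks induce the column partition that the crossover samplers mix
and match; the parametric samplers ignore signatures entirely.

All readers and writers speak delimited text (TSV/CSV): a dense expression
matrix, a two-column labels file and GMT or two-column signature files.  Raw
sequencing formats and probe-level microarray handling are out of scope.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNTS = "counts"
CONTINUOUS = "continuous"
_SCALES = (COUNTS, CONTINUOUS)


# ---------------------------------------------------------------------------
# ExpressionDataset
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with one class label per sample.

    Parameters
    ----------
    matrix:
        Dense ``(n_samples, n_genes)`` array.  In ``counts`` mode every entry
        must be a nonnegative integer (stored as float64 for uniformity); in
        ``continuous`` mode any finite real is allowed.
    sample_ids, gene_ids:
        Unique identifiers for rows and columns.
    labels:
        Class identifier per sample; opaque strings.
    scale:
        ``"counts"`` for raw RNA-seq counts, ``"continuous"`` for
        pre-normalized values (e.g. RMA microarray intensities or log-FPKM).
    """

    matrix: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str]
    scale: str = COUNTS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = [str(l) for l in self.labels]
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x genes)")
        n, g = self.matrix.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids "
                f"and {len(self.labels)} labels"
            )
        if len(self.gene_ids) != g:
            raise ValueError(f"matrix has {g} columns but {len(self.gene_ids)} gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")
        if self.scale == COUNTS:
            _validate_counts(self.matrix, self.sample_ids, self.gene_ids)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        """Class identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for l in self.labels:
            counts[l] = counts.get(l, 0) + 1
        return counts

    def class_indices(self, label: str) -> np.ndarray:
        """Row indices of samples carrying ``label``."""
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == label)

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def subset(self, rows: Sequence[int] | np.ndarray) -> "ExpressionDataset":
        rows = np.asarray(rows, dtype=int)
        return ExpressionDataset(
            matrix=self.matrix[rows].copy(),
            sample_ids=[self.sample_ids[i] for i in rows],
            gene_ids=list(self.gene_ids),
            labels=[self.labels[i] for i in rows],
            scale=self.scale,
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix.copy(),
            sample_ids=list(self.sample_ids),
            gene_ids=list(self.gene_ids),
            labels=list(self.labels),
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.gene_ids)


def _validate_counts(matrix: np.ndarray, sample_ids: list[str], gene_ids: list[str]) -> None:
    """Raise on the first negative or non-integer cell of a counts matrix."""
    bad = (matrix < 0) | (matrix != np.rint(matrix))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "counts-mode matrix must contain nonnegative integers; first "
            f"offending cell: sample {sample_ids[i]!r}, gene {gene_ids[j]!r} "
            f"= {matrix[i, j]!r}"
        )


# ---------------------------------------------------------------------------
# SignatureSet
# ---------------------------------------------------------------------------

DISJOINT = "disjoint"
OVERLAPPING = "overlapping"


@dataclass
class SignatureSet:
    """Ordered mapping of phenotype class -> ordered gene list (a "block").

    A gene may be shared by at most two blocks (the pairwise-overlap case of
    e.g. the Luminal A / Luminal B PAM50 signatures); a gene found in more
    than two blocks is rejected.
    """

    classes: list[str]
    blocks: dict[str, list[str]]
    overlap_policy: str = field(init=False)

    def __post_init__(self) -> None:
        self.classes = [str(c) for c in self.classes]
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class in signature set")
        if set(self.blocks) != set(self.classes):
            raise ValueError("blocks must cover exactly the declared classes")
        membership: dict[str, list[str]] = {}
        for c in self.classes:
            genes = [str(g) for g in self.blocks[c]]
            if not genes:
                raise ValueError(f"signature block for class {c!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate gene within block {c!r}")
            self.blocks[c] = genes
            for g in genes:
                membership.setdefault(g, []).append(c)
        over = {g: cs for g, cs in membership.items() if len(cs) > 1}
        if any(len(cs) > 2 for cs in over.values()):
            bad = [g for g, cs in over.items() if len(cs) > 2]
            raise ValueError(
                f"genes shared by more than two signature blocks are not "
                f"supported: {sorted(bad)}"
            )
        self.overlap_policy = OVERLAPPING if over else DISJOINT
        self._membership = membership

    @property
    def all_genes(self) -> list[str]:
        """Union of blocks in signature order, shared genes listed once."""
        seen: dict[str, None] = {}
        for c in self.classes:
            for g in self.blocks[c]:
                seen.setdefault(g, None)
        return list(seen)

    def overlap_pairs(self) -> dict[tuple[str, str], list[str]]:
        """Shared genes grouped by the (ordered) pair of blocks sharing them."""
        pairs: dict[tuple[str, str], list[str]] = {}
        for g, cs in self._membership.items():
            if len(cs) == 2:
                key = tuple(sorted(cs, key=self.classes.index))
                pairs.setdefault(key, []).append(g)  # type: ignore[arg-type]
        return pairs


# ---------------------------------------------------------------------------
# AugmentationPlan
# ---------------------------------------------------------------------------

@dataclass
class AugmentationPlan:
    """Per-class target sizes derived from a mode and the observed counts.

    ``max`` mode lifts every minority class to the majority size; ``fixed``
    mode lifts every class to ``fixed_size``.  Down-sampling is never allowed.
    """

    mode: str
    per_class_target: dict[str, int]
    observed: dict[str, int]
    fixed_size: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("max", "fixed"):
            raise ValueError("plan mode must be 'max' or 'fixed'")
        for c, target in self.per_class_target.items():
            if target < self.observed[c]:
                raise ValueError(
                    f"target {target} for class {c!r} is below its observed "
                    f"size {self.observed[c]} (down-sampling is not supported)"
                )

    def synthetic_counts(self) -> dict[str, int]:
        return {c: self.per_class_target[c] - self.observed[c] for c in self.per_class_target}


# ---------------------------------------------------------------------------
# SyntheticSample
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSample:
    """One generated sample with full provenance.

    ``provenance`` is method-specific: crossover stores the per-block donor
    sample id (and, for overlapping signatures, the block each shared gene was
    assigned to); parametric methods store the estimating-subset sample ids;
    replacement stores the source sample; SMOTE stores the two endpoints and
    the interpolation gap.
    """

    values: np.ndarray
    label: str
    method: str
    provenance: dict
    seed_state: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    scale: str,
    orientation: str = "samples_in_rows",
    sep: str | None = None,
) -> ExpressionDataset:
    """Load an expression matrix plus labels file into a validated dataset.

    The matrix is delimited text with a header row and the first column
    holding row identifiers.  ``orientation`` declares whether rows are
    samples (default) or genes; internally the dataset is always samples x
    genes.  The labels file is two-column, headerless: ``sample_id<TAB>class``.
    Samples without a label are dropped with a logged count.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    msep = sep or _sep_for(matrix_path)
    df = pd.read_csv(matrix_path, sep=msep, index_col=0)
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {matrix_path}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate gene ids in {matrix_path}")

    lab = pd.read_csv(labels_path, sep=sep or _sep_for(labels_path), header=None,
                      names=["sample_id", "label"], dtype=str)
    if lab["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in labels file {labels_path}")
    label_map = dict(zip(lab["sample_id"], lab["label"]))

    keep = [s for s in df.index.astype(str) if s in label_map]
    dropped = df.shape[0] - len(keep)
    if dropped:
        logger.warning("dropped %d sample(s) with no label in %s", dropped, labels_path)
    if not keep:
        raise ValueError("no samples with labels remain")
    df = df.loc[keep]
    values = df.to_numpy(dtype=np.float64)
    return ExpressionDataset(
        matrix=values,
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        labels=[label_map[str(s)] for s in df.index],
        scale=scale,
    )


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    sep: str | None = None,
) -> None:
    """Write matrix (samples in rows, header + index) and headerless labels."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    msep = sep or _sep_for(matrix_path)
    df = dataset.to_frame()
    if dataset.scale == COUNTS:
        df = df.astype(np.int64)
    df.to_csv(matrix_path, sep=msep)
    pd.DataFrame({"sample_id": dataset.sample_ids, "label": dataset.labels}).to_csv(
        labels_path, sep=sep or _sep_for(labels_path), header=False, index=False
    )


def read_signatures(path: str | Path, format: str = "gmt") -> SignatureSet:
    """Read a signature file in GMT (class, description, genes...) or
    two-column (class, gene) format; overlap policy is inferred from gene
    multiplicity across blocks."""
    path = Path(path)
    classes: list[str] = []
    blocks: dict[str, list[str]] = {}
    if format == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need class, description, >=1 gene): {line!r}")
            c, genes = parts[0], [g for g in parts[2:] if g]
            if c in blocks:
                raise ValueError(f"class {c!r} appears more than once in {path}")
            classes.append(c)
            blocks[c] = genes
    elif format == "two_column":
        # a class's genes must be contiguous: once a block is "closed" by the
        # appearance of a different class it may not reopen
        last: str | None = None
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t" if "\t" in line else None)
            if len(parts) != 2:
                raise ValueError(f"malformed two-column signature line: {line!r}")
            c, g = parts
            if c not in blocks:
                classes.append(c)
                blocks[c] = []
            elif c != last:
                raise ValueError(f"genes of class {c!r} are not contiguous in {path}")
            blocks[c].append(g)
            last = c
    else:
        raise ValueError(f"unknown signature format {format!r}")
    return SignatureSet(classes=classes, blocks=blocks)


def write_signatures(signatures: SignatureSet, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([c, description, *signatures.blocks[c]]) for c in signatures.classes
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Block partition and panel reduction
# ---------------------------------------------------------------------------

def block_partition(
    dataset: ExpressionDataset, signatures: SignatureSet
) -> list[tuple[str, np.ndarray]]:
    """Column index lists, one per class, in signature order.

    Order-independent with respect to the dataset's column ordering: indices
    are looked up by gene id.  In disjoint mode the lists are pairwise
    disjoint and cover exactly the signature panel.
    """
    idx = dataset.gene_index()
    missing = [g for c in signatures.classes for g in signatures.blocks[c] if g not in idx]
    if missing:
        raise KeyError(f"signature genes absent from dataset: {sorted(set(missing))}")
    return [
        (c, np.asarray([idx[g] for g in signatures.blocks[c]], dtype=int))
        for c in signatures.classes
    ]


def restrict_to_panel(
    dataset: ExpressionDataset, signatures: SignatureSet
) -> ExpressionDataset:
    """Drop genes outside every signature block (logged); the signature panel
    is the working gene universe for all downstream steps."""
    panel = signatures.all_genes
    idx = dataset.gene_index()
    missing = [g for g in panel if g not in idx]
    if missing:
        raise KeyError(f"signature genes absent from dataset: {sorted(missing)}")
    dropped = dataset.n_genes - len(panel)
    if dropped:
        logger.info("dropping %d gene(s) outside the signature panel", dropped)
    cols = [idx[g] for g in panel]
    return ExpressionDataset(
        matrix=dataset.matrix[:, cols].copy(),
        sample_ids=list(dataset.sample_ids),
        gene_ids=list(panel),
        labels=list(dataset.labels),
        scale=dataset.scale,
    )
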