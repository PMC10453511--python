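"""Expression time-series and gold-standard network I/O.

The on-disk dialect mirrors GeneNetWeaver/DREAM exports: a UTF-8
tab-separated table whose header row holds gene names (optionally preceded
by a ``Time`` column), with blank lines separating successive experiments.
A gold-standard network is a three-column TSV ``regulator<TAB>target<TAB>{0,1}``.

In memory a dataset is a list of ``(b, n)`` observation-by-gene matrices
sharing one gene order.  Min-max normalization is per gene, with constants
taken from the designated training experiments only so that evaluation
experiments never leak into the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConsistencyError, DataError, FormatError

__all__ = [
    "ExpressionDataset",
    "SupervisedSet",
    "GoldNetwork",
    "read_expression",
    "write_expression",
    "min_max_normalize",
    "denormalize",
    "make_supervised",
    "read_gold_network",
    "write_gold_network",
    "ordered_pairs",
]


@dataclass
class ExpressionDataset:
    """Named genes observed over time, grouped into experiments.

    ``experiments[e][t, i]`` is the expression of gene ``i`` at observation
    ``t`` of experiment ``e``.  All experiments share the gene order.
    """

    gene_names: list[str]
    experiments: list[np.ndarray]
    normalized: bool = False
    norm_min: np.ndarray | None = None
    norm_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.gene_names)
        self.experiments = [np.asarray(e, dtype=float) for e in self.experiments]
        for e in self.experiments:
            if e.ndim != 2 or e.shape[1] != n:
                raise ConsistencyError(
                    f"experiment shape {e.shape} inconsistent with {n} genes"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_observations(self) -> int:
        """Observations per experiment; requires all experiments equal-length."""
        lengths = {e.shape[0] for e in self.experiments}
        if len(lengths) != 1:
            raise ConsistencyError(f"experiments have unequal lengths {sorted(lengths)}")
        return lengths.pop()

    def mean_experiment(self) -> np.ndarray:
        """Element-wise average of all experiments, shape ``(b, n)``.

        This is the evaluation target: averaging the replicates damps
        measurement noise that any single run carries.
        """
        b = self.n_observations
        return np.mean([e for e in self.experiments], axis=0).reshape(b, self.n_genes)

    def gene_max(self) -> np.ndarray:
        """Per-gene maximum observed expression across all experiments."""
        return np.max([e.max(axis=0) for e in self.experiments], axis=0)


@dataclass
class SupervisedSet:
    """One gene's forecasting dataset: windows of all genes -> next value.

    Row ``j`` of ``inputs`` flattens observations ``t = j .. j+m-1`` of every
    gene, gene-major (gene 1's m lags oldest-first, then gene 2's, ...);
    ``targets[j]`` is the focal gene's value at ``t = j+m``.
    """

    inputs: np.ndarray
    targets: np.ndarray
    gene_index: int
    window: int

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass
class GoldNetwork:
    """Ground-truth directed edges over a known gene set."""

    gene_names: list[str]
    labels: dict[tuple[str, str], int] = field(default_factory=dict)
    include_self_loops: bool = False

    def label(self, regulator: str, target: str) -> int:
        return self.labels.get((regulator, target), 0)

    def label_vector(self) -> np.ndarray:
        """Labels over :func:`ordered_pairs`, aligned with flattened scores."""
        pairs = ordered_pairs(self.gene_names, self.include_self_loops)
        return np.array([self.label(r, t) for r, t in pairs], dtype=int)

    def n_positive(self) -> int:
        return int(self.label_vector().sum())


def ordered_pairs(
    gene_names: Sequence[str], include_self_loops: bool = False
) -> list[tuple[str, str]]:
    """Row-major (regulator, target) enumeration used for every flattening."""
    return [
        (r, t)
        for r in gene_names
        for t in gene_names
        if include_self_loops or r != t
    ]


def _parse_block(lines: list[str], header: list[str] | None) -> tuple[list[str], np.ndarray, bool]:
    """Parse one blank-line-delimited block; returns (header, values, had_time)."""
    fields = [ln.split("\t") for ln in lines]
    first = [f.strip() for f in fields[0]]

    def is_header(row: list[str]) -> bool:
        try:
            [float(v) for v in row]
            return False
        except ValueError:
            return True

    if is_header(first):
        header = first
        fields = fields[1:]
        if not fields:
            raise FormatError("block contains a header but no data rows")
    elif header is None:
        raise FormatError("first block must start with a header row of gene names")

    width = len(header)
    rows = []
    for row in fields:
        if len(row) != width:
            raise FormatError(
                f"ragged row: expected {width} columns, found {len(row)}"
            )
        try:
            rows.append([float(v) for v in row])
        except ValueError as exc:
            raise FormatError(f"non-numeric value in data row: {exc}") from None

    values = np.asarray(rows, dtype=float)
    had_time = header[0].lower() == "time"
    if had_time:
        t = values[:, 0]
        if np.any(np.diff(t) <= 0):
            raise FormatError("time column is not strictly increasing")
        values = values[:, 1:]
        header = header[1:]
    return header, values, had_time


def read_expression(path: str | Path | Sequence[str | Path]) -> ExpressionDataset:
    """Read one or more expression TSV files into a dataset.

    Blank lines separate experiments within a file; multiple files append
    further experiments and must agree on the gene header.
    """
    paths = [path] if isinstance(path, (str, Path)) else list(path)
    gene_names: list[str] | None = None
    experiments: list[np.ndarray] = []
    for p in paths:
        text = Path(p).read_text(encoding="utf-8")
        block: list[str] = []
        blocks: list[list[str]] = []
        for ln in text.splitlines():
            if ln.strip() == "":
                if block:
                    blocks.append(block)
                    block = []
            else:
                block.append(ln)
        if block:
            blocks.append(block)
        if not blocks:
            raise FormatError(f"{p}: no data found")
        header = None
        for blk in blocks:
            header, values, _ = _parse_block(blk, header)
            if gene_names is None:
                gene_names = header
            elif header != gene_names:
                raise ConsistencyError(
                    f"{p}: gene header {header} does not match {gene_names}"
                )
            if values.shape[1] != len(gene_names):
                raise ConsistencyError(
                    f"{p}: experiment has {values.shape[1]} genes, expected {len(gene_names)}"
                )
            experiments.append(values)
    assert gene_names is not None
    return ExpressionDataset(gene_names=gene_names, experiments=experiments)


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the dataset in the input dialect at full float precision."""
    lines = []
    header = "\t".join(ds.gene_names)
    for i, exp in enumerate(ds.experiments):
        if i > 0:
            lines.append("")
        lines.append(header)
        for row in exp:
            lines.append("\t".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def min_max_normalize(
    ds: ExpressionDataset, training_experiments: Sequence[int] | None = None
) -> ExpressionDataset:
    """Per-gene min-max scaling with constants from the training experiments.

    Evaluation experiments are transformed with the same constants, so their
    values may fall slightly outside [0, 1].  A constant gene maps to all
    zeros with a warning.
    """
    if ds.normalized:
        raise DataError("dataset is already normalized")
    idx = list(range(ds.n_experiments)) if training_experiments is None else list(training_experiments)
    if not idx:
        raise DataError("at least one training experiment is required")
    stacked = np.vstack([ds.experiments[i] for i in idx])
    lo = stacked.min(axis=0)
    hi = stacked.max(axis=0)
    span = hi - lo
    constant = span == 0
    if np.any(constant):
        names = [ds.gene_names[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant gene(s) {names} mapped to all zeros", stacklevel=2)
    safe = np.where(constant, 1.0, span)
    experiments = [
        np.where(constant, 0.0, (e - lo) / safe) for e in ds.experiments
    ]
    return ExpressionDataset(
        gene_names=list(ds.gene_names),
        experiments=experiments,
        normalized=True,
        norm_min=lo,
        norm_max=hi,
    )


def denormalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Invert :func:`min_max_normalize` using the stored constants."""
    if not ds.normalized or ds.norm_min is None or ds.norm_max is None:
        raise DataError("dataset is not normalized or lacks stored constants")
    span = ds.norm_max - ds.norm_min
    experiments = [e * span + ds.norm_min for e in ds.experiments]
    return ExpressionDataset(gene_names=list(ds.gene_names), experiments=experiments)


def make_supervised(
    ds: ExpressionDataset,
    gene_index: int,
    m: int,
    experiments: Sequence[int] | None = None,
) -> SupervisedSet:
    """Build the sliding-window forecasting set for one gene.

    Each experiment of length ``b`` yields ``b - m`` rows of dimension
    ``n * m``; experiments are concatenated and never windowed across their
    boundary.
    """
    if not ds.normalized:
        raise DataError("normalize the dataset before windowing")
    idx = list(range(ds.n_experiments)) if experiments is None else list(experiments)
    n = ds.n_genes
    if not 0 <= gene_index < n:
        raise DataError(f"gene_index {gene_index} out of range for {n} genes")
    xs, ys = [], []
    for e in idx:
        exp = ds.experiments[e]
        b = exp.shape[0]
        if not 1 <= m < b:
            raise DataError(f"window m={m} must satisfy 1 <= m < b={b}")
        for j in range(b - m):
            # gene-major, oldest lag first: row-major flatten of (n, m)
            xs.append(exp[j : j + m, :].T.reshape(-1))
            ys.append(exp[j + m, gene_index])
    return SupervisedSet(
        inputs=np.asarray(xs), targets=np.asarray(ys), gene_index=gene_index, window=m
    )


def read_gold_network(
    path: str | Path,
    gene_names: Sequence[str],
    include_self_loops: bool = False,
) -> GoldNetwork:
    """Read a DREAM-style gold standard; unlisted pairs default to absent."""
    known = set(gene_names)
    labels: dict[tuple[str, str], int] = {}
    for lineno, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise FormatError(f"line {lineno}: expected 3 tab-separated columns")
        reg, tgt, lab = (p.strip() for p in parts)
        if reg not in known or tgt not in known:
            raise ConsistencyError(f"line {lineno}: unknown gene in pair ({reg}, {tgt})")
        if lab not in {"0", "1"}:
            raise FormatError(f"line {lineno}: label {lab!r} not in {{0,1}}")
        if reg == tgt and not include_self_loops:
            warnings.warn(
                f"self-loop ({reg},{tgt}) retained but excluded from evaluation",
                stacklevel=2,
            )
        labels[(reg, tgt)] = int(lab)
    return GoldNetwork(
        gene_names=list(gene_names), labels=labels, include_self_loops=include_self_loops
    )


def write_gold_network(gold: GoldNetwork, path: str | Path) -> None:
    lines = [f"{r}\t{t}\t{lab}" for (r, t), lab in sorted(gold.labels.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
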