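"""Expression-matrix container and delimited-text readers.

The matrix is genes x samples, already normalized by the user; varpath
performs no internal transformation (no logging, no scaling), so the
statistics downstream are computed on the values exactly as provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ExpressionMatrix", "read_expression", "read_group_labels"]


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        2-D float array of shape ``(len(gene_ids), len(sample_ids))``.
        Missing values are not allowed: the per-group sample count ``n``
        entering the dispersion estimators must be unambiguous.
    group_labels
        Optional map sample_id -> group name. When present there must be
        exactly two distinct groups, each with at least two samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n_g, n_s = self.values.shape
        if n_g != len(self.gene_ids):
            raise ValidationError(
                f"row count {n_g} != number of gene ids {len(self.gene_ids)}"
            )
        if n_s != len(self.sample_ids):
            raise ValidationError(
                f"column count {n_s} != number of sample ids {len(self.sample_ids)}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.count_nonzero(~np.isfinite(self.values)))
            raise ValidationError(
                f"{bad} non-finite cell(s) in the expression matrix; "
                "missing values are not supported"
            )
        if self.group_labels is not None:
            unknown = set(self.group_labels) - set(self.sample_ids)
            if unknown:
                raise ValidationError(
                    f"group labels reference unknown samples: {sorted(unknown)[:5]}"
                )
            groups = sorted(set(self.group_labels.values()))
            if len(groups) != 2:
                raise ValidationError(
                    f"expected exactly 2 groups, found {len(groups)}: {groups}"
                )
            for g in groups:
                n = sum(1 for v in self.group_labels.values() if v == g)
                if n < 2:
                    raise ValidationError(f"group {g!r} has {n} sample(s); need >= 2")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> list[str]:
        """Sorted distinct group names (empty list when unlabeled)."""
        if self.group_labels is None:
            return []
        return sorted(set(self.group_labels.values()))

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        if self.group_labels is None:
            raise ValidationError("matrix has no group labels")
        idx = [
            j
            for j, s in enumerate(self.sample_ids)
            if self.group_labels.get(s) == group
        ]
        if not idx:
            raise ValidationError(f"group {group!r} absent from labels")
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression(
    path: str,
    sep: str = "\t",
    group_labels: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table (first column gene IDs, header row
    sample IDs). ``sep=','`` for CSV input."""
    # round_trip: parsed floats must reproduce written values bit-exactly
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found (wrong separator?)")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cell in expression matrix: {exc}")
    return ExpressionMatrix(
        gene_ids=[str(g).strip() for g in df.index],
        sample_ids=[str(s).strip() for s in df.columns],
        values=values,
        group_labels=group_labels,
    )


def read_group_labels(path: str, sep: str = "\t") -> dict[str, str]:
    """Read a two-column (sample_id, group) table, no header required."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need two columns (sample_id, group)")
    first = df.iloc[0]
    # tolerate an optional header line
    if str(first[0]).lower() in {"sample", "sample_id", "id"}:
        df = df.iloc[1:]
    labels = {
        str(s).strip(): str(g).strip() for s, g in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
    if len(labels) != len(df):
        raise ValidationError(f"{path}: duplicate sample ids in label file")
    return labels
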