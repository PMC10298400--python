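"""Domain types and delimited-text I/O for two-timepoint expression studies.

The analysis consumes two expression matrices (one per timepoint) over the
same samples and genes, plus per-sample metadata (group label ``A``/``B`` and
age in years).  The only derived structure is the per-group *contrast matrix*
``Y = R - S``: the componentwise difference between timepoint-2 and
timepoint-1 expression, one row per individual and one column per gene.

All alignment is by identifier, never by position: matrices whose rows or
columns are stored in a different order are reconciled by sample id and gene
name before any arithmetic.  Missing values are rejected rather than imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "ContrastMatrix",
    "StudyDesign",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "build_contrasts",
]

#: Minimum per-group sample count: OLS with intercept needs df = n - 2 >= 1.
MIN_GROUP_SIZE = 3

Orientation = Literal["samples-as-rows", "genes-as-rows"]


class FormatError(ValueError):
    """A delimited file could not be parsed as a numeric matrix."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant (duplicates, NA, ...)."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Expression values for one timepoint, samples as rows.

    Parameters
    ----------
    values : ndarray of shape (n_samples, m_genes)
        Finite expression values in whatever units the study supplies.
    sample_ids, gene_names : sequences of unique labels
        Row and column identifiers, order-significant.
    timepoint_label : str
        Free-text tag (e.g. ``"t1"``).
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_names: list[str]
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_names = [str(g) for g in self.gene_names]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-d matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.gene_names):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} sample ids x {len(self.gene_names)} gene names"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_names[bad[1]]!r} (missing data are unsupported)"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.gene_names, "gene names")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_names)


@dataclass(frozen=True)
class SampleMetadata:
    """One individual: identifier, group label (``A`` or ``B``), age in years."""

    sample_id: str
    group: str
    age: float

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValidationError(
                f"sample {self.sample_id!r}: group must be 'A' or 'B', got {self.group!r}"
            )
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age must be finite and > 0, got {self.age!r}"
            )


@dataclass
class ContrastMatrix:
    """Per-group timepoint-2 minus timepoint-1 contrasts with aligned ages."""

    values: np.ndarray
    group: str
    sample_ids: list[str]
    gene_names: list[str]
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        if self.group not in ("A", "B"):
            raise ValidationError(f"group must be 'A' or 'B', got {self.group!r}")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.gene_names):
            raise ValidationError("contrast shape does not match identifiers")
        if self.ages.shape != (n,):
            raise ValidationError("ages must align index-wise with sample_ids")
        if not np.isfinite(self.values).all() or not np.isfinite(self.ages).all():
            raise ValidationError("contrasts and ages must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class StudyDesign:
    """The two per-group contrast matrices over a shared gene panel."""

    contrast_A: ContrastMatrix
    contrast_B: ContrastMatrix

    def __post_init__(self) -> None:
        if self.contrast_A.group != "A" or self.contrast_B.group != "B":
            raise ValidationError("contrast_A must be group A and contrast_B group B")
        if self.contrast_A.gene_names != self.contrast_B.gene_names:
            raise ValidationError("the two groups must share an identical gene panel")

    @property
    def m(self) -> int:
        return self.contrast_A.n_genes

    @property
    def gene_names(self) -> list[str]:
        return self.contrast_A.gene_names

    @property
    def n(self) -> int:
        return self.contrast_A.n_samples + self.contrast_B.n_samples


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression_matrix(
    path: str | os.PathLike,
    orientation: Orientation = "samples-as-rows",
    timepoint_label: str = "",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV by default, CSV by extension).

    The file must have one header row and one leading identifier column.
    With ``orientation="genes-as-rows"`` the parsed table is transposed so the
    returned matrix is always samples-as-rows.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise ValidationError(
            f"{path}: missing value at row {df.index[row]!r}, column "
            f"{df.columns[col]!r} (missing data are unsupported)"
        )
    try:
        values = df.to_numpy(dtype=str).astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna().to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise
    if not np.isfinite(values).all():
        raise ValidationError(f"{path}: non-finite values (NaN/inf) are unsupported")
    if orientation == "genes-as-rows":
        values = values.T
        sample_ids, gene_names = list(df.columns), list(df.index)
    elif orientation == "samples-as-rows":
        sample_ids, gene_names = list(df.index), list(df.columns)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(values, sample_ids, gene_names, timepoint_label)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write samples-as-rows, in the dialect implied by the file extension.

    Values are serialized with 17 significant digits so a read round-trips
    bit-identically.
    """
    matrix.to_frame().to_csv(
        path, sep=_sep_for(path), index_label="id", float_format="%.17g"
    )


def read_metadata(path: str | os.PathLike) -> list[SampleMetadata]:
    """Read sample metadata (columns ``sample_id``, ``group``, ``age``)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "group", "age"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    meta = [
        SampleMetadata(str(r.sample_id), str(r.group), float(r.age))
        for r in df.itertuples(index=False)
    ]
    _check_unique([s.sample_id for s in meta], "sample ids")
    return meta


def write_metadata(meta: Iterable[SampleMetadata], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(s.sample_id, s.group, s.age) for s in meta],
        columns=["sample_id", "group", "age"],
    ).to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def write_contrast_matrix(contrast: ContrastMatrix, path: str | os.PathLike) -> None:
    """Dump a per-group contrast matrix for inspection, same dialect rules."""
    pd.DataFrame(
        contrast.values, index=contrast.sample_ids, columns=contrast.gene_names
    ).to_csv(path, sep=_sep_for(path), index_label="id", float_format="%.17g")


def build_contrasts(
    R: ExpressionMatrix,
    S: ExpressionMatrix,
    meta: Iterable[SampleMetadata],
) -> StudyDesign:
    """Compute per-group contrasts Y = R - S and partition samples by group.

    ``R`` (timepoint 2) and ``S`` (timepoint 1) must cover identical sample
    and gene sets; order may differ, alignment is by identifier.  Every sample
    must appear in ``meta`` with a group and age, and each group must retain
    at least 3 samples so the downstream per-gene regression has at least one
    residual degree of freedom.
    """
    meta = list(meta)
    by_id = {s.sample_id: s for s in meta}
    _check_unique([s.sample_id for s in meta], "metadata sample ids")

    if set(R.sample_ids) != set(S.sample_ids):
        raise ValidationError("timepoint matrices cover different sample sets")
    if set(R.gene_names) != set(S.gene_names):
        raise ValidationError("timepoint matrices cover different gene sets")
    missing = [sid for sid in R.sample_ids if sid not in by_id]
    if missing:
        raise ValidationError(f"samples absent from metadata: {missing}")

    s_aligned = S.to_frame().loc[R.sample_ids, R.gene_names].to_numpy()
    contrasts = R.values - s_aligned

    design_parts: dict[str, ContrastMatrix] = {}
    for group in ("A", "B"):
        idx = [k for k, sid in enumerate(R.sample_ids) if by_id[sid].group == group]
        if len(idx) < MIN_GROUP_SIZE:
            raise ValidationError(
                f"group {group} has {len(idx)} samples; at least {MIN_GROUP_SIZE} "
                "are required (OLS with intercept needs df = n - 2 >= 1)"
            )
        ids = [R.sample_ids[k] for k in idx]
        design_parts[group] = ContrastMatrix(
            values=contrasts[idx, :],
            group=group,
            sample_ids=ids,
            gene_names=list(R.gene_names),
            ages=np.array([by_id[sid].age for sid in ids]),
        )
    return StudyDesign(contrast_A=design_parts["A"], contrast_B=design_parts["B"])
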