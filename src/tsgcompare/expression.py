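"""Expression matrices: reading, validation, and RPKM conversion.

The central container is :class:`ExpressionMatrix`, a thin validated wrapper
around a pandas DataFrame (genes as rows, samples as columns) carrying a
``units`` tag that distinguishes raw read counts from RPKM
(reads per kilobase of transcript per million mapped reads).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "rpkm")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of nonnegative expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns labelled by sample id. All cells
        must be finite and >= 0.
    units : str
        Either ``"counts"`` (raw read counts) or ``"rpkm"``.
    """

    values: pd.DataFrame
    units: str = "rpkm"

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValidationError(
                f"units must be one of {VALID_UNITS}, got {self.units!r}"
            )
        df = self.values
        dup_genes = df.index[df.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValidationError(f"duplicate gene ids: {dup_genes}")
        dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValidationError(f"duplicate sample ids: {dup_samples}")
        arr = df.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(arr)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        neg = arr < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative value {arr[g, s]} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GeneMeta:
    """Annotated transcript length in base pairs for one gene."""

    gene_id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValidationError(
                f"length_bp must be >= 1 for gene {self.gene_id!r}, "
                f"got {self.length_bp}"
            )


@dataclass(frozen=True)
class LibrarySizes:
    """Total mapped reads per sample (the 'per million' denominator)."""

    sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, n in self.sizes.items():
            if n < 1:
                raise ValidationError(
                    f"total_mapped_reads must be >= 1 for sample {sample!r}, got {n}"
                )

    def __getitem__(self, sample: str) -> int:
        return self.sizes[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self.sizes


Source = Union[str, Path, io.TextIOBase]


def read_expression_table(
    source: Source, units: str = "rpkm", sep: str = "\t"
) -> ExpressionMatrix:
    """Read a delimited gene x sample table into an :class:`ExpressionMatrix`.

    The first row is a header of sample labels; the first column holds gene
    identifiers. Row and column order are preserved. Periods are decimal
    marks; scientific notation is accepted. Duplicate identifiers, negative
    or non-numeric cells raise :class:`ValidationError` naming the offender.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    header = text.splitlines()[0].split(sep)[1:] if text else []
    dup_cols = {c for c in header if header.count(c) > 1}
    if dup_cols:  # pandas would silently mangle repeated column labels
        raise ValidationError(f"duplicate sample ids: {sorted(dup_cols)}")
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            parsed[col] = df[col].astype(float)
        except ValueError:
            for gene, cell in df[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, "
                        f"sample {col!r}"
                    ) from None
            raise
    return ExpressionMatrix(parsed, units=units)


def write_expression_table(
    matrix: ExpressionMatrix, target: Source, sep: str = "\t"
) -> None:
    """Write the matrix as delimited text, round-trippable by the reader."""
    matrix.values.to_csv(target, sep=sep, index_label="gene_id", float_format="%.10g")


def read_two_column_table(source: Source, sep: str = "\t") -> dict[str, float]:
    """Read an (id, value) two-column table into a dict, order preserved."""
    df = pd.read_csv(source, sep=sep, header=None, names=["id", "value"], dtype=str)
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        key = str(row["id"])
        if key in out:
            raise ValidationError(f"duplicate id {key!r} in two-column table")
        out[key] = float(row["value"])
    return out


def read_gene_lengths(source: Source, sep: str = "\t") -> dict[str, GeneMeta]:
    return {
        g: GeneMeta(g, int(v)) for g, v in read_two_column_table(source, sep).items()
    }


def read_library_sizes(source: Source, sep: str = "\t") -> LibrarySizes:
    return LibrarySizes({s: int(v) for s, v in read_two_column_table(source, sep).items()})


def counts_to_rpkm(
    counts: ExpressionMatrix,
    meta: Mapping[str, GeneMeta],
    libs: LibrarySizes,
) -> ExpressionMatrix:
    """Convert raw counts to RPKM.

    RPKM(g, s) = count(g, s) * 1e9 / (length_bp(g) * total_mapped_reads(s)).

    The library size is taken from ``libs`` rather than recomputed as a
    column sum, because the mapped-library total may include genes absent
    from the matrix.
    """
    if counts.units != "counts":
        raise ValidationError(f"expected a counts matrix, got units {counts.units!r}")
    missing_genes = [g for g in counts.gene_ids if g not in meta]
    if missing_genes:
        raise ValidationError(f"missing gene length for: {missing_genes[:5]}")
    missing_samples = [s for s in counts.sample_ids if s not in libs]
    if missing_samples:
        raise ValidationError(f"missing library size for: {missing_samples[:5]}")
    lengths = np.array([meta[g].length_bp for g in counts.gene_ids], dtype=float)
    totals = np.array([libs[s] for s in counts.sample_ids], dtype=float)
    rpkm = counts.values.to_numpy(dtype=float) * 1e9 / np.outer(lengths, totals)
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=counts.values.index, columns=counts.values.columns),
        units="rpkm",
    )
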