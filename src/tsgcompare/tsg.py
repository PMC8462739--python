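"""Tissue-specific gene (TSG) calling.

A gene is tissue-specific for a tissue group when its expression exceeds a
high threshold (default RPKM > 1) in at least one member sample of that
group and stays below a low threshold (default RPKM < 0.5) in every sample
outside the group. Composite groups (e.g. oral + atrial siphon, or the
three intestine parts) use "any member high" semantics: fellow members of
the qualifying group are exempt from the low test.

Both inequalities are strict, so every call carries a guaranteed
in-group/out-of-group fold difference greater than high/low (2-fold at the
defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class TissueGroupScheme:
    """Ordered mapping of group labels to member sample ids.

    Members must be nonempty and disjoint; to cover a matrix, their union
    must equal the matrix's sample set.
    """

    groups: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate group labels in scheme: {labels}")
        seen: set[str] = set()
        for label, members in self.groups:
            if not members:
                raise ValidationError(f"group {label!r} has no members")
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(
                    f"samples {sorted(overlap)} appear in more than one group"
                )
            seen |= set(members)

    @classmethod
    def from_dict(cls, mapping: dict[str, list[str]]) -> "TissueGroupScheme":
        return cls(tuple((k, tuple(v)) for k, v in mapping.items()))

    def to_dict(self) -> dict[str, list[str]]:
        return {k: list(v) for k, v in self.groups}

    @property
    def labels(self) -> list[str]:
        return [g for g, _ in self.groups]

    def members(self, label: str) -> tuple[str, ...]:
        for g, m in self.groups:
            if g == label:
                return m
        raise KeyError(label)

    @property
    def all_samples(self) -> set[str]:
        return {s for _, m in self.groups for s in m}

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        matrix_samples = set(matrix.sample_ids)
        uncovered = matrix_samples - self.all_samples
        extra = self.all_samples - matrix_samples
        if uncovered or extra:
            raise ValidationError(
                f"scheme/sample mismatch: uncovered samples {sorted(uncovered)}, "
                f"scheme-only samples {sorted(extra)}"
            )


@dataclass(frozen=True)
class TsgCriteria:
    """Calling thresholds in RPKM; both comparisons are strict."""

    high_threshold: float = 1.0
    low_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold):
            raise ValidationError(
                "need 0 < low_threshold < high_threshold, got "
                f"low={self.low_threshold}, high={self.high_threshold}"
            )


@dataclass(frozen=True)
class TsgCall:
    """One gene's tissue-specificity verdict with its evidence values."""

    gene_id: str
    group_label: str
    max_in_group: float
    max_outside_group: float

    @property
    def fold_ratio(self) -> float:
        """In-group / out-of-group max; +inf when the outside max is zero."""
        if self.max_outside_group == 0:
            return math.inf
        return self.max_in_group / self.max_outside_group


def call_tsgs(
    matrix: ExpressionMatrix,
    scheme: TissueGroupScheme,
    criteria: TsgCriteria = TsgCriteria(),
) -> list[TsgCall]:
    """Call tissue-specific genes under the strict exclusive-expression rule.

    Gene g is called for group G iff max over members(G) > high_threshold
    and every sample outside G is < low_threshold. With low <= high a gene
    can qualify for at most one group. Output is sorted by
    (group_label, gene_id); group labels order as in the scheme.
    """
    if matrix.units != "rpkm":
        raise ValidationError(f"TSG calling requires RPKM units, got {matrix.units!r}")
    scheme.validate_against(matrix)
    values = matrix.values
    arr = values.to_numpy(dtype=float)
    col_idx = {s: i for i, s in enumerate(values.columns)}

    # per-group max across member columns, per-gene
    group_max = {}
    for label, members in scheme.groups:
        cols = [col_idx[s] for s in members]
        group_max[label] = arr[:, cols].max(axis=1)

    calls: list[TsgCall] = []
    label_rank = {g: i for i, g in enumerate(scheme.labels)}
    for label, members in scheme.groups:
        outside_cols = [col_idx[s] for s in values.columns if s not in members]
        if outside_cols:
            out_max = arr[:, outside_cols].max(axis=1)
        else:
            out_max = np.zeros(arr.shape[0])
        hit = (group_max[label] > criteria.high_threshold) & (
            out_max < criteria.low_threshold
        )
        for i in np.flatnonzero(hit):
            calls.append(
                TsgCall(
                    gene_id=str(values.index[i]),
                    group_label=label,
                    max_in_group=float(group_max[label][i]),
                    max_outside_group=float(out_max[i]),
                )
            )
    calls.sort(key=lambda c: (label_rank[c.group_label], c.gene_id))
    return calls


def call_two_tissue_genes(
    matrix: ExpressionMatrix,
    scheme: TissueGroupScheme,
    focal_group: str,
    criteria: TsgCriteria = TsgCriteria(),
) -> list[tuple[str, tuple[str, str]]]:
    """Relaxed criterion: genes specific to exactly two groups, one focal.

    Returns (gene_id, (group_a, group_b)) pairs, groups in scheme order,
    for genes whose group max exceeds high_threshold in exactly two groups
    including ``focal_group``, with every sample of every other group below
    low_threshold. Strict single-group TSGs are NOT returned; callers union
    them with this output to form the combined relaxed set.
    """
    if matrix.units != "rpkm":
        raise ValidationError(f"TSG calling requires RPKM units, got {matrix.units!r}")
    scheme.validate_against(matrix)
    if focal_group not in scheme.labels:
        raise ValidationError(f"focal group {focal_group!r} not in scheme")
    values = matrix.values
    arr = values.to_numpy(dtype=float)
    col_idx = {s: i for i, s in enumerate(values.columns)}
    gmax = np.column_stack(
        [
            arr[:, [col_idx[s] for s in members]].max(axis=1)
            for _, members in scheme.groups
        ]
    )  # genes x groups
    labels = scheme.labels
    focal_j = labels.index(focal_group)
    high = gmax > criteria.high_threshold
    out: list[tuple[str, tuple[str, str]]] = []
    for i in range(arr.shape[0]):
        high_j = np.flatnonzero(high[i])
        if len(high_j) != 2 or focal_j not in high_j:
            continue
        rest = [j for j in range(len(labels)) if j not in high_j]
        if all(gmax[i, j] < criteria.low_threshold for j in rest):
            pair = (labels[high_j[0]], labels[high_j[1]])
            out.append((str(values.index[i]), pair))
    out.sort(key=lambda t: t[0])
    return out


def tsg_calls_to_frame(calls: list[TsgCall]):
    """TSG calls as a tidy table (gene_id, group_label, maxima)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "group_label": c.group_label,
                "max_in_group": c.max_in_group,
                "max_outside_group": c.max_outside_group,
            }
            for c in calls
        ],
        columns=["gene_id", "group_label", "max_in_group", "max_outside_group"],
    )
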