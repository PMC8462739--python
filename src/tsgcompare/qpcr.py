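"""qRT-PCR delta-Ct workflow: normalization, detection filtering, testing.

Expression is normalized to a constitutive reference gene on the Ct scale:
dCt = Ct(target) - Ct(reference), relative expression = 2^(-dCt).
Undetected measurements get relative expression 0; a tissue with two or
more undetected replicate sets for a gene is excluded from that gene's
statistical comparison.

Testing is gated on homoscedasticity: Levene's test (group means as
centers) at alpha = 0.05 routes to a parametric one-way ANOVA with Tukey's
HSD when variances look equal, and otherwise to a Kruskal-Wallis omnibus
test with Dunn's rank-based pairwise comparisons under Bonferroni
adjustment. Tests operate on dCt values, not on the 2^(-dCt) scale.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .expression import ValidationError

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class QpcrMeasurement:
    """One replicate set's paired Ct readings for a gene in a tissue."""

    gene_id: str
    tissue: str
    replicate_set: str
    ct_target: float | None
    ct_reference: float | None
    detected: bool

    def __post_init__(self) -> None:
        if self.detected:
            if self.ct_target is None or self.ct_reference is None:
                raise ValidationError(
                    f"{self.gene_id}/{self.tissue}/{self.replicate_set}: "
                    "detected measurement missing a Ct value"
                )
            if self.ct_target <= 0 or self.ct_reference <= 0:
                raise ValidationError(
                    f"{self.gene_id}/{self.tissue}/{self.replicate_set}: "
                    "Ct values must be positive when detected"
                )


def compute_dct(m: QpcrMeasurement) -> tuple[float | None, float]:
    """(dCt, relative expression) for one measurement.

    Detected: dCt = ct_target - ct_reference and relative expression
    2^(-dCt). Undetected: relative expression 0 and dCt None (handled by
    the detection filter downstream).
    """
    if not m.detected:
        return None, 0.0
    dct = m.ct_target - m.ct_reference
    return dct, 2.0 ** (-dct)


@dataclass
class DetectionFilterResult:
    """Per-tissue dCt replicate values after the undetected-set rule."""

    dct_groups: dict[str, list[float]]
    rel_expr_groups: dict[str, list[float]]
    excluded_tissues: dict[str, str]


def filter_detection(
    measurements: Sequence[QpcrMeasurement],
    undetected_dct: float | None = None,
) -> DetectionFilterResult:
    """Apply the >= 2-undetected-sets exclusion rule for one gene.

    A tissue with two or more undetected replicate sets is excluded from
    the statistical comparison. A tissue with exactly one undetected set is
    retained; that replicate contributes expression 0 on the relative
    scale, and by default is dropped from the dCt-scale group (pass
    ``undetected_dct`` to substitute a fixed dCt instead).
    """
    by_tissue: dict[str, list[QpcrMeasurement]] = {}
    for m in measurements:
        by_tissue.setdefault(m.tissue, []).append(m)
    dct_groups: dict[str, list[float]] = {}
    rel_groups: dict[str, list[float]] = {}
    excluded: dict[str, str] = {}
    for tissue, ms in by_tissue.items():
        n_undetected = sum(1 for m in ms if not m.detected)
        if n_undetected >= 2:
            excluded[tissue] = (
                f"{n_undetected} of {len(ms)} replicate sets below detection"
            )
            continue
        dcts: list[float] = []
        rels: list[float] = []
        for m in ms:
            dct, rel = compute_dct(m)
            rels.append(rel)
            if dct is None:
                if undetected_dct is not None:
                    dcts.append(undetected_dct)
            else:
                dcts.append(dct)
        dct_groups[tissue] = dcts
        rel_groups[tissue] = rels
    return DetectionFilterResult(dct_groups, rel_groups, excluded)


@dataclass
class TestReport:
    """Outcome of the gated per-gene tissue comparison."""

    gene_id: str
    levene_p: float | None
    branch: str  # "parametric" | "nonparametric" | "none"
    omnibus_p: float | None
    posthoc: pd.DataFrame
    alpha: float = ALPHA_DEFAULT
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.omnibus_p is not None and self.omnibus_p < self.alpha


_POSTHOC_COLUMNS = ["group1", "group2", "p_raw", "p_adj", "significant"]


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Bonferroni adjustment.

    Pooled mid-ranks with the standard tie correction
    sum(t^3 - t) / (12 (N - 1)); z_ij = (Rbar_i - Rbar_j) /
    sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)), two-sided normal p-values,
    Bonferroni p_adj = min(1, m * p) over the m pairs.
    """
    labels = list(groups)
    sizes = {k: len(groups[k]) for k in labels}
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in labels])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for k in labels:
        stop = start + sizes[k]
        mean_rank[k] = float(ranks[start:stop].mean())
        start = stop
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    rows = []
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    for a, b in pairs:
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, m * p)
        rows.append(
            {
                "group1": a,
                "group2": b,
                "p_raw": p,
                "p_adj": p_adj,
                "significant": p_adj < ALPHA_DEFAULT,
            }
        )
    return pd.DataFrame(rows, columns=_POSTHOC_COLUMNS)


def tissue_comparison_test(
    dct_groups: Mapping[str, Sequence[float]],
    gene_id: str = "",
    alpha: float = ALPHA_DEFAULT,
    posthoc: bool = True,
) -> TestReport:
    """Levene-gated omnibus comparison of per-tissue dCt replicate groups.

    Groups with fewer than 2 replicates are dropped (logged); fewer than 2
    groups remaining yields a no-test report. With Levene p >= alpha the
    parametric branch runs (one-way ANOVA, Tukey HSD); otherwise the
    nonparametric branch (Kruskal-Wallis, Dunn + Bonferroni). Branch
    selection is a pure function of the data. ``posthoc=False`` skips the
    pairwise table (the studentized-range p-values dominate run time),
    for simulation studies that only need the omnibus result.
    """
    excluded: dict[str, str] = {}
    usable: dict[str, list[float]] = {}
    for tissue, vals in dct_groups.items():
        vals = [float(v) for v in vals]
        if len(vals) < 2:
            excluded[tissue] = f"only {len(vals)} replicate(s) after filtering"
        else:
            usable[tissue] = vals
    if len(usable) < 2:
        return TestReport(
            gene_id=gene_id,
            levene_p=None,
            branch="none",
            omnibus_p=None,
            posthoc=pd.DataFrame(columns=_POSTHOC_COLUMNS),
            alpha=alpha,
            excluded=excluded,
        )
    arrays = [np.asarray(v, dtype=float) for v in usable.values()]
    with np.errstate(invalid="ignore"):
        levene_p = float(stats.levene(*arrays, center="mean").pvalue)
    if math.isnan(levene_p):
        # degenerate case (identical absolute deviations in every group):
        # no evidence against homoscedasticity, stay parametric
        levene_p = 1.0
    empty = pd.DataFrame(columns=_POSTHOC_COLUMNS)
    if levene_p >= alpha:
        branch = "parametric"
        omnibus_p = float(stats.f_oneway(*arrays).pvalue)
        pairwise = _tukey_posthoc(usable, alpha) if posthoc else empty
    else:
        branch = "nonparametric"
        omnibus_p = float(stats.kruskal(*arrays).pvalue)
        pairwise = dunn_posthoc(usable) if posthoc else empty
    return TestReport(
        gene_id=gene_id,
        levene_p=levene_p,
        branch=branch,
        omnibus_p=omnibus_p,
        posthoc=pairwise,
        alpha=alpha,
        excluded=excluded,
    )


def _tukey_posthoc(groups: Mapping[str, Sequence[float]], alpha: float) -> pd.DataFrame:
    data = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(data, labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    out = pd.DataFrame(
        {
            "group1": frame["group1"].astype(str),
            "group2": frame["group2"].astype(str),
            "p_raw": res.pvalues,  # Tukey p-values are family-wise already
            "p_adj": res.pvalues,
            "significant": res.reject,
        }
    )
    return out[_POSTHOC_COLUMNS]


def analyze_gene(
    measurements: Sequence[QpcrMeasurement],
    gene_id: str | None = None,
    alpha: float = ALPHA_DEFAULT,
    undetected_dct: float | None = None,
    posthoc: bool = True,
) -> TestReport:
    """Full per-gene workflow: detection filter then gated comparison."""
    if gene_id is None:
        gene_id = measurements[0].gene_id if measurements else ""
    filt = filter_detection(measurements, undetected_dct=undetected_dct)
    report = tissue_comparison_test(
        filt.dct_groups, gene_id=gene_id, alpha=alpha, posthoc=posthoc
    )
    report.excluded = {**filt.excluded_tissues, **report.excluded}
    return report


def read_qpcr_table(source, sep: str = "\t") -> list[QpcrMeasurement]:
    """Read a replicate table (gene, tissue, replicate_set, ct_target,
    ct_reference, detected) into measurements."""
    df = pd.read_csv(source, sep=sep)
    required = {"gene_id", "tissue", "replicate_set", "ct_target", "ct_reference", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
    out: list[QpcrMeasurement] = []
    for _, row in df.iterrows():
        detected = bool(row["detected"]) if not isinstance(row["detected"], str) else (
            row["detected"].strip().lower() in {"1", "true", "yes"}
        )
        out.append(
            QpcrMeasurement(
                gene_id=str(row["gene_id"]),
                tissue=str(row["tissue"]),
                replicate_set=str(row["replicate_set"]),
                ct_target=float(row["ct_target"]) if detected else None,
                ct_reference=float(row["ct_reference"]) if detected else None,
                detected=detected,
            )
        )
    return out


def _stars(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def reports_to_frame(reports: Sequence[TestReport]) -> pd.DataFrame:
    """Per-gene summary table (P_L, branch, omnibus P, stars, exclusions)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "gene_id": r.gene_id,
                "levene_p": r.levene_p,
                "branch": r.branch,
                "omnibus_p": r.omnibus_p,
                "stars": _stars(r.omnibus_p),
                "n_significant_pairs": int(r.posthoc["significant"].sum())
                if len(r.posthoc)
                else 0,
                "excluded_tissues": ";".join(
                    f"{t}({why})" for t, why in sorted(r.excluded.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "levene_p",
            "branch",
            "omnibus_p",
            "stars",
            "n_significant_pairs",
            "excluded_tissues",
        ],
    )
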