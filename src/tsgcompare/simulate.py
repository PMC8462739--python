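"""Synthetic data with planted ground truth for every pipeline stage.

Generates a focal-species RPKM matrix with planted tissue-specific genes
(TSGs) that satisfy the calling thresholds with margin, a target-species
matrix whose linked homologs are high in a planted tissue with probability
q, a matching BLAST-tabular hit file (true links below the e-value
threshold plus decoys above it), and qRT-PCR Ct replicate tables with a
constitutive reference gene.

A single integer seed drives a named stream per component, so each stage
can be regenerated independently and every output is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ValidationError
from .qpcr import QpcrMeasurement
from .tsg import TissueGroupScheme, TsgCriteria

# Stream tags keep the per-component generators independent.
_STREAMS = {"focal": 11, "target": 23, "qpcr": 37}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def default_scheme() -> TissueGroupScheme:
    """Adult ascidian tissue grouping: 11 samples in 9 groups.

    The intestine's three parts form one composite group ("any part high"
    qualifies); the two siphons are kept as separate groups here and may be
    merged by callers that want combined siphon calls.
    """
    return TissueGroupScheme.from_dict(
        {
            "oral_siphon": ["oral_siphon"],
            "atrial_siphon": ["atrial_siphon"],
            "neural_complex": ["neural_complex"],
            "endostyle": ["endostyle"],
            "heart": ["heart"],
            "ovary": ["ovary"],
            "pharynx": ["pharynx"],
            "stomach": ["stomach"],
            "intestine": ["intestine_proximal", "intestine_middle", "intestine_distal"],
        }
    )


@dataclass
class PlantedTruth:
    """Ground truth behind a synthetic dataset."""

    seed: int
    tsg_labels: dict[str, str] = field(default_factory=dict)  # gene -> group
    links: dict[str, dict[str, str]] = field(default_factory=dict)  # species -> gene -> subject
    high_tissue: dict[str, dict[str, str]] = field(default_factory=dict)  # species -> subject -> tissue
    bias_map: dict[str, dict[str, tuple[str, float]]] = field(default_factory=dict)  # species -> group -> (tissue, q)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "tsg_labels": self.tsg_labels,
                "links": self.links,
                "high_tissue": self.high_tissue,
                "bias_map": {
                    sp: {g: list(tq) for g, tq in m.items()}
                    for sp, m in self.bias_map.items()
                },
            },
            indent=1,
            sort_keys=True,
        )


def _is_tsg_somewhere(
    row: np.ndarray,
    group_cols: Sequence[tuple[str, np.ndarray]],
    criteria: TsgCriteria,
) -> bool:
    for _, cols in group_cols:
        mask = np.zeros(len(row), dtype=bool)
        mask[cols] = True
        if row[mask].max() > criteria.high_threshold and (
            (~mask).sum() == 0 or row[~mask].max() < criteria.low_threshold
        ):
            return True
    return False


def generate_focal_expression(
    n_genes: int,
    scheme: TissueGroupScheme | None = None,
    n_tsg_per_group: int | Mapping[str, int] = 5,
    seed: int = 0,
    criteria: TsgCriteria = TsgCriteria(),
    broad_fraction: float = 0.1,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Focal-species RPKM matrix with planted TSGs.

    Planted TSGs draw in-group RPKM ~ Uniform(2, 50) (comfortably above the
    high threshold) and out-of-group ~ Uniform(0, 0.4) (below the low
    threshold with margin). Background genes are log-normal across samples,
    with ``broad_fraction`` of them forced broadly expressed (> 1
    everywhere); any background draw that would accidentally satisfy the
    calling rule is redrawn, so the planted labels are exactly the callable
    set.
    """
    if scheme is None:
        scheme = default_scheme()
    labels = scheme.labels
    if isinstance(n_tsg_per_group, int):
        per_group = {g: n_tsg_per_group for g in labels}
    else:
        per_group = dict(n_tsg_per_group)
        unknown = set(per_group) - set(labels)
        if unknown:
            raise ValidationError(f"unknown groups in n_tsg_per_group: {sorted(unknown)}")
    n_tsg = sum(per_group.values())
    if n_tsg > n_genes:
        raise ValidationError(
            f"requested {n_tsg} TSGs but only {n_genes} genes"
        )
    samples = [s for _, members in scheme.groups for s in members]
    n_samples = len(samples)
    col_idx = {s: i for i, s in enumerate(samples)}
    group_cols = [
        (g, np.array([col_idx[s] for s in members]))
        for g, members in scheme.groups
    ]
    rng = _rng(seed, "focal")
    values = np.empty((n_genes, n_samples))
    truth = PlantedTruth(seed=seed)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]

    gi = 0
    for g, cols in group_cols:
        for _ in range(per_group.get(g, 0)):
            row = rng.uniform(0.0, 0.4, n_samples)
            row[cols] = rng.uniform(2.0, 50.0, len(cols))
            values[gi] = row
            truth.tsg_labels[gene_ids[gi]] = g
            gi += 1
    n_background = n_genes - gi
    n_broad = int(round(broad_fraction * n_background))
    for k in range(n_background):
        if k < n_broad:
            values[gi] = rng.uniform(2.0, 50.0, n_samples)
        else:
            while True:
                base = rng.lognormal(mean=0.5, sigma=1.5)
                row = base * rng.lognormal(mean=0.0, sigma=0.3, size=n_samples)
                if not _is_tsg_somewhere(row, group_cols, criteria):
                    break
            values[gi] = row
        gi += 1
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=samples), units="rpkm"
    )
    return matrix, truth


@dataclass
class TargetSpeciesData:
    """One synthetic target species: expression, hits, expected similarity."""

    species_tag: str
    expression: ExpressionMatrix
    blast_text: str
    expected_similarity: pd.DataFrame  # focal group x target tissue, planted q
    n_links: dict[str, int]  # per focal group


def generate_target_species(
    truth: PlantedTruth,
    tissues: Sequence[str],
    q_bias: Mapping[str, tuple[str, float]],
    homolog_fraction: float = 0.7,
    seed: int | None = None,
    species_tag: str = "target",
    n_decoys_per_link: int = 2,
) -> TargetSpeciesData:
    """Target-species matrix, BLAST tabular text, and expected similarity.

    Each planted TSG gains a subject with probability ``homolog_fraction``.
    A linked subject is high (normalized value 1.0 after min-max scaling)
    in the tissue its focal group maps to with probability q, and otherwise
    in a uniformly chosen other tissue. True links get e-values
    10^-Uniform(6, 50); decoy hits get e-values at or above the 1e-5
    threshold and never survive best-hit filtering.
    """
    if not tissues:
        raise ValidationError("target tissue list is empty")
    if not (0 <= homolog_fraction <= 1):
        raise ValidationError(f"homolog_fraction {homolog_fraction} outside [0, 1]")
    for group, (tissue, q) in q_bias.items():
        if tissue not in tissues:
            raise ValidationError(f"bias tissue {tissue!r} not in tissue list")
        if not (0 <= q <= 1):
            raise ValidationError(f"bias probability {q} outside [0, 1]")
    if seed is None:
        seed = truth.seed
    rng = _rng(seed, "target")
    tissues = list(tissues)
    rows: dict[str, np.ndarray] = {}
    lines: list[str] = []
    links: dict[str, str] = {}
    high_tissue: dict[str, str] = {}
    n_links: dict[str, int] = {}
    subj_i = 0
    for gene in sorted(truth.tsg_labels):
        group = truth.tsg_labels[gene]
        if rng.random() >= homolog_fraction:
            continue
        subject = f"{species_tag.upper()}_{subj_i:05d}"
        subj_i += 1
        links[gene] = subject
        n_links[group] = n_links.get(group, 0) + 1
        if group in q_bias:
            mapped, q = q_bias[group]
            if rng.random() < q:
                high = mapped
            else:
                others = [t for t in tissues if t != mapped]
                high = others[rng.integers(len(others))] if others else mapped
        else:
            high = tissues[rng.integers(len(tissues))]
        high_tissue[subject] = high
        profile = rng.uniform(0.0, 1.0, len(tissues))
        profile[tissues.index(high)] = rng.uniform(50.0, 100.0)
        rows[subject] = profile
        evalue = 10.0 ** (-rng.uniform(6.0, 50.0))
        bitscore = rng.uniform(100.0, 500.0)
        lines.append(_blast_line(gene, subject, rng, evalue, bitscore))
        for d in range(n_decoys_per_link):
            decoy_ev = 10.0 ** (-rng.uniform(0.0, 4.5))
            lines.append(
                _blast_line(
                    gene,
                    f"DECOY_{species_tag.upper()}_{subj_i}_{d}",
                    rng,
                    decoy_ev,
                    rng.uniform(600.0, 900.0),  # high score: only the e-value saves us
                )
            )
    expr = ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=tissues), units="rpkm"
    )
    groups = sorted({g for g in truth.tsg_labels.values()})
    expected = pd.DataFrame(0.0, index=groups, columns=tissues)
    for group, (tissue, q) in q_bias.items():
        if group in expected.index:
            expected.at[group, tissue] = q
    truth.links[species_tag] = links
    truth.high_tissue[species_tag] = high_tissue
    truth.bias_map[species_tag] = {g: (t, q) for g, (t, q) in q_bias.items()}
    return TargetSpeciesData(
        species_tag=species_tag,
        expression=expr,
        blast_text="\n".join(lines) + ("\n" if lines else ""),
        expected_similarity=expected,
        n_links=n_links,
    )


def _blast_line(
    query: str, subject: str, rng: np.random.Generator, evalue: float, bitscore: float
) -> str:
    aln_len = int(rng.integers(80, 400))
    pident = float(rng.uniform(25.0, 95.0))
    mismatch = int(aln_len * (1 - pident / 100))
    fields = [
        query,
        subject,
        f"{pident:.1f}",
        str(aln_len),
        str(mismatch),
        str(int(rng.integers(0, 5))),
        "1",
        str(aln_len),
        "1",
        str(aln_len),
        f"{evalue:.3g}",
        f"{bitscore:.1f}",
    ]
    return "\t".join(fields)


def generate_qpcr_dataset(
    gene_tissues: Mapping[str, str],
    tissues: Sequence[str],
    effect_dct: float = 10.0,
    n_replicates: int = 4,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline_dct: float = 8.0,
    reference_ct_mean: float = 20.0,
    undetected: Mapping[tuple[str, str], int] | None = None,
) -> list[QpcrMeasurement]:
    """qRT-PCR Ct replicates with a constitutive reference gene.

    For each (gene, tissue, replicate): reference Ct ~ Normal(20, noise_sd)
    and target Ct = reference + baseline_dct - effect_dct in the gene's
    planted tissue (plus Normal(0, noise_sd) noise), so the planted tissue
    sits effect_dct cycles below baseline. ``undetected`` marks the first k
    replicate sets of a (gene, tissue) as below detection.
    """
    if n_replicates < 3:
        raise ValidationError(f"n_replicates must be >= 3, got {n_replicates}")
    rng = _rng(seed, "qpcr")
    undetected = dict(undetected or {})
    out: list[QpcrMeasurement] = []
    for gene in gene_tissues:
        planted = gene_tissues[gene]
        for tissue in tissues:
            n_undet = undetected.get((gene, tissue), 0)
            for rep in range(n_replicates):
                ref_ct = rng.normal(reference_ct_mean, noise_sd)
                effect = effect_dct if tissue == planted else 0.0
                tgt_ct = ref_ct + baseline_dct - effect + rng.normal(0.0, noise_sd)
                if rep < n_undet:
                    out.append(
                        QpcrMeasurement(gene, tissue, f"set{rep + 1}", None, None, False)
                    )
                else:
                    out.append(
                        QpcrMeasurement(
                            gene, tissue, f"set{rep + 1}", float(tgt_ct), float(ref_ct), True
                        )
                    )
    return out


def qpcr_to_frame(measurements: Sequence[QpcrMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "tissue": m.tissue,
                "replicate_set": m.replicate_set,
                "ct_target": "" if m.ct_target is None else m.ct_target,
                "ct_reference": "" if m.ct_reference is None else m.ct_reference,
                "detected": m.detected,
            }
            for m in measurements
        ],
        columns=["gene_id", "tissue", "replicate_set", "ct_target", "ct_reference", "detected"],
    )
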