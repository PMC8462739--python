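"""Cross-species tissue similarity from min-max-normalized homolog profiles.

Each focal tissue group's TSGs are mapped (via their best hits) to
target-species expression profiles. Every profile is rescaled per gene so
its lowest-expressing tissue is 0 and its highest is 1; the tissue
similarity of a target tissue is then the fraction of (non-degenerate)
homolog profiles whose normalized value there exceeds a threshold
(default 0.8, strict >). Constant profiles cannot be rescaled and are
excluded from numerator and denominator, with the count reported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .expression import ExpressionMatrix, ValidationError
from .homology import HomologyMap
from .tsg import TsgCall


@dataclass(frozen=True)
class NormalizedProfile:
    """Per-tissue expression rescaled to [0, 1]; constant profiles flagged."""

    gene_id: str
    tissues: tuple[str, ...]
    values: tuple[float, ...]
    degenerate: bool = False

    def value(self, tissue: str) -> float:
        return self.values[self.tissues.index(tissue)]


@dataclass(frozen=True)
class SimilarityConfig:
    """Counting threshold on the normalized scale; strict >."""

    high_fraction_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.high_fraction_threshold < 1):
            raise ValidationError(
                f"threshold must be in (0, 1), got {self.high_fraction_threshold}"
            )


@dataclass
class SimilarityMatrix:
    """Focal group x target tissue fractions with per-row denominators.

    ``fractions`` rows are focal groups, columns target tissues; a row of
    NaN marks a group whose TSGs yielded no usable homolog profile.
    ``denominators`` counts the non-degenerate TSG-homolog pairs per row;
    ``dropped`` logs unresolvable and degenerate counts.
    """

    fractions: pd.DataFrame
    denominators: dict[str, int]
    dropped: dict[str, dict[str, int]] = field(default_factory=dict)


def minmax_normalize(
    profile: Mapping[str, float] | pd.Series, gene_id: str = ""
) -> NormalizedProfile:
    """Rescale a per-tissue profile so min -> 0 and max -> 1.

    v' = (v - min) / (max - min). A constant profile is flagged degenerate
    with all values set to 0. Fewer than 2 tissues is an error.
    """
    if isinstance(profile, pd.Series):
        tissues = tuple(str(t) for t in profile.index)
        vals = profile.to_numpy(dtype=float)
        gene_id = gene_id or str(profile.name or "")
    else:
        tissues = tuple(profile)
        vals = np.array([profile[t] for t in tissues], dtype=float)
    if len(tissues) < 2:
        raise ValidationError("min-max normalization needs >= 2 tissues")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return NormalizedProfile(gene_id, tissues, (0.0,) * len(tissues), True)
    scaled = (vals - lo) / (hi - lo)
    return NormalizedProfile(gene_id, tissues, tuple(float(v) for v in scaled), False)


def tissue_similarity(
    profiles: Sequence[NormalizedProfile],
    config: SimilarityConfig = SimilarityConfig(),
) -> dict[str, float]:
    """Fraction of non-degenerate profiles high (> threshold) per tissue.

    Degenerate profiles count in neither numerator nor denominator; zero
    usable profiles is an error (the ratio is undefined).
    """
    usable = [p for p in profiles if not p.degenerate]
    if not usable:
        raise ValidationError("tissue similarity undefined: no non-degenerate profiles")
    tissues = usable[0].tissues
    for p in usable[1:]:
        if p.tissues != tissues:
            raise ValidationError("profiles do not share a common tissue set")
    thr = config.high_fraction_threshold
    n = len(usable)
    counts = np.zeros(len(tissues), dtype=int)
    for p in usable:
        counts += np.asarray(p.values) > thr
    return {t: counts[i] / n for i, t in enumerate(tissues)}


def similarity_matrix(
    tsg_calls: Sequence[TsgCall],
    hmap: HomologyMap,
    target_expr: ExpressionMatrix,
    species_tag: str,
    config: SimilarityConfig = SimilarityConfig(),
    replicate_map: Mapping[str, Sequence[str]] | None = None,
) -> SimilarityMatrix:
    """Per focal group, the tissue-similarity row against one target species.

    For each TSG the best-hit subject's profile over the target's tissues
    is min-max normalized; duplicated subjects contribute once per TSG
    (the denominator counts TSG-homolog pairs). Subjects absent from
    ``target_expr`` are dropped and counted. ``replicate_map`` optionally
    collapses replicate columns to named tissues by averaging before
    normalization.
    """
    expr = target_expr.values
    if replicate_map:
        expr = pd.DataFrame(
            {t: expr[list(cols)].mean(axis=1) for t, cols in replicate_map.items()}
        )
    tissues = [str(c) for c in expr.columns]
    groups: dict[str, list[TsgCall]] = {}
    for c in tsg_calls:
        groups.setdefault(c.group_label, []).append(c)

    rows: dict[str, list[float]] = {}
    denominators: dict[str, int] = {}
    dropped: dict[str, dict[str, int]] = {}
    for label, calls in groups.items():
        profiles: list[NormalizedProfile] = []
        n_unresolvable = n_degenerate = 0
        for call in calls:
            best = hmap.get(call.gene_id, species_tag)
            if best is None:
                continue
            if best.subject_id not in expr.index:
                n_unresolvable += 1
                continue
            prof = minmax_normalize(expr.loc[best.subject_id], gene_id=call.gene_id)
            if prof.degenerate:
                n_degenerate += 1
                continue
            profiles.append(prof)
        dropped[label] = {
            "unresolvable": n_unresolvable,
            "degenerate": n_degenerate,
        }
        if not profiles:
            rows[label] = [np.nan] * len(tissues)
            denominators[label] = 0
            continue
        frac = tissue_similarity(profiles, config)
        rows[label] = [frac[t] for t in tissues]
        denominators[label] = len(profiles)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    return SimilarityMatrix(frame, denominators, dropped)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of profiles: merge tree plus leaf order."""

    gene_ids: tuple[str, ...]
    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    leaf_order: tuple[str, ...]


def cluster_profiles(
    profiles: Sequence[NormalizedProfile],
    linkage_method: str = "complete",
    distance_metric: str = "euclidean",
) -> ClusterResult:
    """Deterministic hierarchical clustering of normalized profiles.

    Defaults: Euclidean distance on the normalized values, complete
    linkage. Returns the merge list and a leaf order for heatmap rendering.
    """
    if len(profiles) < 2:
        raise ValidationError("clustering needs >= 2 profiles")
    tissues = profiles[0].tissues
    for p in profiles[1:]:
        if p.tissues != tissues:
            raise ValidationError("profiles do not share a common tissue set")
    data = np.array([p.values for p in profiles], dtype=float)
    z = linkage(pdist(data, metric=distance_metric), method=linkage_method)
    order = leaves_list(z)
    ids = tuple(p.gene_id for p in profiles)
    return ClusterResult(ids, z, tuple(ids[i] for i in order))


Target = Union[str, Path, io.TextIOBase]


def export_network(
    matrices: Mapping[str, SimilarityMatrix],
    min_edge: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Similarity matrices as an edge table plus a node-attribute table.

    One edge per (focal tissue, target tissue, species) with weight equal
    to the similarity fraction, emitted when weight > min_edge. Focal and
    target node sets are disjoint by construction (target nodes are
    species-prefixed), so there are no self-edges. NaN rows (undefined
    similarity) yield no edges.
    """
    edges: list[dict] = []
    nodes: dict[str, dict] = {}
    for species, sim in matrices.items():
        for focal in sim.fractions.index:
            nodes.setdefault(str(focal), {"node": str(focal), "species": "focal"})
            for tissue in sim.fractions.columns:
                w = sim.fractions.at[focal, tissue]
                target_node = f"{species}:{tissue}"
                nodes.setdefault(
                    target_node, {"node": target_node, "species": species}
                )
                if pd.notna(w) and w > min_edge:
                    edges.append(
                        {
                            "source": str(focal),
                            "weight": float(w),
                            "target": target_node,
                        }
                    )
    edge_df = pd.DataFrame(edges, columns=["source", "weight", "target"])
    node_df = pd.DataFrame(list(nodes.values()), columns=["node", "species"])
    return edge_df, node_df


def write_sif(edge_df: pd.DataFrame, target: Target) -> None:
    """Write edges as SIF-style three-column text (source, weight, target)."""
    edge_df.to_csv(target, sep="\t", index=False, float_format="%.10g")


def read_sif(source: Target) -> pd.DataFrame:
    return pd.read_csv(source, sep="\t")
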