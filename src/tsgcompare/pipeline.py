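"""End-to-end pipeline: configuration, orchestration, report bundle.

A run reads a YAML configuration naming the inputs and thresholds, then
executes the stages in order — TSG calling, homology mapping, breakdown,
similarity, clustering, network export, and (optionally) the qPCR
workflow — writing a bundle of delimited tables with stable names plus a
JSON run log of versions, thresholds, and audit counts. Reruns with
unchanged inputs reproduce the bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .expression import (
    ExpressionMatrix,
    ValidationError,
    counts_to_rpkm,
    read_expression_table,
    read_gene_lengths,
    read_library_sizes,
)
from .homology import (
    DEFAULT_EVALUE_MAX,
    HomologyMap,
    best_hits,
    breakdown_to_frame,
    homology_breakdown,
    parse_blast_tabular,
)
from .qpcr import analyze_gene, read_qpcr_table, reports_to_frame
from .similarity import (
    SimilarityConfig,
    cluster_profiles,
    export_network,
    minmax_normalize,
    similarity_matrix,
    write_sif,
)
from .tsg import TissueGroupScheme, TsgCriteria, call_tsgs, tsg_calls_to_frame


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    expression_path: str
    scheme: dict[str, list[str]]
    units: str = "rpkm"
    gene_lengths_path: str | None = None
    library_sizes_path: str | None = None
    blast_paths: dict[str, str] = field(default_factory=dict)  # species -> path
    target_expression_paths: dict[str, str] = field(default_factory=dict)
    qpcr_path: str | None = None
    annotation_path: str | None = None
    high_threshold: float = 1.0
    low_threshold: float = 0.5
    evalue_max: float = DEFAULT_EVALUE_MAX
    high_fraction_threshold: float = 0.8
    linkage_method: str = "complete"
    distance_metric: str = "euclidean"
    min_edge: float = 0.0
    alpha: float = 0.05
    sep: str = "\t"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def input_paths(self) -> list[str]:
        paths = [self.expression_path]
        paths += [p for p in (self.gene_lengths_path, self.library_sizes_path) if p]
        paths += list(self.blast_paths.values())
        paths += list(self.target_expression_paths.values())
        paths += [p for p in (self.qpcr_path, self.annotation_path) if p]
        return paths


def annotate_genes(gene_table: pd.DataFrame, mapping_path: str | Path) -> pd.DataFrame:
    """Left-join a gene_id -> term annotation table onto a gene table.

    The mapping is two-column delimited text, possibly many rows per gene;
    terms per gene are concatenated with ';', de-duplicated, input order
    preserved. Genes without terms carry an empty annotation, never
    dropped.
    """
    terms: dict[str, list[str]] = {}
    with open(mapping_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValidationError(
                    f"annotation line {lineno}: expected two tab-separated fields"
                )
            gene, term = parts
            bucket = terms.setdefault(gene, [])
            if term not in bucket:
                bucket.append(term)
    out = gene_table.copy()
    out["annotation"] = [
        ";".join(terms.get(str(g), [])) for g in gene_table["gene_id"]
    ]
    return out


_FLOAT_FMT = "%.10g"


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every configured stage, writing the report bundle to ``out_dir``.

    Returns the run log dict (also written as run_log.json). Any stage
    failure removes partial outputs and raises :class:`PipelineError`
    naming the stage.
    """
    out_dir = Path(out_dir)
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise PipelineError("startup", f"missing input files: {missing}")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame, index: bool = False, index_label=None):
        path = out_dir / name
        frame.to_csv(
            path, sep=config.sep, index=index, index_label=index_label,
            float_format=_FLOAT_FMT,
        )
        written.append(path)
        return path

    log: dict = {
        "tsgcompare_version": __version__,
        "thresholds": {
            "high_threshold": config.high_threshold,
            "low_threshold": config.low_threshold,
            "evalue_max": config.evalue_max,
            "high_fraction_threshold": config.high_fraction_threshold,
            "alpha": config.alpha,
        },
        "counts": {},
    }
    stage = "startup"
    try:
        stage = "expression"
        matrix = read_expression_table(
            config.expression_path, units=config.units, sep=config.sep
        )
        if config.units == "counts":
            if not (config.gene_lengths_path and config.library_sizes_path):
                raise ValidationError(
                    "counts input requires gene_lengths_path and library_sizes_path"
                )
            matrix = counts_to_rpkm(
                matrix,
                read_gene_lengths(config.gene_lengths_path, sep=config.sep),
                read_library_sizes(config.library_sizes_path, sep=config.sep),
            )
        log["counts"]["genes_read"] = matrix.shape[0]
        log["counts"]["samples_read"] = matrix.shape[1]

        stage = "tsg_calling"
        scheme = TissueGroupScheme.from_dict(config.scheme)
        criteria = TsgCriteria(config.high_threshold, config.low_threshold)
        calls = call_tsgs(matrix, scheme, criteria)
        calls_df = tsg_calls_to_frame(calls)
        emit("tsg_calls.tsv", calls_df)
        log["counts"]["tsgs_called"] = len(calls)
        log["counts"]["tsgs_per_group"] = {
            g: int(n) for g, n in calls_df["group_label"].value_counts().sort_index().items()
        }

        stage = "annotation"
        if config.annotation_path:
            emit("tsg_calls_annotated.tsv", annotate_genes(calls_df, config.annotation_path))

        stage = "homology"
        hmap = HomologyMap()
        n_hits_read = 0
        if config.blast_paths:
            all_hits = []
            for species, path in sorted(config.blast_paths.items()):
                hits = parse_blast_tabular(path, species_tag=species)
                n_hits_read += len(hits)
                all_hits.extend(hits)
            hmap = best_hits(all_hits, evalue_max=config.evalue_max)
            emit("best_hits.tsv", hmap.to_frame())
            log["counts"]["blast_hits_read"] = n_hits_read
            log["counts"]["best_hits_kept"] = len(hmap)

        stage = "breakdown"
        species = sorted(config.blast_paths)
        if len(species) >= 2:
            by_group: dict[str, list[str]] = {g: [] for g in scheme.labels}
            for c in calls:
                by_group[c.group_label].append(c.gene_id)
            breakdown = homology_breakdown(by_group, hmap, (species[0], species[1]))
            emit("homology_breakdown.tsv", breakdown_to_frame(breakdown))

        stage = "similarity"
        sim_config = SimilarityConfig(config.high_fraction_threshold)
        matrices = {}
        for sp, path in sorted(config.target_expression_paths.items()):
            target = read_expression_table(path, units="rpkm", sep=config.sep)
            sim = similarity_matrix(calls, hmap, target, sp, sim_config)
            matrices[sp] = sim
            emit(f"similarity_{sp}.tsv", sim.fractions, index=True, index_label="group")
            log["counts"][f"similarity_{sp}_denominators"] = sim.denominators
            log["counts"][f"similarity_{sp}_dropped"] = sim.dropped

            stage = "clustering"
            profiles = []
            seen = set()
            for (q, tag), h in sorted(hmap.items()):
                if tag != sp or h.subject_id in seen or h.subject_id not in target.values.index:
                    continue
                seen.add(h.subject_id)
                p = minmax_normalize(target.values.loc[h.subject_id])
                if not p.degenerate:
                    profiles.append(p)
            if len(profiles) >= 2:
                result = cluster_profiles(
                    profiles, config.linkage_method, config.distance_metric
                )
                emit(
                    f"cluster_order_{sp}.tsv",
                    pd.DataFrame(
                        {
                            "gene_id": result.leaf_order,
                            "leaf_rank": range(len(result.leaf_order)),
                        }
                    ),
                )
            stage = "similarity"

        stage = "network"
        if matrices:
            edges, nodes = export_network(matrices, min_edge=config.min_edge)
            path = out_dir / "network_edges.sif"
            write_sif(edges, path)
            written.append(path)
            emit("network_nodes.tsv", nodes)
            log["counts"]["network_edges"] = len(edges)

        stage = "qpcr"
        if config.qpcr_path:
            measurements = read_qpcr_table(config.qpcr_path, sep=config.sep)
            by_gene: dict[str, list] = {}
            for m in measurements:
                by_gene.setdefault(m.gene_id, []).append(m)
            reports = [
                analyze_gene(ms, gene_id=g, alpha=config.alpha)
                for g, ms in sorted(by_gene.items())
            ]
            emit("qpcr_report.tsv", reports_to_frame(reports))
            posthoc_rows = []
            for r in reports:
                ph = r.posthoc.copy()
                ph.insert(0, "gene_id", r.gene_id)
                posthoc_rows.append(ph)
            if posthoc_rows:
                emit("qpcr_posthoc.tsv", pd.concat(posthoc_rows, ignore_index=True))
            log["counts"]["qpcr_genes_tested"] = len(reports)

        stage = "run_log"
        log_path = out_dir / "run_log.json"
        with open(log_path, "w") as fh:
            json.dump(log, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(log_path)
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:
        _cleanup(written)
        raise PipelineError(stage, str(exc)) from exc
    return log


def _cleanup(paths: list[Path]) -> None:
    for p in paths:
        try:
            p.unlink()
        except OSError:
            pass
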