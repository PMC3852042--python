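"""End-to-end orchestration: sets -> annotation -> trends -> retention fit."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import homology, ontology, trends
from .retention import RetentionModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    edges: Path
    genes: Path
    obo: Path
    annotations: Path
    group: homology.GenomeGroup
    out_dir: Path
    alpha_level: float = 0.05
    seed: int = 0
    n_ancestral: Optional[int] = None  # None: skip the retention fit
    #: which sets feed the retention counts: "full" (stable-genome framing)
    #: or "any"
    counts_restrict: str = "full"
    include_part_of: bool = False


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run build-sets -> annotate -> trends (-> fit-model); return the report.

    Every stage writes its outputs under ``config.out_dir`` so it can be
    reloaded independently; the report (also written as ``report.json``)
    records counts by completeness, the share of sets with at least one GO
    hit, the trend table file, the derived retention counts and the model
    fit, plus seeds and output checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        "alpha_level": config.alpha_level,
        "seed": config.seed,
        "n_ancestral": config.n_ancestral,
        "counts_restrict": config.counts_restrict,
        "group": {
            "name": config.group.name,
            "genomes": list(config.group.genomes),
        },
    }}

    stage = "build-sets"
    try:
        genes = homology.read_gene_table(config.genes)
        edges = homology.read_edge_list(config.edges)
        sets = homology.build_homology_sets(edges, genes, config.group)
        homology.write_set_members(sets, out / "set_members.tsv")
        homology.write_set_summary(sets, config.group, out / "set_summary.tsv")
        unplaced = homology.unplaced_genes(genes, sets)
        pd.DataFrame(
            [(g.gene_id, g.genome_id) for g in unplaced],
            columns=["gene_id", "genome_id"],
        ).to_csv(out / "unplaced_genes.tsv", sep="\t", index=False)
        by_completeness: dict[str, int] = {}
        for s in sets:
            by_completeness[s.completeness.kind] = (
                by_completeness.get(s.completeness.kind, 0) + 1
            )
        report[stage] = {
            "n_sets": len(sets),
            "by_completeness": by_completeness,
            "n_unplaced_genes": len(unplaced),
        }
    except Exception as exc:  # noqa: BLE001 - halt with stage name and cause
        raise PipelineError(stage, exc) from exc

    stage = "annotate"
    try:
        dag = ontology.load_ontology(
            str(config.obo), include_part_of=config.include_part_of
        )
        ann = ontology.read_annotations(config.annotations, dag=dag)
        set_ann = ontology.annotate_sets(sets, ann, dag)
        ontology.write_set_annotations(set_ann, out / "set_annotations.tsv")
        n_hit = sum(1 for v in set_ann.values() if v)
        report[stage] = {
            "n_terms": len(dag.terms),
            "n_annotated_genes": len(ann),
            "pct_sets_with_go_hit": 100.0 * n_hit / len(sets) if sets else 0.0,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "trends"
    try:
        scores = {s.set_id: s.score for s in sets}
        model = trends.TrendModel(
            set_ann, scores, dag, alpha_level=config.alpha_level,
            group_name=config.group.name,
        )
        res = model.fit()
        res.to_tsv(out / "trend_table.tsv")
        report[stage] = {
            "n_terms_analysed": len(res.table),
            "calls": res.table["call"].value_counts().to_dict(),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "fit-model"
    counts = homology.counts_from_sets(
        sets, config.group, restrict=config.counts_restrict
    )
    counts.to_csv(out / "retention_counts.tsv", sep="\t", index=False)
    report[stage] = {"counts": counts.to_dict(orient="list")}
    if config.n_ancestral is not None:
        try:
            fit = RetentionModel(counts, n_ancestral=config.n_ancestral).fit(
                seed=config.seed
            )
            report[stage].update(
                {
                    "loglike": fit.llf,
                    "params": fit.params_series().to_dict(),
                    "larger_class_share_pct": 100.0 * fit.larger_class_share,
                }
            )
            (out / "retention_params.tsv").write_text(
                fit.params_series().to_frame("estimate").to_csv(sep="\t")
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, exc) from exc

    report["checksums"] = {
        p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
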