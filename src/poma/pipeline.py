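"""Five-stage biomarker pipeline: DE -> network -> NOD -> TFP -> (assoc) -> AGP.

Stages, mirroring the funnel the improved-POMA model applies:

1. differential expression on the two-group matrix (t-test p < p_cut and
   |fold change| > fc_cut);
2. reference network build and trim to the disease-specific network;
3. NOD scoring and Wilcoxon outlier filter;
4. TFP scoring and outlier filter applied to stage-3 survivors;
5. optional intersection with a user-supplied literature-association miRNA
   list (a declarative stand-in for manual citation mining);
6. AGP scoring and outlier filter on stage-5 survivors;
7. ranking of the candidates by descending AGP (ties: NOD desc, then ID).

Outlier p-values for all three metrics are computed against the full
background of scored miRNAs; the sequential filters shrink the candidate
list, never the background. All intermediate tables are written so partial
funnels stay inspectable, and a run with a fixed config is byte-identical
across repeats.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import diffexpr, io, outliers, scores
from .io import GeneSet, ValidationError
from .network import build_reference_network, build_specific_network, write_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "CandidateReport", "StageError", "run_poma", "rank_candidates"]

STAGES = ("de", "network", "nod", "tfp", "association", "agp")


class StageError(RuntimeError):
    """A pipeline stage produced an empty result; partial outputs were kept."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    expression: Path
    annotation: Path
    interactions: list[Path]
    tf_genes: Path
    disease_genes: Path
    outdir: Path
    associated_mirnas: Path | None = None
    probe_map: Path | None = None
    gmt: Path | None = None
    p_cut: float = 0.05
    fc_cut: float = 2.0
    alpha: float = 0.05
    agp_network: str = "reference"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.p_cut, self.fc_cut, self.alpha) <= 0:
            raise ValidationError("thresholds must be positive")
        for name in ("expression", "annotation", "tf_genes", "disease_genes", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        self.interactions = [Path(p) for p in self.interactions]
        for name in ("associated_mirnas", "probe_map", "gmt"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    def to_dict(self) -> dict[str, Any]:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, list):
                v = [str(x) for x in v]
            d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(**d)


@dataclass
class CandidateReport:
    """Ranked candidates plus the full score table and per-stage provenance."""

    candidates: list[str]
    score_table: pd.DataFrame  # indexed by miRNA: nod/tfp/agp, *_p, stage_flags
    stage_counts: dict[str, int]
    survivors: dict[str, list[str]]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "candidates": self.candidates,
            "stage_counts": self.stage_counts,
            "survivors": self.survivors,
            "provenance": self.provenance,
        }


def rank_candidates(table: pd.DataFrame) -> list[str]:
    """Order miRNAs by descending AGP; ties by descending NOD, then ID."""
    if "agp" not in table.columns:
        raise ValidationError("AGP not computed")
    order = sorted(
        table.index, key=lambda m: (-table.at[m, "agp"], -table.at[m, "nod"], m)
    )
    return order


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _score_table_for_export(table: pd.DataFrame, ranking: list[str]) -> pd.DataFrame:
    rank = {m: i + 1 for i, m in enumerate(ranking)}
    rows = []
    for m in ranking:
        r = table.loc[m]
        rows.append(
            {
                "rank": rank[m],
                "mirna_id": m,
                "NOD": int(r["nod"]),
                "NOD_p": float(r["nod_p"]),
                "TFP": float(r["tfp"]),
                "TFP_p": float(r["tfp_p"]),
                "AGP": float(r["agp"]),
                "AGP_p": float(r["agp_p"]),
                "stage_flags": r["stage_flags"],
            }
        )
    return pd.DataFrame(rows, columns=io.SCORE_COLUMNS)


def run_poma(config: PipelineConfig) -> CandidateReport:
    """Execute the full pipeline and write all artifacts to ``config.outdir``.

    Raises :class:`StageError` naming the first stage whose survivor set is
    empty; artifacts computed before the failure are preserved on disk.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": config.to_dict(),
        "input_checksums": {
            str(p): _checksum(Path(p))
            for p in [config.expression, config.annotation, *config.interactions,
                      config.tf_genes, config.disease_genes]
            + ([config.associated_mirnas] if config.associated_mirnas else [])
        },
    }

    # stage 1: differential expression
    matrix = io.read_expression(config.expression, config.annotation)
    if config.probe_map is not None:
        matrix = diffexpr.collapse_probes(matrix, io.read_probe_map(config.probe_map))
    de_results = diffexpr.select_de_genes(matrix, config.p_cut, config.fc_cut)
    de_frame = diffexpr.de_results_frame(de_results)
    de_frame.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.10g")
    de_ids = sorted(r.gene_id for r in de_results if r.is_de)
    logger.info("stage de: %d/%d genes flagged", len(de_ids), len(de_results))
    if not de_ids:
        raise StageError("de", "no differentially expressed genes")
    de_set = GeneSet("de_genes", frozenset(io.normalize_gene(g) for g in de_ids))

    # stage 2: networks
    interactions = io.read_interactions(config.interactions)
    reference = build_reference_network(interactions)
    write_network(reference, out / "reference_network.tsv")
    try:
        specific = build_specific_network(reference, de_set)
    except ValidationError as exc:
        raise StageError("network", str(exc)) from exc
    write_network(specific, out / "specific_network.tsv")
    logger.info("stage network: %s", specific.summary())

    # stages 3-6: scoring and sequential outlier filtering
    tf_set = io.read_gene_set(config.tf_genes, "tf")
    disease_set = io.read_gene_set(config.disease_genes, "disease")
    table = scores.score_all(specific, reference, tf_set, disease_set, config.agp_network)
    for metric in ("nod", "tfp", "agp"):
        table[f"{metric}_p"] = outliers.outlier_pvalues(table[metric], metric)

    nod_survivors = outliers.select_significant(table, "nod", config.alpha)
    logger.info("stage nod: %d/%d survivors", len(nod_survivors), len(table))
    tfp_survivors = outliers.select_significant(table, "tfp", config.alpha, within=nod_survivors)
    logger.info("stage tfp: %d survivors", len(tfp_survivors))

    if config.associated_mirnas is not None:
        assoc = io.read_mirna_list(config.associated_mirnas)
        assoc_survivors = [m for m in tfp_survivors if m in assoc.members]
    else:
        assoc_survivors = list(tfp_survivors)
    logger.info("stage association: %d survivors", len(assoc_survivors))

    agp_survivors = outliers.select_significant(table, "agp", config.alpha, within=assoc_survivors)
    logger.info("stage agp: %d survivors", len(agp_survivors))

    survivors = {
        "nod": nod_survivors,
        "tfp": tfp_survivors,
        "association": assoc_survivors,
        "agp": agp_survivors,
    }
    flags = {
        m: ",".join(s for s in ("nod", "tfp", "association", "agp") if m in set(survivors[s]))
        or "-"
        for m in table.index
    }
    table["stage_flags"] = pd.Series(flags)

    # stage 7: ranking and report
    full_ranking = rank_candidates(table)
    export = _score_table_for_export(table, full_ranking)
    io.write_score_table(export, out / "score_table.tsv")
    candidates = rank_candidates(table.loc[agp_survivors]) if agp_survivors else []
    report = CandidateReport(
        candidates=candidates,
        score_table=table,
        stage_counts={
            "de_genes": len(de_ids),
            "network_mirnas": len(specific.mirna_nodes),
            "network_genes": len(specific.gene_nodes),
            "network_edges": specific.graph.number_of_edges(),
            "nod": len(nod_survivors),
            "tfp": len(tfp_survivors),
            "association": len(assoc_survivors),
            "agp": len(agp_survivors),
        },
        survivors=survivors,
        provenance=provenance,
    )
    if candidates:
        io.write_score_table(
            _score_table_for_export(table, candidates), out / "candidates.tsv"
        )
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    for stage in ("nod", "tfp", "association", "agp"):
        if not survivors[stage]:
            raise StageError(stage, "no surviving miRNAs")
    return report
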