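"""End-to-end orchestration: normalize -> QC -> DE -> filters -> cluster ->
target scan -> negative-network integration -> export.

Every stated analysis threshold lives in :class:`PipelineConfig`:
gene DE |log2FC| >= 1 at FDR <= 0.01; miRNA DE at raw p <= 0.05; the
|log2FC| >= 2 screen feeding the k = 6 co-expression clustering; the
score < 4 target retention rule; and the FC > 4 gate for network miRNAs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

from . import coexpression, expression, network, targetscan
from .io import (
    ExpressionMatrix,
    TillermirError,
    parse_annotation_map,
    parse_expression_table,
    parse_fasta,
    read_design,
    read_id_list,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths, thresholds, and switches for one pipeline run."""

    gene_matrix: str
    gene_design: str
    mirna_matrix: str
    mirna_design: str
    transcripts: str
    mirnas: str
    annotations: str | None = None
    tf_list: str | None = None
    transcript_gene_map: str | None = None
    gene_unit: str = "FPKM"
    mirna_unit: str = "counts"
    group_a: str = "TP"
    group_b: str = "YS"
    lfc_min: float = 1.0
    fdr: float = 0.01
    mirna_p: float = 0.05
    screen_lfc: float = 2.0
    network_fc: float = 4.0
    score_threshold: float = 4.0
    k: int = 6
    epsilon: float = 0.01
    seed: int = 0
    double_wobble_in_seed: bool = True
    best_per_pair: bool = True

    def __post_init__(self) -> None:
        for name in ("lfc_min", "fdr", "mirna_p", "screen_lfc", "network_fc",
                     "score_threshold", "epsilon"):
            if getattr(self, name) <= 0 and name != "lfc_min":
                raise TillermirError(f"{name} must be positive")
        if self.k < 1:
            raise TillermirError("k must be >= 1")


@dataclass
class PipelineResult:
    summary: dict[str, Any]
    outdir: Path
    de_genes: dict[str, list[expression.DeRecord]] = field(default_factory=dict)
    de_mirnas: list[expression.DeRecord] = field(default_factory=list)
    pairs: list[network.InteractionPair] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage, writing result tables and a machine-readable run
    summary (counts per stage, config, seed) under `outdir`.

    Any stage error aborts with the stage name and cause; the summary is
    still written with a `failed_stage` marker so partial output is
    flagged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": asdict(config), "stages": {}}
    result = PipelineResult(summary=summary, outdir=outdir)

    try:
        _run_stages(config, outdir, summary, result)
    except PipelineStageError as exc:
        summary["failed_stage"] = exc.stage
        summary["error"] = str(exc.cause)
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return result


def _run_stages(
    config: PipelineConfig,
    outdir: Path,
    summary: dict[str, Any],
    result: PipelineResult,
) -> None:
    stages = summary["stages"]

    @_stage("load")
    def load():
        gene = parse_expression_table(
            config.gene_matrix, read_design(config.gene_design), config.gene_unit
        )
        mirna = parse_expression_table(
            config.mirna_matrix, read_design(config.mirna_design), config.mirna_unit
        )
        transcripts = parse_fasta(config.transcripts, kind="transcript")
        mirna_seqs = parse_fasta(config.mirnas, kind="mirna")
        return gene, mirna, transcripts, mirna_seqs

    gene_matrix, mirna_matrix, transcripts, mirna_seqs = load()
    stages["load"] = {
        "genes": len(gene_matrix.feature_ids),
        "mirnas": len(mirna_matrix.feature_ids),
        "transcripts": len(transcripts),
        "mirna_sequences": len(mirna_seqs),
    }
    logger.info("load: %s", stages["load"])

    @_stage("normalize")
    def normalize() -> ExpressionMatrix:
        if mirna_matrix.unit == "counts":
            return expression.compute_tpm(mirna_matrix)
        return mirna_matrix

    mirna_tpm = normalize()
    if gene_matrix.unit not in ("FPKM", "TPM"):
        raise PipelineStageError(
            "normalize",
            TillermirError(
                f"gene matrix unit {gene_matrix.unit!r} is not normalized; "
                "provide FPKM (use compute_fpkm with lengths and library sizes)"
            ),
        )
    stages["normalize"] = {"mirna_unit": mirna_tpm.unit, "gene_unit": gene_matrix.unit}

    @_stage("qc")
    def qc():
        out = {}
        for label, m in (("gene", gene_matrix), ("mirna", mirna_tpm)):
            pcc = expression.replicate_pcc(m)
            pcc.to_csv(outdir / f"{label}_replicate_pcc.tsv", sep="\t", lineterminator="\n")
            within = []
            for t in m.tissues():
                cols = m.samples_for(t)
                for i, a in enumerate(cols):
                    for b in cols[i + 1:]:
                        within.append(float(pcc.loc[a, b]))
            out[f"{label}_min_within_tissue_pcc"] = min(within) if within else None
        return out

    stages["qc"] = qc()
    logger.info("qc: %s", stages["qc"])

    tissues = gene_matrix.tissues()

    @_stage("de_genes")
    def de_genes():
        records = {}
        for i, a in enumerate(tissues):
            for b in tissues[i + 1:]:
                key = f"{a}_vs_{b}"
                recs = expression.call_de(
                    gene_matrix, a, b,
                    lfc_min=config.lfc_min, alpha=config.fdr,
                    criterion="fdr", epsilon=config.epsilon,
                )
                expression.write_de_table(recs, outdir / f"de_genes_{key}.tsv")
                records[key] = recs
        return records

    result.de_genes = de_genes()
    stages["de_genes"] = {
        key: sum(r.is_de for r in recs) for key, recs in result.de_genes.items()
    }
    logger.info("de_genes: %s", stages["de_genes"])

    @_stage("de_mirnas")
    def de_mirnas():
        recs = expression.call_de(
            mirna_tpm, config.group_a, config.group_b,
            lfc_min=0.0, alpha=config.mirna_p,
            criterion="pvalue", epsilon=config.epsilon,
        )
        expression.write_de_table(
            recs, outdir / f"de_mirnas_{config.group_a}_vs_{config.group_b}.tsv"
        )
        return recs

    result.de_mirnas = de_mirnas()
    stages["de_mirnas"] = {"n_de": sum(r.is_de for r in result.de_mirnas)}
    logger.info("de_mirnas: %s", stages["de_mirnas"])

    @_stage("filters")
    def filters():
        valid = expression.call_valid_genes(gene_matrix)
        ts_calls = expression.call_tissue_specific(gene_matrix)
        with open(outdir / "tissue_specific_genes.tsv", "w") as fh:
            fh.write("feature_id\ttissue\n")
            for c in sorted(ts_calls, key=lambda c: (c.tissue, c.feature_id)):
                fh.write(f"{c.feature_id}\t{c.tissue}\n")
        return valid, ts_calls

    valid, ts_calls = filters()
    stages["filters"] = {
        "valid_gene_venn": valid.venn_counts(),
        "tissue_specific": {
            t: sum(c.tissue == t for c in ts_calls) for t in tissues
        },
    }
    logger.info("filters: %s", stages["filters"])

    @_stage("cluster")
    def cluster():
        screened = coexpression.screen_degs(
            [r for recs in result.de_genes.values() for r in recs],
            lfc_screen=config.screen_lfc,
        )
        profiles = coexpression.build_profiles(gene_matrix, screened)
        clusters = coexpression.kmeans_cluster(
            profiles, k=config.k, seed=config.seed
        )
        coexpression.assignments_to_frame(clusters).to_csv(
            outdir / "cluster_assignments.tsv", sep="\t", index=False, lineterminator="\n"
        )
        enrich_counts = {}
        if config.annotations:
            annotations = parse_annotation_map(config.annotations)
            background = set(gene_matrix.feature_ids)
            for label in range(1, clusters.k + 1):
                results = coexpression.enrich(
                    clusters.members(label), background, annotations
                )
                coexpression.enrichment_to_frame(results).to_csv(
                    outdir / f"enrichment_cluster{label}.tsv",
                    sep="\t", index=False, lineterminator="\n",
                )
                enrich_counts[str(label)] = sum(r.fdr <= 0.05 for r in results)
        return screened, clusters, enrich_counts

    screened, clusters, enrich_counts = cluster()
    stages["cluster"] = {
        "screened": len(screened),
        "clustered": len(clusters.assignments),
        "k": clusters.k,
        "inertia": clusters.inertia,
        "enriched_terms_fdr05": enrich_counts,
    }
    logger.info("cluster: %s", stages["cluster"])

    @_stage("scan")
    def scan():
        hits = targetscan.scan_many(
            mirna_seqs, transcripts,
            max_report_score=config.score_threshold,
            double_wobble_in_seed=config.double_wobble_in_seed,
        )
        retained = targetscan.filter_hits(
            hits, threshold=config.score_threshold, best_per_pair=config.best_per_pair
        )
        targetscan.write_hits_table(retained, outdir / "retained_hits.tsv")
        return hits, retained

    hits, retained = scan()
    stages["scan"] = {"scanned_hits": len(hits), "retained_hits": len(retained)}
    logger.info("scan: %s", stages["scan"])

    @_stage("network")
    def build_network():
        key = f"{config.group_a}_vs_{config.group_b}"
        gene_records = result.de_genes[key]
        net_mirnas = network.select_network_mirnas(
            result.de_mirnas, fc_min=config.network_fc
        )
        tf = read_id_list(config.tf_list) if config.tf_list else set()
        tx_map = None
        if config.transcript_gene_map:
            import pandas as pd

            df = pd.read_csv(
                config.transcript_gene_map, sep="\t",
                names=["transcript_id", "gene_id"], header=None,
            )
            tx_map = dict(zip(df.transcript_id, df.gene_id))
        pairs = network.build_negative_pairs(
            net_mirnas, result.de_mirnas, gene_records, retained,
            tf_list=tf, transcript_to_gene=tx_map,
        )
        network.export_network(pairs, outdir / "network_edges.tsv", "edge_tsv")
        network.export_network(pairs, outdir / "network.sif", "sif")
        return net_mirnas, pairs

    net_mirnas, pairs = build_network()
    result.pairs = pairs
    net_summary = network.summarize_network(pairs)
    stages["network"] = {
        "network_mirnas": len(net_mirnas),
        "n_pairs": net_summary.n_pairs,
        "n_mirnas": net_summary.n_mirnas,
        "n_genes": net_summary.n_genes,
        "pairs_by_direction": net_summary.pairs_by_direction,
        "n_tf_targets": net_summary.n_tf_targets,
    }
    logger.info("network: %s", stages["network"])

    # bookkeeping consistency
    assert stages["network"]["network_mirnas"] <= len(result.de_mirnas)
    assert stages["scan"]["retained_hits"] <= stages["scan"]["scanned_hits"]
    assert stages["network"]["n_pairs"] <= stages["scan"]["retained_hits"]
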