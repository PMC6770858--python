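"""Negative miRNA-mRNA interaction network construction and export.

A "negative interaction" is a predicted miRNA-target pair whose two members
are differentially expressed in opposite directions between the two
compared tissues (tiller primordia vs young spikes in the motivating
design). Admission requires all four of:

1. the miRNA is DE with linear fold change strictly above `fc_min`
   (default 4, i.e. |log2FC| > 2);
2. the target gene passes the gene DE thresholds;
3. the DE directions are opposite (sign(miRNA log2FC) = -sign(gene log2FC));
4. a retained duplex hit (penalty score < 4) links the pair.

Transcript ids resolve to gene ids through an optional map (identity by
default); transcription factors are flagged from a user-supplied id list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .expression import DeRecord
from .targetscan import DuplexHit
from .io import TillermirError

logger = logging.getLogger(__name__)

NETWORK_FC_MIN = 4.0


@dataclass(frozen=True)
class InteractionPair:
    mirna_id: str
    gene_id: str
    mirna_log2fc: float
    gene_log2fc: float
    best_score: float  # minimum penalty over linking hits (half-integer)
    mirna_direction: str  # 'up_in_a' / 'up_in_b'
    gene_direction: str
    is_tf: bool = False


@dataclass(frozen=True)
class NetworkSummary:
    n_pairs: int
    n_mirnas: int
    n_genes: int
    pairs_by_direction: dict[str, int]  # keyed by the gene's DE direction
    n_tf_targets: int


def select_network_mirnas(
    de_mirnas: Iterable[DeRecord], fc_min: float = NETWORK_FC_MIN
) -> set[str]:
    """miRNAs admitted to the network: DE with linear fold change strictly
    above fc_min in either direction (|log2FC| > log2(fc_min))."""
    lfc_min = math.log2(fc_min)
    return {
        r.feature_id
        for r in de_mirnas
        if r.is_de and abs(r.log2fc) > lfc_min
    }


def build_negative_pairs(
    network_mirnas: set[str],
    de_mirnas: Iterable[DeRecord],
    de_genes: Iterable[DeRecord],
    retained_hits: Iterable[DuplexHit],
    tf_list: set[str] | None = None,
    transcript_to_gene: Mapping[str, str] | None = None,
) -> list[InteractionPair]:
    """Emit every (miRNA, gene) pair satisfying the four admission
    conditions, in deterministic (mirna_id, gene_id) order.

    Hits referencing features absent from the DE records are skipped; the
    skip count is logged.
    """
    tf_list = tf_list or set()
    mirna_by_id = {r.feature_id: r for r in de_mirnas}
    gene_by_id = {r.feature_id: r for r in de_genes}

    best: dict[tuple[str, str], int] = {}
    skipped = 0
    for h in retained_hits:
        if not h.retained:
            continue
        gene_id = (
            transcript_to_gene.get(h.transcript_id, h.transcript_id)
            if transcript_to_gene
            else h.transcript_id
        )
        if h.mirna_id not in mirna_by_id or gene_id not in gene_by_id:
            skipped += 1
            continue
        key = (h.mirna_id, gene_id)
        if key not in best or h.score_half < best[key]:
            best[key] = h.score_half
    if skipped:
        logger.warning("skipped %d hits with no matching DE record", skipped)

    pairs: list[InteractionPair] = []
    for (mirna_id, gene_id), score_half in sorted(best.items()):
        if mirna_id not in network_mirnas:
            continue
        m = mirna_by_id[mirna_id]
        g = gene_by_id[gene_id]
        if not g.is_de:
            continue
        if m.log2fc * g.log2fc >= 0:  # same direction or degenerate: not negative
            continue
        pairs.append(
            InteractionPair(
                mirna_id=mirna_id,
                gene_id=gene_id,
                mirna_log2fc=m.log2fc,
                gene_log2fc=g.log2fc,
                best_score=score_half / 2.0,
                mirna_direction=m.direction,
                gene_direction=g.direction,
                is_tf=gene_id in tf_list,
            )
        )
    return pairs


def summarize_network(pairs: Sequence[InteractionPair]) -> NetworkSummary:
    by_direction: dict[str, int] = {}
    for p in pairs:
        by_direction[p.gene_direction] = by_direction.get(p.gene_direction, 0) + 1
    return NetworkSummary(
        n_pairs=len(pairs),
        n_mirnas=len({p.mirna_id for p in pairs}),
        n_genes=len({p.gene_id for p in pairs}),
        pairs_by_direction=by_direction,
        n_tf_targets=len({p.gene_id for p in pairs if p.is_tf}),
    )


_EDGE_COLUMNS = ["mirna_id", "gene_id", "mirna_log2fc", "gene_log2fc",
                 "best_score", "mirna_direction", "gene_direction", "is_tf"]


def export_network(
    pairs: Sequence[InteractionPair], path: str | Path, format: str = "edge_tsv"
) -> None:
    """Write the network as an edge-list TSV or a Cytoscape SIF
    ('mirna represses gene'), in stable (mirna_id, gene_id) order."""
    ordered = sorted(pairs, key=lambda p: (p.mirna_id, p.gene_id))
    if format == "edge_tsv":
        pd.DataFrame(
            [
                (p.mirna_id, p.gene_id, p.mirna_log2fc, p.gene_log2fc,
                 p.best_score, p.mirna_direction, p.gene_direction, p.is_tf)
                for p in ordered
            ],
            columns=_EDGE_COLUMNS,
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for p in ordered:
                fh.write(f"{p.mirna_id}\trepresses\t{p.gene_id}\n")
    else:
        raise TillermirError(f"unknown network export format {format!r}")


def parse_edge_tsv(path: str | Path) -> list[InteractionPair]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _EDGE_COLUMNS:
        raise TillermirError(f"unexpected edge-list columns in {path}")
    return [
        InteractionPair(
            mirna_id=str(r.mirna_id),
            gene_id=str(r.gene_id),
            mirna_log2fc=float(r.mirna_log2fc),
            gene_log2fc=float(r.gene_log2fc),
            best_score=float(r.best_score),
            mirna_direction=str(r.mirna_direction),
            gene_direction=str(r.gene_direction),
            is_tf=bool(r.is_tf),
        )
        for r in df.itertuples()
    ]
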