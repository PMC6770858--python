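"""Normalization, replicate QC, differential expression, and filter rules.

The DE caller is a two-sided Student's t-test on log2(x + 1) with
Benjamini-Hochberg correction across all tested features, driven by the
study's thresholds: genes are called at |log2FC| >= 1 and FDR <= 0.01;
miRNAs at a raw-p threshold of 0.05 with no fold-change floor. Fold changes
are computed on the original abundance scale with a small epsilon guard.

Filter rules implemented here:

* valid gene — abundance strictly above 1 in every replicate of a tissue;
* tissue-specific — mean abundance in one tissue strictly more than twice
  the mean in each of the other two tissues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, TISSUES, TillermirError

DEFAULT_EPSILON = 0.01


@dataclass(frozen=True)
class DeRecord:
    """Per-feature two-group comparison result (group A vs group B)."""

    feature_id: str
    mean_a: float
    mean_b: float
    log2fc: float  # log2((mean_b + eps) / (mean_a + eps))
    p_value: float
    fdr: float
    is_de: bool
    direction: str  # 'up_in_b', 'up_in_a', or 'none'


@dataclass(frozen=True)
class TissueSpecificCall:
    feature_id: str
    tissue: str
    tissue_means: dict[str, float]
    ratios: tuple[float, float]  # specific mean / each other tissue mean


@dataclass(frozen=True)
class ValidGeneSet:
    """Per-tissue valid-gene sets plus the derived Venn counts."""

    by_tissue: dict[str, frozenset[str]]

    def venn_counts(self) -> dict[str, int]:
        tissues = [t for t in TISSUES if t in self.by_tissue]
        sets = {t: self.by_tissue[t] for t in tissues}
        counts: dict[str, int] = {}
        if len(tissues) == 3:
            a, b, c = (sets[t] for t in tissues)
            counts[f"{tissues[0]}_only"] = len(a - b - c)
            counts[f"{tissues[1]}_only"] = len(b - a - c)
            counts[f"{tissues[2]}_only"] = len(c - a - b)
            counts["shared_all"] = len(a & b & c)
        counts["union"] = len(frozenset().union(*sets.values())) if sets else 0
        return counts


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million normalization: each sample column is scaled
    to sum to 1e6. Requires unit 'counts' and a positive total per sample."""
    if counts.unit != "counts":
        raise TillermirError(f"compute_tpm expects unit 'counts', got {counts.unit!r}")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise TillermirError(f"all-zero sample {zero.index[0]!r}: cannot normalize")
    tpm = counts.values / totals * 1e6
    return ExpressionMatrix(values=tpm, design=counts.design.copy(), unit="TPM")


def compute_fpkm(
    counts: ExpressionMatrix,
    lengths: dict[str, float] | pd.Series,
    library_sizes: dict[str, float] | pd.Series,
) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (feature length in nt * library size)."""
    if counts.unit != "counts":
        raise TillermirError(f"compute_fpkm expects unit 'counts', got {counts.unit!r}")
    lengths = pd.Series(lengths, dtype=float)
    missing = [f for f in counts.feature_ids if f not in lengths.index]
    if missing:
        raise TillermirError(f"missing length for feature {missing[0]!r}")
    lengths = lengths.loc[counts.feature_ids]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise TillermirError(f"non-positive length for feature {bad!r}")
    lib = pd.Series(library_sizes, dtype=float)
    missing_s = [s for s in counts.sample_ids if s not in lib.index]
    if missing_s:
        raise TillermirError(f"missing library size for sample {missing_s[0]!r}")
    lib = lib.loc[counts.sample_ids]
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise TillermirError(f"non-positive library size for sample {bad!r}")
    fpkm = counts.values.mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(values=fpkm, design=counts.design.copy(), unit="FPKM")


def replicate_pcc(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation over all sample pairs (replicate-consistency QC).

    Zero-variance samples yield NaN against every partner (flagged
    undefined, never silently 0); the diagonal is 1 for non-degenerate
    samples.
    """
    if len(matrix.feature_ids) < 2:
        raise TillermirError("need >= 2 features to correlate samples")
    return matrix.values.corr(method="pearson")


def log2_fold_change(mean_a: float, mean_b: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """log2((mean_b + eps) / (mean_a + eps)); antisymmetric in (a, b)."""
    if epsilon <= 0:
        raise TillermirError("epsilon must be > 0")
    if mean_a < 0 or mean_b < 0:
        raise TillermirError("group means must be non-negative")
    return math.log2((mean_b + epsilon) / (mean_a + epsilon))


def call_de(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    lfc_min: float = 1.0,
    alpha: float = 0.01,
    criterion: str = "fdr",
    epsilon: float = DEFAULT_EPSILON,
) -> list[DeRecord]:
    """Two-group differential expression between two tissues.

    p-values come from a two-sided Student's t-test (pooled variance) on
    log2(value + 1) per feature; FDR is Benjamini-Hochberg over all tested
    features. The pooled-variance test is exact under log-normal noise and
    holds its nominal size at small replicate counts, where the unpooled
    variant is conservative. A feature
    is DE iff |log2FC| >= lfc_min and (fdr if criterion='fdr' else p)
    <= alpha. Gene defaults are shown; for miRNAs use lfc_min=0,
    alpha=0.05, criterion='pvalue'. Features constant in both groups get
    p = 1 by convention.
    """
    if criterion not in ("fdr", "pvalue"):
        raise TillermirError(f"criterion must be 'fdr' or 'pvalue', got {criterion!r}")
    a_cols = matrix.samples_for(group_a)
    b_cols = matrix.samples_for(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise TillermirError(
            f"each group needs >= 2 replicates (got {group_a}:{len(a_cols)}, "
            f"{group_b}:{len(b_cols)})"
        )
    a = matrix.values[a_cols].to_numpy(dtype=float)
    b = matrix.values[b_cols].to_numpy(dtype=float)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(la, lb, axis=1, equal_var=True)
    # constant-in-both-groups features: p = 1 by convention (not NaN)
    constant = (np.ptp(la, axis=1) == 0) & (np.ptp(lb, axis=1) == 0)
    pvals = np.where(constant | ~np.isfinite(pvals), 1.0, pvals)

    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = np.log2((mean_b + epsilon) / (mean_a + epsilon))

    records = []
    for i, fid in enumerate(matrix.feature_ids):
        stat_val = fdrs[i] if criterion == "fdr" else pvals[i]
        de = bool(abs(lfc[i]) >= lfc_min and stat_val <= alpha)
        if de:
            direction = "up_in_b" if lfc[i] > 0 else "up_in_a"
        else:
            direction = "none"
        records.append(
            DeRecord(
                feature_id=fid,
                mean_a=float(mean_a[i]),
                mean_b=float(mean_b[i]),
                log2fc=float(lfc[i]),
                p_value=float(pvals[i]),
                fdr=float(fdrs[i]),
                is_de=de,
                direction=direction,
            )
        )
    return records


def call_valid_genes(matrix: ExpressionMatrix, floor: float = 1.0) -> ValidGeneSet:
    """A gene is valid in tissue t iff its abundance is strictly above
    `floor` in every replicate of t."""
    by_tissue: dict[str, frozenset[str]] = {}
    for t in matrix.tissues():
        vals = matrix.tissue_values(t)
        ok = (vals > floor).all(axis=1)
        by_tissue[t] = frozenset(vals.index[ok])
    return ValidGeneSet(by_tissue=by_tissue)


def call_tissue_specific(
    matrix: ExpressionMatrix, ratio_min: float = 2.0
) -> list[TissueSpecificCall]:
    """Emit a call for tissue t iff mean_t > ratio_min * mean_u for BOTH
    other tissues (strict). At most one call per feature follows from the
    strict >2x rule; all-zero features yield no call."""
    means = matrix.tissue_means()
    tissues = list(means.columns)
    if len(tissues) != 3:
        raise TillermirError("tissue-specific calling needs the 3-tissue design")
    calls: list[TissueSpecificCall] = []
    for fid, row in means.iterrows():
        for t in tissues:
            others = [u for u in tissues if u != t]
            if all(row[t] > ratio_min * row[u] for u in others):
                ratios = tuple(
                    float("inf") if row[u] == 0 else float(row[t] / row[u])
                    for u in others
                )
                calls.append(
                    TissueSpecificCall(
                        feature_id=str(fid),
                        tissue=t,
                        tissue_means={u: float(row[u]) for u in tissues},
                        ratios=ratios,  # type: ignore[arg-type]
                    )
                )
                break  # strict rule: at most one tissue can win
    return calls


def de_records_to_frame(records: list[DeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_id, r.mean_a, r.mean_b, r.log2fc, r.p_value, r.fdr, r.is_de, r.direction)
            for r in records
        ],
        columns=["feature_id", "mean_a", "mean_b", "log2fc", "p_value", "fdr", "is_de", "direction"],
    )


def write_de_table(records: list[DeRecord], path: str | Path) -> None:
    de_records_to_frame(records).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_de_table(path: str | Path) -> list[DeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DeRecord(
            feature_id=str(row.feature_id),
            mean_a=float(row.mean_a),
            mean_b=float(row.mean_b),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            fdr=float(row.fdr),
            is_de=bool(row.is_de),
            direction=str(row.direction),
        )
        for row in df.itertuples()
    ]
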