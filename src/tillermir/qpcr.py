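"""Relative qPCR quantification by the 2^-ddCt method.

dCt = Ct(target) - Ct(reference gene) within a sample; ddCt compares a
sample's dCt to a calibrator sample's; relative expression is 2^-ddCt.
Technical replicates are averaged on the Ct (cycle) scale before the
subtraction, the standard bench convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import TillermirError

CT_WARN_LO = 0.0
CT_WARN_HI = 45.0


@dataclass(frozen=True)
class CtObservation:
    sample_id: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        for name, v in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if not math.isfinite(v):
                raise TillermirError(f"{self.sample_id}: non-finite {name} {v!r}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def relative_expression(obs: CtObservation, calibrator: CtObservation) -> float:
    """2^-(dCt(obs) - dCt(calibrator)); 1.0 when obs is its own calibrator."""
    ddct = obs.delta_ct - calibrator.delta_ct
    return 2.0 ** (-ddct)


def relative_expression_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """Compute relative expression for every (sample, gene) in a long-format
    Ct table with columns sample_id, gene, ct.

    Technical replicates (repeated rows) are averaged on the Ct scale. The
    output has columns sample_id, gene, rel_expression.
    """
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise TillermirError(f"Ct table needs columns {sorted(required)}")
    mean_ct = ct_table.groupby(["sample_id", "gene"], sort=True)["ct"].mean()
    samples = mean_ct.index.get_level_values("sample_id").unique()
    if calibrator_sample not in samples:
        raise TillermirError(f"calibrator sample {calibrator_sample!r} not in table")
    rows = []
    for sample in samples:
        per_gene = mean_ct.loc[sample]
        if reference_gene not in per_gene.index:
            raise TillermirError(
                f"reference gene {reference_gene!r} missing for sample {sample!r}"
            )
        for gene, ct in per_gene.items():
            if gene == reference_gene:
                continue
            obs = CtObservation(sample, float(ct), float(per_gene[reference_gene]))
            cal_genes = mean_ct.loc[calibrator_sample]
            if gene not in cal_genes.index:
                raise TillermirError(
                    f"gene {gene!r} missing for calibrator {calibrator_sample!r}"
                )
            cal = CtObservation(
                calibrator_sample,
                float(cal_genes[gene]),
                float(cal_genes[reference_gene]),
            )
            rows.append((sample, gene, relative_expression(obs, cal)))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "rel_expression"])


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    df["ct"] = df["ct"].astype(float)
    return df
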