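"""Domain types and readers/writers shared by every pipeline stage.

Sequences are stored on the RNA alphabet {A, C, G, U}; DNA input (T) is
accepted everywhere and normalized to U at parse time, since public miRNA
tables print DNA while duplex scoring is defined on RNA pairing.

Expression matrices carry an explicit sample design (tissue, replicate) for
the three-tissue comparison this package targets: tiller primordia (TP),
stem tips (ST), and young spikes (YS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

RNA_ALPHABET = frozenset("ACGU")
TISSUES = ("TP", "ST", "YS")

MIRNA_MIN_LEN = 18
MIRNA_MAX_LEN = 30


class TillermirError(ValueError):
    """Base class for domain validation errors."""


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, convert T to U, and validate against the RNA alphabet.

    Raises :class:`TillermirError` naming the first offending character and
    its 1-based position.
    """
    seq = raw.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise TillermirError(
                f"{context}: invalid character {ch!r} at position {pos} "
                f"(alphabet is A/C/G/U, T accepted as U)"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A transcript (mRNA) sequence on the RNA alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise TillermirError("sequence record must have a non-empty id")
        object.__setattr__(self, "seq", normalize_sequence(self.seq, context=self.id))
        if not self.seq:
            raise TillermirError(f"{self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MirnaRecord(SequenceRecord):
    """A mature miRNA sequence, 18-30 nt (the small-RNA validity window)."""

    origin: str = "known"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.origin not in ("known", "novel"):
            raise TillermirError(f"{self.id}: origin must be 'known' or 'novel'")
        n = len(self.seq)
        if not (MIRNA_MIN_LEN <= n <= MIRNA_MAX_LEN):
            raise TillermirError(
                f"{self.id}: miRNA length {n} nt outside the valid "
                f"{MIRNA_MIN_LEN}-{MIRNA_MAX_LEN} nt range"
            )


def parse_fasta(path: str | Path, kind: str = "transcript") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecord or MirnaRecord objects.

    kind='mirna' enforces the 18-30 nt rule per record. Duplicate ids are an
    error. Records are returned in file order.
    """
    if kind not in ("transcript", "mirna"):
        raise TillermirError(f"unknown FASTA kind {kind!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise TillermirError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        if kind == "mirna":
            origin = "novel" if "novel" in rec.description.lower() else "known"
            records.append(MirnaRecord(id=rec.id, seq=str(rec.seq), origin=origin))
        else:
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA (RNA alphabet, 70-column wrap)."""
    bio = []
    for r in records:
        desc = r.origin if isinstance(r, MirnaRecord) else ""
        bio.append(_BioSeqRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples abundance grid with tissue/replicate design.

    values: DataFrame indexed by feature id, columns are sample ids.
    design: DataFrame indexed by sample id with columns 'tissue', 'replicate'.
    unit: one of 'counts', 'FPKM', 'TPM'.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise TillermirError(f"duplicate feature id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise TillermirError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise TillermirError(
                f"non-finite value at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TillermirError(
                f"negative value {arr[i, j]} at feature {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )
        missing = set(v.columns) - set(self.design.index)
        if missing:
            raise TillermirError(f"design missing samples: {sorted(missing)}")
        v.index.name = "feature_id"
        v.columns.name = None
        self.design = self.design.loc[list(v.columns), ["tissue", "replicate"]]
        self.design.index.name = "sample_id"
        bad = set(self.design["tissue"]) - set(TISSUES)
        if bad:
            raise TillermirError(f"unknown tissues in design: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tissues(self) -> list[str]:
        present = set(self.design["tissue"])
        return [t for t in TISSUES if t in present]

    def samples_for(self, tissue: str) -> list[str]:
        return list(self.design.index[self.design["tissue"] == tissue])

    def tissue_values(self, tissue: str) -> pd.DataFrame:
        return self.values[self.samples_for(tissue)]

    def tissue_means(self) -> pd.DataFrame:
        """Per-feature arithmetic mean of replicates, one column per tissue."""
        return pd.DataFrame(
            {t: self.tissue_values(t).mean(axis=1) for t in self.tissues()}
        )

    def write(self, values_path: str | Path, design_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, sep="\t", lineterminator="\n")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", lineterminator="\n")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design TSV: columns sample_id, tissue, replicate."""
    d = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    required = {"sample_id", "tissue", "replicate"}
    if not required.issubset(d.columns):
        raise TillermirError(
            f"design file {path} must have columns {sorted(required)}"
        )
    return d.set_index("sample_id")


def parse_expression_table(
    path: str | Path,
    design: pd.DataFrame | Mapping[str, tuple[str, int]],
    unit: str,
) -> ExpressionMatrix:
    """Read a feature_id-keyed TSV of abundances into an ExpressionMatrix.

    `design` is either the DataFrame from :func:`read_design` or a mapping
    sample_id -> (tissue, replicate). Negative or non-numeric cells raise
    with their coordinates; row/column order is preserved.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(
            [(s, t, r) for s, (t, r) in design.items()],
            columns=["sample_id", "tissue", "replicate"],
        ).set_index("sample_id")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                feat = raw.index[bad][0]
                raise TillermirError(
                    f"non-numeric value {raw.loc[feat, col]!r} at feature "
                    f"{feat!r}, sample {col!r}"
                ) from exc
        raise
    return ExpressionMatrix(values=values, design=design, unit=unit)


# ---------------------------------------------------------------------------
# Annotation maps
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """feature id -> set of term ids, with optional term labels."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def add(self, feature_id: str, term_id: str, label: str | None = None) -> None:
        if not term_id:
            raise TillermirError("empty term id")
        self.terms.setdefault(feature_id, set()).add(term_id)
        if label:
            self.labels[term_id] = label

    def features_for(self, term_id: str) -> set[str]:
        return {f for f, ts in self.terms.items() if term_id in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out


def parse_annotation_map(path: str | Path) -> AnnotationMap:
    """Read a 2/3-column TSV (feature, term[, label]); duplicate lines are
    idempotent (set semantics)."""
    amap = AnnotationMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise TillermirError(f"{path}:{lineno}: malformed annotation line {line!r}")
            amap.add(parts[0], parts[1], parts[2] if len(parts) > 2 else None)
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for feature in sorted(amap.terms):
            for term in sorted(amap.terms[feature]):
                label = amap.labels.get(term, "")
                if label:
                    fh.write(f"{feature}\t{term}\t{label}\n")
                else:
                    fh.write(f"{feature}\t{term}\n")


def read_id_list(path: str | Path) -> set[str]:
    """One id per line (e.g. a transcription-factor list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def make_design(
    tissues: Sequence[str] = TISSUES, replicates: int = 3
) -> pd.DataFrame:
    """The standard 3-tissue x r-replicate design, sample ids '<tissue>_r<i>'."""
    rows = [
        (f"{t}_r{i}", t, i) for t in tissues for i in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "replicate"]).set_index(
        "sample_id"
    )
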