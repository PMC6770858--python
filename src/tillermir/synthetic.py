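"""Synthetic sequences, expression matrices, and ground-truth manifests.

The generator emulates the three-tissue (TP, ST, YS) x three-replicate
bulk design the pipeline targets, with known structure planted on top of
null features:

* tissue-specific genes with a chosen mean-ratio over the other tissues;
* differentially expressed features with a chosen true log2 fold change,
  applied as symmetric multiplicative shifts to the two compared tissues;
* miRNA target sites embedded in transcripts as the reverse complement of
  the miRNA carrying an exact, chosen penalty budget of mismatches and
  G:U wobbles;
* negative miRNA-mRNA pairs that satisfy all four network admission
  conditions, plus decoy pairs violating exactly one condition each.

Replicate noise is multiplicative lognormal (positive support, like
FPKM/TPM data). All randomness flows from one seed through named
substreams, and identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    ExpressionMatrix,
    MirnaRecord,
    SequenceRecord,
    TISSUES,
    TillermirError,
    make_design,
    write_annotation_map,
    write_fasta,
)
from .targetscan import (
    SCORE_THRESHOLD,
    classify_pair,
    reverse_complement,
    scan_targets,
)

DEFAULT_MIRNA_LENGTH_WEIGHTS = {21: 0.43, 24: 0.37}
# remaining mass is spread uniformly over the other valid lengths (18-30)

_BASES = np.array(list("ACGU"))


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG stream of the master seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTs:
    feature_id: str
    tissue: str
    ratio: float


@dataclass(frozen=True)
class PlantedDe:
    feature_id: str
    group_a: str
    group_b: str
    log2fc: float  # true log2(mean_b / mean_a)


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    transcript_id: str
    site_start: int
    budget: float  # engineered penalty (half-integer)


@dataclass(frozen=True)
class PlantedPair:
    mirna_id: str
    gene_id: str


@dataclass(frozen=True)
class Decoy:
    mirna_id: str
    gene_id: str
    violated: str  # 'direction' | 'gene_not_de' | 'mirna_fc' | 'site_score'


@dataclass
class SyntheticTruth:
    """Manifest of everything the generator planted, for recovery tests."""

    seed: int
    ts_genes: list[PlantedTs] = field(default_factory=list)
    de_genes: list[PlantedDe] = field(default_factory=list)
    de_mirnas: list[PlantedDe] = field(default_factory=list)
    target_sites: list[PlantedSite] = field(default_factory=list)
    negative_pairs: list[PlantedPair] = field(default_factory=list)
    decoys: list[Decoy] = field(default_factory=list)
    params: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """TSV sections, one '#section' header line per section."""
        with open(path, "w") as fh:
            fh.write("#section\tts_genes\nfeature_id\ttissue\tratio\n")
            for t in self.ts_genes:
                fh.write(f"{t.feature_id}\t{t.tissue}\t{t.ratio}\n")
            for name, items in (("de_genes", self.de_genes), ("de_mirnas", self.de_mirnas)):
                fh.write(f"#section\t{name}\nfeature_id\tgroup_a\tgroup_b\tlog2fc\n")
                for d in items:
                    fh.write(f"{d.feature_id}\t{d.group_a}\t{d.group_b}\t{d.log2fc}\n")
            fh.write("#section\ttarget_sites\nmirna_id\ttranscript_id\tsite_start\tbudget\n")
            for s in self.target_sites:
                fh.write(f"{s.mirna_id}\t{s.transcript_id}\t{s.site_start}\t{s.budget}\n")
            fh.write("#section\tnegative_pairs\nmirna_id\tgene_id\n")
            for p in self.negative_pairs:
                fh.write(f"{p.mirna_id}\t{p.gene_id}\n")
            fh.write("#section\tdecoys\nmirna_id\tgene_id\tviolated\n")
            for d in self.decoys:
                fh.write(f"{d.mirna_id}\t{d.gene_id}\t{d.violated}\n")
            fh.write("#section\tparams\nkey\tvalue\n")
            fh.write(f"seed\t{self.seed}\n")
            for k in sorted(self.params):
                fh.write(f"{k}\t{self.params[k]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticTruth":
        sections: dict[str, list[list[str]]] = {}
        current: list[list[str]] | None = None
        expect_header = False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#section\t"):
                    name = line.split("\t", 1)[1]
                    current = sections.setdefault(name, [])
                    expect_header = True
                    continue
                if expect_header:
                    expect_header = False  # column header line
                    continue
                assert current is not None, f"data before any section in {path}"
                current.append(line.split("\t"))
        truth = cls(seed=0)
        for r in sections.get("ts_genes", []):
            truth.ts_genes.append(PlantedTs(r[0], r[1], float(r[2])))
        for r in sections.get("de_genes", []):
            truth.de_genes.append(PlantedDe(r[0], r[1], r[2], float(r[3])))
        for r in sections.get("de_mirnas", []):
            truth.de_mirnas.append(PlantedDe(r[0], r[1], r[2], float(r[3])))
        for r in sections.get("target_sites", []):
            truth.target_sites.append(PlantedSite(r[0], r[1], int(r[2]), float(r[3])))
        for r in sections.get("negative_pairs", []):
            truth.negative_pairs.append(PlantedPair(r[0], r[1]))
        for r in sections.get("decoys", []):
            truth.decoys.append(Decoy(r[0], r[1], r[2]))
        for r in sections.get("params", []):
            if r[0] == "seed":
                truth.seed = int(r[1])
            else:
                truth.params[r[0]] = r[1]
        return truth


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def sample_mirna_lengths(
    n: int,
    rng: np.random.Generator,
    weights: Mapping[int, float] | None = None,
) -> np.ndarray:
    """Draw miRNA lengths from the stated mixture; the unassigned mass is
    uniform over the remaining 18-30 nt lengths."""
    weights = dict(weights or DEFAULT_MIRNA_LENGTH_WEIGHTS)
    for length in weights:
        if not (18 <= length <= 30):
            raise TillermirError(f"miRNA length {length} outside 18-30 nt")
    rest = 1.0 - sum(weights.values())
    if rest < -1e-9:
        raise TillermirError("miRNA length weights sum to more than 1")
    others = [l for l in range(18, 31) if l not in weights]
    lengths = list(weights) + others
    probs = list(weights.values()) + [max(rest, 0.0) / len(others)] * len(others)
    probs = np.asarray(probs) / np.sum(probs)
    return rng.choice(np.asarray(lengths), size=n, p=probs)


def generate_sequences(
    n_transcripts: int,
    transcript_len: tuple[int, int] = (250, 500),
    n_mirnas: int = 40,
    mirna_lengths: Mapping[int, float] | None = None,
    seed: int = 0,
    transcript_ids: Sequence[str] | None = None,
    mirna_ids: Sequence[str] | None = None,
) -> tuple[list[SequenceRecord], list[MirnaRecord]]:
    """I.i.d. uniform-ACGU transcripts and miRNAs, reproducible per seed."""
    lo, hi = transcript_len
    if lo < 1 or hi < lo:
        raise TillermirError(f"bad transcript length range {transcript_len}")
    rng = np.random.default_rng(seed)
    if transcript_ids is None:
        transcript_ids = [f"tx{i+1:04d}" for i in range(n_transcripts)]
    if mirna_ids is None:
        mirna_ids = [f"mir{i+1:03d}" for i in range(n_mirnas)]
    transcripts = [
        SequenceRecord(id=tid, seq=_random_seq(rng, int(rng.integers(lo, hi + 1))))
        for tid in transcript_ids
    ]
    lengths = sample_mirna_lengths(len(mirna_ids), rng, mirna_lengths)
    mirnas = [
        MirnaRecord(
            id=mid,
            seq=_random_seq(rng, int(L)),
            origin="known" if rng.random() < 0.2 else "novel",
        )
        for mid, L in zip(mirna_ids, lengths)
    ]
    return transcripts, mirnas


# ---------------------------------------------------------------------------
# Target-site planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSpec:
    """Imperfection recipe for one planted site."""

    mirna_id: str
    transcript_id: str
    position: int  # 0-based site start on the transcript
    n_seed_mismatch: int = 0
    n_nonseed_mismatch: int = 0
    n_seed_wobble: int = 0
    n_nonseed_wobble: int = 0

    def budget(self, double_wobble_in_seed: bool = True) -> float:
        """Engineered penalty under the default scoring switches."""
        wb_seed = 1.0 if double_wobble_in_seed else 0.5
        return (
            2.0 * self.n_seed_mismatch
            + 1.0 * self.n_nonseed_mismatch
            + wb_seed * self.n_seed_wobble
            + 0.5 * self.n_nonseed_wobble
        )


def budget_to_spec_counts(budget: float) -> tuple[int, int, int, int]:
    """A canonical imperfection recipe realizing a half-integer budget with
    non-seed imperfections only (counts: seed mm, non-seed mm, seed wobble,
    non-seed wobble)."""
    half = round(budget * 2)
    if half < 0 or abs(budget * 2 - half) > 1e-9:
        raise TillermirError(f"budget {budget} is not a non-negative half-integer")
    return (0, half // 2, 0, half % 2)


def _build_site(mirna_seq: str, spec: SiteSpec, rng: np.random.Generator) -> str:
    """The reverse complement of the miRNA with exactly the requested
    imperfections at seeded-random eligible positions."""
    L = len(mirna_seq)
    site = list(reverse_complement(mirna_seq))
    seed_pos = [i for i in range(2, 14) if i <= L]
    nonseed_pos = [i for i in range(1, L + 1) if i not in seed_pos]
    rng.shuffle(seed_pos)
    rng.shuffle(nonseed_pos)

    def take(pool: list[int], n: int, wobble: bool, region: str) -> list[int]:
        if wobble:
            eligible = [i for i in pool if mirna_seq[i - 1] in "GU"]
        else:
            eligible = list(pool)
        if len(eligible) < n:
            raise TillermirError(
                f"{spec.mirna_id}: cannot place {n} "
                f"{'wobbles' if wobble else 'mismatches'} in the {region} region"
            )
        chosen = eligible[:n]
        for i in chosen:
            pool.remove(i)
        return chosen

    placements: list[tuple[int, bool]] = []
    placements += [(i, True) for i in take(seed_pos, spec.n_seed_wobble, True, "seed")]
    placements += [(i, False) for i in take(seed_pos, spec.n_seed_mismatch, False, "seed")]
    placements += [(i, True) for i in take(nonseed_pos, spec.n_nonseed_wobble, True, "non-seed")]
    placements += [(i, False) for i in take(nonseed_pos, spec.n_nonseed_mismatch, False, "non-seed")]

    for i, wobble in placements:
        m = mirna_seq[i - 1]
        j = L - i  # site offset pairing miRNA position i
        if wobble:
            site[j] = "U" if m == "G" else "G"
        else:
            choices = [b for b in "ACGU" if classify_pair(m, b) == "mismatch"]
            site[j] = str(rng.choice(choices))
    return "".join(site)


def plant_target_sites(
    transcripts: Sequence[SequenceRecord],
    mirnas: Sequence[MirnaRecord],
    site_specs: Sequence[SiteSpec],
    seed: int = 0,
    max_retries: int = 20,
    score_threshold: float = SCORE_THRESHOLD,
) -> tuple[list[SequenceRecord], list[PlantedSite]]:
    """Embed the requested sites and return modified transcripts plus the
    planted-site truth entries.

    After planting, every supplied miRNA is rescanned against every
    modified transcript; if a chance (unplanted) window scores at or below
    the retention threshold, the transcript's background is re-randomized
    and planting retried, up to `max_retries` times.
    """
    rng = np.random.default_rng(seed)
    mirna_by_id = {m.id: m for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}
    specs_by_tx: dict[str, list[SiteSpec]] = {}
    for s in site_specs:
        if s.mirna_id not in mirna_by_id:
            raise TillermirError(f"site spec references unknown miRNA {s.mirna_id!r}")
        if s.transcript_id not in tx_by_id:
            raise TillermirError(f"site spec references unknown transcript {s.transcript_id!r}")
        L = mirna_by_id[s.mirna_id].length
        tx_len = tx_by_id[s.transcript_id].length
        if not (0 <= s.position <= tx_len - L):
            raise TillermirError(
                f"site for {s.mirna_id} at {s.position} does not fit in "
                f"{s.transcript_id} (len {tx_len})"
            )
        specs_by_tx.setdefault(s.transcript_id, []).append(s)
    for tx_id, specs in specs_by_tx.items():
        spans = sorted(
            (s.position, s.position + mirna_by_id[s.mirna_id].length) for s in specs
        )
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise TillermirError(f"overlapping planted sites on {tx_id}")

    planted: list[PlantedSite] = []
    out: list[SequenceRecord] = []
    for t in transcripts:
        specs = specs_by_tx.get(t.id, [])
        if not specs:
            out.append(t)
            continue
        expected = {
            (s.mirna_id, s.position): s.budget() for s in specs
        }
        seq = t.seq
        for attempt in range(max_retries + 1):
            chars = list(seq)
            for s in specs:
                m = mirna_by_id[s.mirna_id]
                site = _build_site(m.seq, s, rng)
                chars[s.position : s.position + m.length] = site
            candidate = SequenceRecord(id=t.id, seq="".join(chars))
            collision = False
            for m in mirnas:
                for h in scan_targets(m, candidate, max_report_score=score_threshold):
                    key = (h.mirna_id, h.site_start)
                    if key not in expected:
                        collision = True
                        break
                if collision:
                    break
            if not collision:
                out.append(candidate)
                break
            # chance sub-threshold window: re-randomize the background
            site_mask = [False] * t.length
            for s in specs:
                L = mirna_by_id[s.mirna_id].length
                for j in range(s.position, s.position + L):
                    site_mask[j] = True
            seq = "".join(
                c if site_mask[j] else _random_seq(rng, 1)
                for j, c in enumerate(t.seq)
            )
        else:
            raise TillermirError(
                f"could not plant sites on {t.id} without chance hits after "
                f"{max_retries} retries"
            )
        for s in specs:
            planted.append(
                PlantedSite(
                    mirna_id=s.mirna_id,
                    transcript_id=s.transcript_id,
                    site_start=s.position,
                    budget=s.budget(),
                )
            )
    return out, planted


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

def generate_expression(
    feature_ids: Sequence[str],
    planted_ts: Sequence[PlantedTs] = (),
    planted_de: Sequence[PlantedDe] = (),
    replicates: int = 3,
    noise_sd: float = 0.15,
    baseline_log_mean: float = math.log(50.0),
    baseline_sigma: float = 1.0,
    baseline_overrides: Mapping[str, float] | None = None,
    unit: str = "FPKM",
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Three-tissue x r-replicate matrix with planted structure.

    Baseline means are lognormal; tissue effects apply multiplicatively: a
    tissue-specific spec multiplies its tissue by `ratio`, and a DE spec
    with true log2FC f multiplies group_b by 2^(f/2) and group_a by
    2^(-f/2) (the third tissue stays at baseline). Replicate values are
    tissue mean x lognormal(0, noise_sd). Multiple DE specs for a feature
    compose multiplicatively; two TS specs for one feature is an error.
    """
    if replicates < 2:
        raise TillermirError("need >= 2 replicates per tissue")
    seen_ts: dict[str, str] = {}
    for t in planted_ts:
        if t.feature_id in seen_ts:
            raise TillermirError(
                f"{t.feature_id} is tissue-specific for both "
                f"{seen_ts[t.feature_id]} and {t.tissue}"
            )
        if t.tissue not in TISSUES:
            raise TillermirError(f"unknown tissue {t.tissue!r}")
        if not (math.isfinite(t.ratio) and t.ratio > 0):
            raise TillermirError(f"{t.feature_id}: bad ratio {t.ratio}")
        seen_ts[t.feature_id] = t.tissue
    seen_de: set[tuple[str, str, str]] = set()
    for d in planted_de:
        key = (d.feature_id, d.group_a, d.group_b)
        if key in seen_de:
            raise TillermirError(f"duplicate DE spec for {key}")
        if not math.isfinite(d.log2fc):
            raise TillermirError(f"{d.feature_id}: non-finite log2fc")
        seen_de.add(key)

    rng = np.random.default_rng(seed)
    ids = list(feature_ids)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_sigma, size=len(ids)))
    if baseline_overrides:
        for i, fid in enumerate(ids):
            if fid in baseline_overrides:
                baseline[i] = baseline_overrides[fid]

    mult = pd.DataFrame(1.0, index=ids, columns=list(TISSUES))
    for t in planted_ts:
        mult.loc[t.feature_id, t.tissue] *= t.ratio
    for d in planted_de:
        mult.loc[d.feature_id, d.group_b] *= 2.0 ** (d.log2fc / 2.0)
        mult.loc[d.feature_id, d.group_a] *= 2.0 ** (-d.log2fc / 2.0)

    design = make_design(replicates=replicates)
    cols = {}
    for sample_id, row in design.iterrows():
        tissue_mean = baseline * mult[row["tissue"]].to_numpy()
        noise = (
            np.exp(rng.normal(0.0, noise_sd, size=len(ids)))
            if noise_sd > 0
            else np.ones(len(ids))
        )
        cols[sample_id] = tissue_mean * noise
    values = pd.DataFrame(cols, index=ids)
    matrix = ExpressionMatrix(values=values, design=design, unit=unit)
    truth = SyntheticTruth(
        seed=seed,
        ts_genes=list(planted_ts),
        de_genes=list(planted_de),
        params={"noise_sd": str(noise_sd), "replicates": str(replicates)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Study conditions for the full synthetic dataset.

    Sizes are desk-scale stand-ins for the real design; noise_sd 0.15 is a
    typical replicate coefficient of variation for well-behaved bulk
    RNA-seq. Planted fold changes sit well past the pipeline thresholds
    because the features the method is meant to recover (miRNA targets,
    trend genes) show large tissue contrasts in this system.
    """

    n_genes: int = 300
    transcript_len: tuple[int, int] = (250, 500)
    n_mirnas: int = 40
    replicates: int = 3
    noise_sd: float = 0.15
    n_ts_per_tissue: int = 4
    ts_ratio: float = 5.0
    n_trend_genes_per_shape: int = 10
    trend_lfc: float = 4.0
    n_pairs: int = 8
    pair_gene_lfc: float = 4.0
    pair_mirna_lfc: float = 3.5
    pair_budgets: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
    decoy_site_budget: float = 4.0
    decoy_mirna_lfc: float = 1.2  # linear FC ~2.3, safely <= the FC>4 gate
    n_tf: int = 30
    n_terms: int = 10
    gene_baseline_log_mean: float = math.log(20.0)
    gene_baseline_sigma: float = 1.5  # leaves a low-expression tail below FPKM 1
    mirna_baseline_log_mean: float = math.log(300.0)
    mirna_baseline_sigma: float = 0.8


# the six trend archetypes over (TP, ST, YS): which tissues are high
_TREND_SHAPES = (
    ("TP",), ("ST",), ("YS",), ("TP", "ST"), ("TP", "YS"), ("ST", "YS"),
)


@dataclass
class SyntheticDataset:
    """In-memory handle on a generated dataset plus its truth manifest."""

    transcripts: list[SequenceRecord]
    mirnas: list[MirnaRecord]
    gene_matrix: ExpressionMatrix  # FPKM
    mirna_matrix: ExpressionMatrix  # raw counts
    annotations: AnnotationMap
    tf_list: set[str]
    truth: SyntheticTruth


def generate_full_dataset(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate mutually consistent sequences, matrices, annotation map,
    TF list, and truth manifest; optionally write everything under outdir.

    Planted negative pairs satisfy all four network admission conditions;
    each decoy violates exactly one (opposite-direction, gene-DE,
    miRNA FC>4, site score<4 respectively).
    """
    cfg = config or GeneratorConfig()
    n_structured_genes = (
        3 * cfg.n_ts_per_tissue
        + len(_TREND_SHAPES) * cfg.n_trend_genes_per_shape
        + cfg.n_pairs
        + 4
    )
    if cfg.n_genes < n_structured_genes:
        raise TillermirError(
            f"n_genes={cfg.n_genes} too small for {n_structured_genes} structured genes"
        )
    n_structured_mirnas = cfg.n_pairs + 4
    if cfg.n_mirnas < n_structured_mirnas:
        raise TillermirError(
            f"n_mirnas={cfg.n_mirnas} too small for {n_structured_mirnas} structured miRNAs"
        )
    if len(cfg.pair_budgets) != cfg.n_pairs:
        raise TillermirError("pair_budgets must have one budget per planted pair")
    if max(cfg.pair_budgets) >= SCORE_THRESHOLD:
        raise TillermirError("planted pair budgets must be below the retention threshold")

    # --- ids ---------------------------------------------------------------
    ts_ids = [
        f"g_ts_{t}_{i+1}" for t in TISSUES for i in range(cfg.n_ts_per_tissue)
    ]
    trend_ids = [
        f"g_trend_{''.join(shape)}_{i+1}"
        for shape in _TREND_SHAPES
        for i in range(cfg.n_trend_genes_per_shape)
    ]
    pair_gene_ids = [f"g_pair_{i+1}" for i in range(cfg.n_pairs)]
    decoy_kinds = ("direction", "gene_not_de", "mirna_fc", "site_score")
    decoy_gene_ids = {k: f"g_dec_{k}" for k in decoy_kinds}
    n_null_genes = cfg.n_genes - n_structured_genes
    null_gene_ids = [f"g_null_{i+1}" for i in range(n_null_genes)]
    gene_ids = ts_ids + trend_ids + pair_gene_ids + list(decoy_gene_ids.values()) + null_gene_ids

    pair_mirna_ids = [f"mir_pair_{i+1}" for i in range(cfg.n_pairs)]
    decoy_mirna_ids = {k: f"mir_dec_{k}" for k in decoy_kinds}
    n_null_mirnas = cfg.n_mirnas - n_structured_mirnas
    null_mirna_ids = [f"mir_null_{i+1}" for i in range(n_null_mirnas)]
    mirna_ids = pair_mirna_ids + list(decoy_mirna_ids.values()) + null_mirna_ids

    # --- sequences (transcript ids are gene ids: identity gene map) --------
    seq_rng_seed = substream(seed, "sequences").integers(2**31)
    transcripts, mirnas = generate_sequences(
        n_transcripts=len(gene_ids),
        transcript_len=cfg.transcript_len,
        n_mirnas=len(mirna_ids),
        seed=int(seq_rng_seed),
        transcript_ids=gene_ids,
        mirna_ids=mirna_ids,
    )
    mirna_by_id = {m.id: m for m in mirnas}
    tx_by_id = {t.id: t for t in transcripts}

    # --- target sites ------------------------------------------------------
    site_rng = substream(seed, "sites")
    site_specs: list[SiteSpec] = []

    def make_spec(mirna_id: str, gene_id: str, budget: float) -> SiteSpec:
        sm, nm, sw, nw = budget_to_spec_counts(budget)
        L = mirna_by_id[mirna_id].length
        tx_len = tx_by_id[gene_id].length
        pos = int(site_rng.integers(0, tx_len - L + 1))
        return SiteSpec(
            mirna_id=mirna_id,
            transcript_id=gene_id,
            position=pos,
            n_seed_mismatch=sm,
            n_nonseed_mismatch=nm,
            n_seed_wobble=sw,
            n_nonseed_wobble=nw,
        )

    for mid, gid, budget in zip(pair_mirna_ids, pair_gene_ids, cfg.pair_budgets):
        site_specs.append(make_spec(mid, gid, budget))
    for kind in decoy_kinds:
        budget = cfg.decoy_site_budget if kind == "site_score" else 1.0
        site_specs.append(make_spec(decoy_mirna_ids[kind], decoy_gene_ids[kind], budget))

    transcripts, planted_sites = plant_target_sites(
        transcripts,
        mirnas,
        site_specs,
        seed=int(substream(seed, "plant").integers(2**31)),
    )

    # --- gene expression ---------------------------------------------------
    planted_ts = [
        PlantedTs(fid, t, cfg.ts_ratio)
        for t in TISSUES
        for fid in ts_ids
        if fid.startswith(f"g_ts_{t}_")
    ]
    gene_de: list[PlantedDe] = []
    idx = 0
    for shape in _TREND_SHAPES:
        for _ in range(cfg.n_trend_genes_per_shape):
            fid = trend_ids[idx]
            idx += 1
            # realize the shape as composed pairwise DE effects
            for high in shape:
                for low in (t for t in TISSUES if t not in shape):
                    a, b = sorted((high, low), key=TISSUES.index)
                    sign = 1.0 if b == high else -1.0
                    gene_de.append(PlantedDe(fid, a, b, sign * cfg.trend_lfc))
    # pair genes alternate direction between TP and YS
    pair_gene_signs = [1 if i % 2 == 0 else -1 for i in range(cfg.n_pairs)]
    for gid, s in zip(pair_gene_ids, pair_gene_signs):
        gene_de.append(PlantedDe(gid, "TP", "YS", s * cfg.pair_gene_lfc))
    # decoy genes: direction decoy matches its miRNA's sign; not-DE decoy is
    # sub-threshold; the other two are ordinary strong DE genes
    gene_de.append(PlantedDe(decoy_gene_ids["direction"], "TP", "YS", cfg.pair_gene_lfc))
    gene_de.append(PlantedDe(decoy_gene_ids["gene_not_de"], "TP", "YS", -0.3))
    gene_de.append(PlantedDe(decoy_gene_ids["mirna_fc"], "TP", "YS", -cfg.pair_gene_lfc))
    gene_de.append(PlantedDe(decoy_gene_ids["site_score"], "TP", "YS", -cfg.pair_gene_lfc))

    structured_gene_ids = set(ts_ids + trend_ids + pair_gene_ids + list(decoy_gene_ids.values()))
    overrides_rng = substream(seed, "baselines")
    gene_overrides = {
        fid: float(np.exp(overrides_rng.normal(math.log(80.0), 0.3)))
        for fid in gene_ids
        if fid in structured_gene_ids
    }
    gene_matrix, _ = generate_expression(
        gene_ids,
        planted_ts=planted_ts,
        planted_de=gene_de,
        replicates=cfg.replicates,
        noise_sd=cfg.noise_sd,
        baseline_log_mean=cfg.gene_baseline_log_mean,
        baseline_sigma=cfg.gene_baseline_sigma,
        baseline_overrides=gene_overrides,
        unit="FPKM",
        seed=int(substream(seed, "gene_expr").integers(2**31)),
    )

    # --- miRNA expression (raw counts; miRNA direction opposes its gene) ---
    mirna_de: list[PlantedDe] = []
    for mid, s in zip(pair_mirna_ids, pair_gene_signs):
        mirna_de.append(PlantedDe(mid, "TP", "YS", -s * cfg.pair_mirna_lfc))
    mirna_de.append(PlantedDe(decoy_mirna_ids["direction"], "TP", "YS", cfg.pair_mirna_lfc))
    mirna_de.append(PlantedDe(decoy_mirna_ids["gene_not_de"], "TP", "YS", cfg.pair_mirna_lfc))
    mirna_de.append(PlantedDe(decoy_mirna_ids["mirna_fc"], "TP", "YS", cfg.decoy_mirna_lfc))
    mirna_de.append(PlantedDe(decoy_mirna_ids["site_score"], "TP", "YS", cfg.pair_mirna_lfc))
    mirna_abund, _ = generate_expression(
        mirna_ids,
        planted_de=mirna_de,
        replicates=cfg.replicates,
        noise_sd=cfg.noise_sd,
        baseline_log_mean=cfg.mirna_baseline_log_mean,
        baseline_sigma=cfg.mirna_baseline_sigma,
        unit="counts",
        seed=int(substream(seed, "mirna_expr").integers(2**31)),
    )
    mirna_counts = ExpressionMatrix(
        values=np.rint(mirna_abund.values).clip(lower=0.0),
        design=mirna_abund.design.copy(),
        unit="counts",
    )

    # --- annotations and TF list -------------------------------------------
    annot_rng = substream(seed, "annotations")
    annotations = AnnotationMap()
    terms = [f"T{i+1:02d}" for i in range(cfg.n_terms)]
    for fid in gene_ids:
        for term in annot_rng.choice(terms, size=int(annot_rng.integers(1, 4)), replace=False):
            annotations.add(fid, str(term), f"synthetic term {term}")

    tf_rng = substream(seed, "tf")
    tf_list = {pair_gene_ids[0]}
    tf_list |= set(tf_rng.choice(gene_ids, size=cfg.n_tf, replace=False).tolist())

    truth = SyntheticTruth(
        seed=seed,
        ts_genes=planted_ts,
        de_genes=gene_de,
        de_mirnas=mirna_de,
        target_sites=planted_sites,
        negative_pairs=[PlantedPair(m, g) for m, g in zip(pair_mirna_ids, pair_gene_ids)],
        decoys=[Decoy(decoy_mirna_ids[k], decoy_gene_ids[k], k) for k in decoy_kinds],
        params={k: str(v) for k, v in asdict(cfg).items()},
    )

    dataset = SyntheticDataset(
        transcripts=transcripts,
        mirnas=mirnas,
        gene_matrix=gene_matrix,
        mirna_matrix=mirna_counts,
        annotations=annotations,
        tf_list=tf_list,
        truth=truth,
    )
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every component in the formats the readers understand."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "mirnas": outdir / "mirnas.fasta",
        "gene_matrix": outdir / "gene_fpkm.tsv",
        "gene_design": outdir / "gene_design.tsv",
        "mirna_matrix": outdir / "mirna_counts.tsv",
        "mirna_design": outdir / "mirna_design.tsv",
        "annotations": outdir / "annotations.tsv",
        "tf_list": outdir / "tf_list.txt",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(dataset.transcripts, paths["transcripts"])
    write_fasta(dataset.mirnas, paths["mirnas"])
    dataset.gene_matrix.write(paths["gene_matrix"], paths["gene_design"])
    dataset.mirna_matrix.write(paths["mirna_matrix"], paths["mirna_design"])
    write_annotation_map(dataset.annotations, paths["annotations"])
    with open(paths["tf_list"], "w") as fh:
        for gid in sorted(dataset.tf_list):
            fh.write(gid + "\n")
    dataset.truth.save(paths["truth"])
    return paths
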