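"""Plant miRNA target prediction by position-weighted penalty scoring.

An ungapped complementarity scan in the TargetFinder tradition: every
window of the transcript the length of the miRNA is aligned antiparallel
against the miRNA and scored per base pair — 0 for a Watson-Crick match,
0.5 for a G:U wobble, 1 for a mismatch — with the penalty doubled when the
imperfection falls in the miRNA seed region, positions 2-13 counting from
the miRNA 5' end. Candidate target sites with a total score strictly below
4 are retained.

Scores are half-integers and are carried internally as integer half-points,
so threshold comparisons are exact. Whether the seed doubling applies to
G:U wobbles as well as true mismatches is a documented switch
(`double_wobble_in_seed`, default True, the TargetFinder-style reading).

Pairing convention: miRNA position i (1-based from its 5' end) pairs with
site position L - i + 1, the site being read 5'->3' on the transcript
sense strand. Site coordinates are 0-based half-open on the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MirnaRecord, SequenceRecord, TillermirError, normalize_sequence

SEED_LO = 2
SEED_HI = 13
SCORE_THRESHOLD = 4.0

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_STATE_SYMBOL = {"match": "=", "wobble": "W", "mismatch": "M"}

# half-point penalty lookup, rows = miRNA base, cols = target base
# (A,C,G,U): match 0, wobble 1 (= 0.5), mismatch 2 (= 1.0)
_PENALTY_HALF = np.full((4, 4), 2, dtype=np.int64)
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PENALTY_HALF[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0
for _m, _t in (("G", "U"), ("U", "G")):
    _PENALTY_HALF[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 1


def reverse_complement(seq: str) -> str:
    """Reverse complement on the RNA alphabet (A<->U, G<->C)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise TillermirError(f"invalid RNA base {exc.args[0]!r}") from None


def classify_pair(mirna_base: str, target_base: str) -> str:
    """'match' for Watson-Crick pairs, 'wobble' for G:U / U:G, else
    'mismatch'."""
    for b in (mirna_base, target_base):
        if b not in _COMPLEMENT:
            raise TillermirError(f"invalid RNA base {b!r}")
    half = _PENALTY_HALF[_BASE_INDEX[mirna_base], _BASE_INDEX[target_base]]
    return ("match", "wobble", "mismatch")[half]


@dataclass(frozen=True)
class DuplexHit:
    """One miRNA-vs-transcript-window alignment."""

    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript sense strand
    site_len: int
    pair_states: tuple[str, ...]  # per miRNA position 1..L
    score_half: int  # penalty in half-points (exact)
    retained: bool = False

    @property
    def score(self) -> float:
        return self.score_half / 2.0

    @property
    def site_end(self) -> int:
        return self.site_start + self.site_len

    @property
    def pair_state_string(self) -> str:
        """Compact per-position string, e.g. '===W==M...' (miRNA 5'->3')."""
        return "".join(_STATE_SYMBOL[s] for s in self.pair_states)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


def _seed_weights(length: int, seed_lo: int, seed_hi: int) -> np.ndarray:
    """Doubling weight per site offset j (site 5'->3'): site position j+1
    pairs miRNA position L - j."""
    mirna_pos = length - np.arange(length)  # 1-based miRNA position per offset
    return np.where((mirna_pos >= seed_lo) & (mirna_pos <= seed_hi), 2, 1).astype(np.int64)


def score_duplex(
    mirna: MirnaRecord | str,
    site: str,
    seed_lo: int = SEED_LO,
    seed_hi: int = SEED_HI,
    double_wobble_in_seed: bool = True,
) -> tuple[float, tuple[str, ...]]:
    """Score one miRNA/site duplex; returns (score, per-position states).

    `site` is the target window read 5'->3' on the transcript and must have
    the miRNA's length. States are reported per miRNA position 1..L.
    """
    mseq = mirna.seq if isinstance(mirna, MirnaRecord) else normalize_sequence(mirna)
    site = normalize_sequence(site, context="site")
    if len(site) != len(mseq):
        raise TillermirError(
            f"site length {len(site)} != miRNA length {len(mseq)}"
        )
    L = len(mseq)
    states: list[str] = []
    half_total = 0
    for i in range(1, L + 1):  # miRNA position, 1-based from 5' end
        m = mseq[i - 1]
        t = site[L - i]  # antiparallel partner
        state = classify_pair(m, t)
        states.append(state)
        half = {"match": 0, "wobble": 1, "mismatch": 2}[state]
        in_seed = seed_lo <= i <= seed_hi
        if in_seed and (state == "mismatch" or (state == "wobble" and double_wobble_in_seed)):
            half *= 2
        half_total += half
    return half_total / 2.0, tuple(states)


def scan_targets(
    mirna: MirnaRecord,
    transcript: SequenceRecord,
    max_report_score: float = SCORE_THRESHOLD,
    seed_lo: int = SEED_LO,
    seed_hi: int = SEED_HI,
    double_wobble_in_seed: bool = True,
) -> list[DuplexHit]:
    """Score every length-L window of the transcript against the miRNA.

    Hits with score <= max_report_score are returned sorted by
    (score asc, site_start asc); overlaps are allowed at this stage. A
    transcript shorter than the miRNA yields an empty list.
    """
    L = mirna.length
    if transcript.length < L:
        return []
    t_idx = _encode(transcript.seq)
    m_rev = _encode(mirna.seq)[::-1]  # offset j pairs miRNA index L-1-j
    windows = np.lib.stride_tricks.sliding_window_view(t_idx, L)
    half = _PENALTY_HALF[m_rev[np.newaxis, :], windows]
    weights = _seed_weights(L, seed_lo, seed_hi)
    if double_wobble_in_seed:
        weighted = half * weights[np.newaxis, :]
    else:
        # double only true mismatches (half == 2) in the seed
        weighted = np.where(half == 2, half * weights[np.newaxis, :], half)
    scores_half = weighted.sum(axis=1)
    max_half = int(round(max_report_score * 2))
    hits: list[DuplexHit] = []
    for start in np.nonzero(scores_half <= max_half)[0]:
        score, states = score_duplex(
            mirna,
            transcript.seq[start : start + L],
            seed_lo=seed_lo,
            seed_hi=seed_hi,
            double_wobble_in_seed=double_wobble_in_seed,
        )
        hits.append(
            DuplexHit(
                mirna_id=mirna.id,
                transcript_id=transcript.id,
                site_start=int(start),
                site_len=L,
                pair_states=states,
                score_half=int(scores_half[start]),
            )
        )
    hits.sort(key=lambda h: (h.score_half, h.site_start))
    return hits


def scan_many(
    mirnas: Iterable[MirnaRecord],
    transcripts: Sequence[SequenceRecord],
    max_report_score: float = SCORE_THRESHOLD,
    **kwargs,
) -> list[DuplexHit]:
    """Scan every miRNA against every transcript."""
    hits: list[DuplexHit] = []
    for m in mirnas:
        for t in transcripts:
            hits.extend(scan_targets(m, t, max_report_score=max_report_score, **kwargs))
    return hits


def filter_hits(
    hits: Iterable[DuplexHit],
    threshold: float = SCORE_THRESHOLD,
    best_per_pair: bool = True,
) -> list[DuplexHit]:
    """Retain hits scoring strictly below `threshold`; with best_per_pair,
    keep only the minimum-score hit per (miRNA, transcript) pair, ties
    resolved toward the smallest site_start."""
    if threshold <= 0:
        raise TillermirError("threshold must be > 0")
    threshold_half = int(round(threshold * 2))
    passing = [h for h in hits if h.score_half < threshold_half]
    if best_per_pair:
        best: dict[tuple[str, str], DuplexHit] = {}
        for h in passing:
            key = (h.mirna_id, h.transcript_id)
            cur = best.get(key)
            if cur is None or (h.score_half, h.site_start) < (cur.score_half, cur.site_start):
                best[key] = h
        passing = sorted(best.values(), key=lambda h: (h.mirna_id, h.transcript_id))
    return [replace(h, retained=True) for h in passing]


def hits_to_frame(hits: Iterable[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.mirna_id, h.transcript_id, h.site_start, h.site_end, h.score,
             h.pair_state_string, h.retained)
            for h in hits
        ],
        columns=["mirna_id", "transcript_id", "site_start", "site_end", "score",
                 "pair_states", "retained"],
    )


def write_hits_table(hits: Iterable[DuplexHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, lineterminator="\n")
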