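"""Cross-species equivalence of skipped-exon events by exon-triplet alignment.

For each ortholog gene pair, every unique skipped-exon event of one species
is compared with every event of the other: the three exon sequences
(target, 5'-adjacent, 3'-adjacent, in transcribed orientation) are globally
aligned type-against-type, and a pair is eligible when all three alignments
reach ≥ 70% identity.  Eligible pairs are then accepted greedily by total
alignment score, removing both events after each acceptance and repeating
until no eligible pair remains — so a gene with several regulated exons can
contribute several equivalent event pairs.

The aligner is a Needleman–Wunsch/Gotoh global alignment with affine gaps:
a gap of length L costs ``gap_open + L * gap_extend``.  Traceback ties are
resolved deterministically (diagonal, then up, then left); identity is
matched columns over total alignment columns, and ``N`` never counts as a
match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diff_events import EventKey, MasterRecord
from .io_tables import GenomeSource, HomologPair, fetch_sequence, write_tsv

logger = logging.getLogger(__name__)

try:  # optional JIT; the pure-Python kernel is the same code
    from numba import njit
except ImportError:  # pragma: no cover - numba is normally present
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_NEG_INF = -1e30
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ExonTripletSeqs:
    """The three exon sequences of one event, in transcribed orientation."""

    target_seq: str
    fiveprime_adjacent_seq: str
    threeprime_adjacent_seq: str

    def __post_init__(self) -> None:
        for name, seq in (
            ("target", self.target_seq),
            ("5'-adjacent", self.fiveprime_adjacent_seq),
            ("3'-adjacent", self.threeprime_adjacent_seq),
        ):
            if not seq:
                raise ValueError(f"{name} exon sequence is empty")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and the identity acceptance threshold.

    ``identity_mode`` selects the identity denominator: total alignment
    columns (default) or the shorter sequence length.
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    identity_threshold: float = 0.70
    identity_mode: str = "columns"

    def __post_init__(self) -> None:
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be ≤ 0")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.identity_mode not in ("columns", "shorter"):
            raise ValueError("identity_mode must be 'columns' or 'shorter'")


@dataclass(frozen=True)
class PairScore:
    """Per-exon alignment scores/identities of one candidate event pair."""

    scores: tuple[float, float, float]        # target, 5', 3'
    identities: tuple[float, float, float]
    eligible: bool

    @property
    def total_score(self) -> float:
        return sum(self.scores)


@dataclass(frozen=True)
class EventMatch:
    """An accepted cross-species equivalence between two events."""

    event_key_a: EventKey
    event_key_b: EventKey
    pair_score: PairScore
    match_round: int


# ---------------------------------------------------------------------------
# Gotoh global alignment with deterministic traceback
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gotoh_kernel(a, b, match, mismatch, gap_open, gap_extend):
    """Returns (score, matched_columns, total_columns).

    Three-state affine DP (M = diagonal end, X = gap in b / 'up',
    Y = gap in a / 'left'); on every tie the preference is M, then X,
    then Y.  A gap of length L costs gap_open + L*gap_extend.  Code 4 (N)
    mismatches everything, including itself.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    # traceback: state provenance per cell, 0=M 1=X 2=Y, -1 unset
    tb_m = np.full((n + 1, m + 1), -1, dtype=np.int8)
    tb_x = np.full((n + 1, m + 1), -1, dtype=np.int8)
    tb_y = np.full((n + 1, m + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + i * gap_extend
        tb_x[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Y[0, j] = gap_open + j * gap_extend
        tb_y[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # diagonal
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            best = M[i - 1, j - 1]
            prov = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                prov = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                prov = 2
            M[i, j] = best + s
            tb_m[i, j] = prov
            # up: consume a[i-1] against a gap
            best = M[i - 1, j] + gap_open + gap_extend
            prov = 0
            cand = X[i - 1, j] + gap_extend
            if cand > best:
                best = cand
                prov = 1
            cand = Y[i - 1, j] + gap_open + gap_extend
            if cand > best:
                best = cand
                prov = 2
            X[i, j] = best
            tb_x[i, j] = prov
            # left: consume b[j-1] against a gap
            best = M[i, j - 1] + gap_open + gap_extend
            prov = 0
            cand = X[i, j - 1] + gap_open + gap_extend
            if cand > best:
                best = cand
                prov = 1
            cand = Y[i, j - 1] + gap_extend
            if cand > best:
                best = cand
                prov = 2
            Y[i, j] = best
            tb_y[i, j] = prov
    # end state: prefer M, then X, then Y
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    # traceback, counting columns and matched columns
    i, j = n, m
    matched = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == 0:
            prov = tb_m[i, j]
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matched += 1
            i -= 1
            j -= 1
        elif state == 1:
            prov = tb_x[i, j]
            i -= 1
        else:
            prov = tb_y[i, j]
            j -= 1
        state = prov
    return score, matched, columns


def _encode(seq: str) -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq):
        codes[i] = _CODE.get(ch, 4)
    return codes


def global_align(a: str, b: str,
                 params: AlignmentParams | None = None
                 ) -> tuple[float, float]:
    """Global affine-gap alignment; returns ``(score, identity)``.

    Identity is the fraction of matched columns (equal symbols, neither a
    gap nor N) over total alignment columns (or over the shorter sequence
    length under ``identity_mode='shorter'``).
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    score, matched, columns = _gotoh_kernel(
        _encode(a.upper()), _encode(b.upper()),
        params.match_score, params.mismatch_score,
        params.gap_open, params.gap_extend,
    )
    if params.identity_mode == "columns":
        identity = matched / columns
    else:
        identity = matched / min(len(a), len(b))
    return float(score), float(identity)


# ---------------------------------------------------------------------------
# triplet extraction and pair scoring
# ---------------------------------------------------------------------------

def extract_triplet(event: EventKey, genome: GenomeSource
                    ) -> ExonTripletSeqs:
    """Fetch the three exon sequences of one event, strand-resolved.

    On the plus strand the genomic-left flank is the 5'-adjacent exon; on
    the minus strand roles swap and every sequence is reverse-complemented.
    """
    try:
        target = fetch_sequence(genome, event.chrom, *event.target,
                                event.strand)
        left = fetch_sequence(genome, event.chrom, *event.left_flank,
                              event.strand)
        right = fetch_sequence(genome, event.chrom, *event.right_flank,
                               event.strand)
    except (KeyError, IndexError) as exc:
        raise type(exc)(f"event {event}: {exc}") from None
    if event.strand == "+":
        five, three = left, right
    else:
        five, three = right, left
    return ExonTripletSeqs(
        target_seq=target,
        fiveprime_adjacent_seq=five,
        threeprime_adjacent_seq=three,
    )


def score_event_pair(ta: ExonTripletSeqs, tb: ExonTripletSeqs,
                     params: AlignmentParams | None = None) -> PairScore:
    """Align same-type exons; eligible iff all three identities ≥ threshold."""
    params = params or AlignmentParams()
    pairs = (
        (ta.target_seq, tb.target_seq),
        (ta.fiveprime_adjacent_seq, tb.fiveprime_adjacent_seq),
        (ta.threeprime_adjacent_seq, tb.threeprime_adjacent_seq),
    )
    scores = []
    identities = []
    for sa, sb in pairs:
        score, ident = global_align(sa, sb, params)
        scores.append(score)
        identities.append(ident)
    eligible = all(i >= params.identity_threshold for i in identities)
    return PairScore(tuple(scores), tuple(identities), eligible)


def match_events_for_gene_pair(
    events_a: Sequence[EventKey],
    events_b: Sequence[EventKey],
    genomes: Mapping[str, GenomeSource],
    params: AlignmentParams | None = None,
    mode: str = "global",
) -> list[EventMatch]:
    """Greedy pairing of one homolog pair's events across species.

    ``mode='global'`` (default): repeatedly accept the eligible pair with
    the highest total score (ties broken by lexicographically smallest key
    pair), remove both events, and repeat.  ``mode='per_event'``: iterate
    species-A events in key order, each claiming its best remaining
    eligible partner (first-come pairing).
    """
    params = params or AlignmentParams()
    if mode not in ("global", "per_event"):
        raise ValueError(f"unknown matching mode {mode!r}")
    events_a = sorted(set(events_a))
    events_b = sorted(set(events_b))
    if not events_a or not events_b:
        return []
    trip_a = {k: extract_triplet(k, genomes[k.species]) for k in events_a}
    trip_b = {k: extract_triplet(k, genomes[k.species]) for k in events_b}
    scored: list[tuple[EventKey, EventKey, PairScore]] = []
    for ka in events_a:
        for kb in events_b:
            ps = score_event_pair(trip_a[ka], trip_b[kb], params)
            if ps.eligible:
                scored.append((ka, kb, ps))
    matches: list[EventMatch] = []
    if mode == "global":
        used_a: set[EventKey] = set()
        used_b: set[EventKey] = set()
        remaining = list(scored)
        round_no = 1
        while remaining:
            best = min(
                remaining,
                key=lambda t: (-t[2].total_score, t[0], t[1]),
            )
            ka, kb, ps = best
            matches.append(EventMatch(ka, kb, ps, round_no))
            used_a.add(ka)
            used_b.add(kb)
            remaining = [
                t for t in remaining
                if t[0] not in used_a and t[1] not in used_b
            ]
            round_no += 1
    else:  # per_event: species-A events claim partners in key order
        by_a: dict[EventKey, list[tuple[EventKey, PairScore]]] = {}
        for ka, kb, ps in scored:
            by_a.setdefault(ka, []).append((kb, ps))
        used_b = set()
        round_no = 1
        for ka in events_a:
            candidates = [
                (kb, ps) for kb, ps in by_a.get(ka, [])
                if kb not in used_b
            ]
            if not candidates:
                continue
            kb, ps = min(candidates,
                         key=lambda t: (-t[1].total_score, t[0]))
            matches.append(EventMatch(ka, kb, ps, round_no))
            used_b.add(kb)
            round_no += 1
    return matches


def match_all(
    master: Sequence[MasterRecord],
    homologs: Iterable[HomologPair],
    genomes: Mapping[str, GenomeSource],
    params: AlignmentParams | None = None,
    species_a: str = "mouse",
    species_b: str = "human",
    mode: str = "global",
) -> list[EventMatch]:
    """Run the per-gene-pair matching over every ortholog pair.

    An event whose gene has several homologs competes in each pair
    independently; if it wins matches in more than one pair only the
    highest-total-score match is retained (ties broken by key pair), the
    rest are dropped and logged.
    """
    params = params or AlignmentParams()
    by_gene: dict[tuple[str, str], list[EventKey]] = {}
    for rec in master:
        by_gene.setdefault(
            (rec.key.species, rec.key.gene_id), []
        ).append(rec.key)
    all_matches: list[EventMatch] = []
    n_skipped = 0
    for pair in sorted(set(homologs),
                       key=lambda p: (p.gene_id_species_a,
                                      p.gene_id_species_b)):
        ev_a = by_gene.get((species_a, pair.gene_id_species_a), [])
        ev_b = by_gene.get((species_b, pair.gene_id_species_b), [])
        if not ev_a or not ev_b:
            n_skipped += 1
            continue
        all_matches.extend(
            match_events_for_gene_pair(ev_a, ev_b, genomes, params, mode)
        )
    if n_skipped:
        logger.info("match_all: %d homolog pair(s) without events on both "
                    "sides skipped", n_skipped)
    # resolve cross-pair conflicts: keep the best match per event key
    ordered = sorted(
        all_matches,
        key=lambda m: (-m.pair_score.total_score,
                       m.event_key_a, m.event_key_b),
    )
    used: set[EventKey] = set()
    retained: list[EventMatch] = []
    dropped = 0
    for m in ordered:
        if m.event_key_a in used or m.event_key_b in used:
            dropped += 1
            continue
        used.add(m.event_key_a)
        used.add(m.event_key_b)
        retained.append(m)
    if dropped:
        logger.info("match_all: dropped %d lower-scoring multi-homolog "
                    "match(es)", dropped)
    retained.sort(key=lambda m: (m.event_key_a, m.event_key_b))
    return retained


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def matches_to_frame(matches: Sequence[EventMatch]) -> pd.DataFrame:
    records = []
    for m in matches:
        ps = m.pair_score
        records.append({
            "event_key_a": str(m.event_key_a),
            "event_key_b": str(m.event_key_b),
            "score_target": ps.scores[0],
            "score_5prime": ps.scores[1],
            "score_3prime": ps.scores[2],
            "identity_target": ps.identities[0],
            "identity_5prime": ps.identities[1],
            "identity_3prime": ps.identities[2],
            "total_score": ps.total_score,
            "match_round": m.match_round,
        })
    return pd.DataFrame(records, columns=[
        "event_key_a", "event_key_b", "score_target", "score_5prime",
        "score_3prime", "identity_target", "identity_5prime",
        "identity_3prime", "total_score", "match_round",
    ])


def matches_from_frame(df: pd.DataFrame) -> list[EventMatch]:
    matches = []
    for rec in df.itertuples(index=False):
        ps = PairScore(
            scores=(float(rec.score_target), float(rec.score_5prime),
                    float(rec.score_3prime)),
            identities=(float(rec.identity_target),
                        float(rec.identity_5prime),
                        float(rec.identity_3prime)),
            eligible=True,
        )
        matches.append(EventMatch(
            EventKey.parse(rec.event_key_a),
            EventKey.parse(rec.event_key_b),
            ps, int(rec.match_round),
        ))
    return matches


def write_matches(matches: Sequence[EventMatch], path,
                  header_comment: str | None = None) -> None:
    write_tsv(matches_to_frame(matches), path, header_comment)
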