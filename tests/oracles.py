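"""Independent reference implementations used only by the test suite.

Each oracle mirrors a pipeline operation through a different route:
Biopython's C pairwise aligner for global alignment scores, a single
sorted-sweep for the greedy event matching, and exhaustive spacer
enumeration for the bounded-gap CA patterns.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

from orthosplice import AlignmentParams, EventKey, GenomeSource

BASES = "ACGT"


def biopython_global_score(a: str, b: str,
                           params: AlignmentParams | None = None) -> float:
    """Global affine-gap score where a gap of length L costs open + L*ext."""
    params = params or AlignmentParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return float(aligner.score(a, b))


def sorted_sweep_matching(scored_pairs):
    """Reference greedy: one sweep over eligible pairs sorted by
    (total score desc, key pair asc), accepting non-conflicting pairs.

    ``scored_pairs``: iterable of (key_a, key_b, PairScore) with only
    eligible entries.  Returns the accepted (key_a, key_b) set.
    """
    ordered = sorted(scored_pairs,
                     key=lambda t: (-t[2].total_score, t[0], t[1]))
    used_a, used_b, accepted = set(), set(), set()
    for ka, kb, _ in ordered:
        if ka in used_a or kb in used_b:
            continue
        used_a.add(ka)
        used_b.add(kb)
        accepted.add((ka, kb))
    return accepted


def brute_force_ca_hits(seq: str, n_units: int) -> list[tuple[int, str]]:
    """Leftmost non-overlapping bounded-gap CA repeats by enumeration.

    At each candidate offset every spacer combination (each 0-2 bases,
    enumerated lexicographically, mirroring a lazy regex) is tried; the
    first matching combination is the reported hit and the search resumes
    past its end.
    """
    hits = []
    pos = 0
    n = len(seq)
    spacer_combos = _lex_spacer_combos(n_units - 1)
    while pos < n:
        found = None
        for combo in spacer_combos:
            end = pos
            ok = True
            for i in range(n_units):
                if seq[end:end + 2] != "CA":
                    ok = False
                    break
                end += 2
                if i < n_units - 1:
                    end += combo[i]
            if ok and end <= n:
                found = (pos, seq[pos:end])
                break
        if found:
            hits.append(found)
            pos += len(found[1])
        else:
            pos += 1
    return hits


def _lex_spacer_combos(k: int) -> list[tuple[int, ...]]:
    combos = [()]
    for _ in range(k):
        combos = [c + (s,) for c in combos for s in (0, 1, 2)]
    combos.sort()
    return combos


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_dna(rng: np.random.Generator, seq: str, p: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < p:
            ch = [b for b in BASES if b != ch][rng.integers(0, 3)]
        out.append(ch)
    return "".join(out)


def make_gene_instance(rng: np.random.Generator, n_a: int, n_b: int,
                       divergence: float = 0.08):
    """A random one-gene matching instance with planted relatives.

    Species-A events get random exon triplets laid onto one contig;
    species-B events are mutated copies of randomly chosen A events (so
    some cross pairs are eligible and some are not), laid onto a second
    contig.  Returns (events_a, events_b, genomes).
    """
    def build_side(trips, species, contig_name, gene_id):
        seqs, keys, pos = [], [], 0
        for five, target, three in trips:
            l = (pos, pos + len(five))
            pos = l[1] + 20
            t = (pos, pos + len(target))
            pos = t[1] + 20
            r = (pos, pos + len(three))
            pos = r[1] + 30
            seqs.append((l, five))
            seqs.append((t, target))
            seqs.append((r, three))
            keys.append(EventKey(species, gene_id, contig_name, "+",
                                 t, l, r))
        contig = ["A"] * pos
        for (s, e), seq in seqs:
            contig[s:e] = list(seq)
        return keys, "".join(contig)

    trips_a = [
        tuple(random_dna(rng, int(rng.integers(25, 60))) for _ in range(3))
        for _ in range(n_a)
    ]
    trips_b = []
    for _ in range(n_b):
        if n_a and rng.random() < 0.7:
            src = trips_a[rng.integers(0, n_a)]
            trips_b.append(tuple(mutate_dna(rng, s, divergence)
                                 for s in src))
        else:
            trips_b.append(tuple(
                random_dna(rng, int(rng.integers(25, 60)))
                for _ in range(3)
            ))
    events_a, contig_a = build_side(trips_a, "mouse", "cA", "gA")
    events_b, contig_b = build_side(trips_b, "human", "cB", "gB")
    genomes = {
        "mouse": GenomeSource("gnA", {"cA": contig_a}),
        "human": GenomeSource("gnB", {"cB": contig_b}),
    }
    return events_a, events_b, genomes
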