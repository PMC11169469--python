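"""hnRNPL binding-motif annotation of skipped-exon events.

Each event is scanned across five transcribed-orientation segments — the
skipped exon, the two immediately adjacent introns and the two adjacent
exons — for (a) the canonical hnRNPL consensus motifs ACACACA and ACACAAA
(exact substring match on the sense strand) and (b) bounded-gap CA repeats:
four CA units with at most two arbitrary bases between consecutive units
(maximal span 14 nt) or three CA units under the same gap bound (maximal
span 10 nt), i.e. the regular expressions ``CA.{0,2}CA.{0,2}CA.{0,2}CA``
and ``CA.{0,2}CA.{0,2}CA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diff_events import EventKey
from .io_tables import GenomeSource, fetch_sequence, write_tsv

SEGMENTS = (
    "fiveprime_exon",
    "upstream_intron",
    "skipped_exon",
    "downstream_intron",
    "threeprime_exon",
)

CANONICAL = "canonical"
CA4 = "ca4"
CA3 = "ca3"


@dataclass(frozen=True)
class MotifSpec:
    """Consensus strings and bounded-gap CA patterns.

    The lazy quantifiers make each reported CA-repeat hit the minimal-span
    instance starting at its offset; spans can never exceed 14 (ca4) or
    10 (ca3) nucleotides.
    """

    canonical_consensus: tuple[str, ...] = ("ACACACA", "ACACAAA")
    ca4_pattern: str = r"CA.{0,2}?CA.{0,2}?CA.{0,2}?CA"
    ca3_pattern: str = r"CA.{0,2}?CA.{0,2}?CA"


@dataclass(frozen=True)
class MotifHit:
    segment: str
    motif_id: str          # canonical | ca4 | ca3
    offset: int            # 0-based within the segment sequence
    matched: str


@dataclass
class ScanRegion:
    """The five scan segments of one event, in transcribed orientation."""

    event_key: EventKey
    segments: dict[str, str]                  # name -> sequence (may be "")
    intervals: dict[str, tuple[int, int]]     # name -> genomic half-open
    zero_length_introns: tuple[str, ...] = ()


@dataclass
class MotifAnnotation:
    event_key: EventKey
    hits: list[MotifHit] = field(default_factory=list)

    @property
    def has_canonical(self) -> bool:
        return any(h.motif_id == CANONICAL for h in self.hits)

    @property
    def has_ca_rich(self) -> bool:
        return any(h.motif_id in (CA3, CA4) for h in self.hits)

    def segment_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in SEGMENTS}
        for h in self.hits:
            counts[h.segment] += 1
        return counts


def build_scan_region(event: EventKey, genome: GenomeSource) -> ScanRegion:
    """Extract the five segments; introns are the gaps between exons.

    Genomic intervals: upstream-left intron (left-flank end, target start)
    and right intron (target end, right-flank start); on the minus strand
    the genomic-right gap is the transcript's upstream intron.  Zero-length
    introns (abutting exons) are retained as empty segments and flagged.
    """
    t, l, r = event.target, event.left_flank, event.right_flank
    if not (l[1] <= t[0] and t[1] <= r[0]):
        raise ValueError(f"event {event}: flanks overlap the target exon")
    left_intron = (l[1], t[0])
    right_intron = (t[1], r[0])

    def seq(iv: tuple[int, int]) -> str:
        if iv[0] == iv[1]:
            return ""
        return fetch_sequence(genome, event.chrom, iv[0], iv[1],
                              event.strand)

    if event.strand == "+":
        genomic = {
            "fiveprime_exon": l,
            "upstream_intron": left_intron,
            "skipped_exon": t,
            "downstream_intron": right_intron,
            "threeprime_exon": r,
        }
    else:
        genomic = {
            "fiveprime_exon": r,
            "upstream_intron": right_intron,
            "skipped_exon": t,
            "downstream_intron": left_intron,
            "threeprime_exon": l,
        }
    segments = {name: seq(iv) for name, iv in genomic.items()}
    zero = tuple(
        name for name in ("upstream_intron", "downstream_intron")
        if genomic[name][0] == genomic[name][1]
    )
    return ScanRegion(event_key=event, segments=segments,
                      intervals=genomic, zero_length_introns=zero)


def scan_consensus(seq: str, spec: MotifSpec | None = None,
                   segment: str = "skipped_exon") -> list[MotifHit]:
    """All (possibly overlapping) exact occurrences of each consensus."""
    spec = spec or MotifSpec()
    hits: list[MotifHit] = []
    for motif in spec.canonical_consensus:
        start = seq.find(motif)
        while start != -1:
            hits.append(MotifHit(segment, CANONICAL, start, motif))
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h.offset, h.matched))
    return hits


def scan_ca_repeats(seq: str, spec: MotifSpec | None = None,
                    segment: str = "skipped_exon") -> list[MotifHit]:
    """Leftmost non-overlapping bounded-gap CA-repeat hits, per pattern."""
    spec = spec or MotifSpec()
    hits: list[MotifHit] = []
    for motif_id, pattern in ((CA4, spec.ca4_pattern),
                              (CA3, spec.ca3_pattern)):
        for m in re.finditer(pattern, seq):
            hits.append(MotifHit(segment, motif_id, m.start(), m.group()))
    hits.sort(key=lambda h: (h.offset, h.motif_id))
    return hits


def scan_region(region: ScanRegion, spec: MotifSpec | None = None
                ) -> MotifAnnotation:
    spec = spec or MotifSpec()
    ann = MotifAnnotation(event_key=region.event_key)
    for name in SEGMENTS:
        seq = region.segments.get(name, "")
        if not seq:
            continue
        ann.hits.extend(scan_consensus(seq, spec, segment=name))
        ann.hits.extend(scan_ca_repeats(seq, spec, segment=name))
    return ann


def annotate_events(events: Iterable[EventKey],
                    genomes: Mapping[str, GenomeSource],
                    spec: MotifSpec | None = None) -> list[MotifAnnotation]:
    """Scan every event's five segments; one annotation per event key."""
    spec = spec or MotifSpec()
    annotations = []
    for key in sorted(set(events)):
        region = build_scan_region(key, genomes[key.species])
        annotations.append(scan_region(region, spec))
    return annotations


def summarize_cohort(annotations: Sequence[MotifAnnotation]
                     ) -> dict[str, int]:
    """Cohort-level counts of events carrying each motif class."""
    return {
        "n_events": len(annotations),
        "n_canonical": sum(a.has_canonical for a in annotations),
        "n_ca_rich": sum(a.has_ca_rich for a in annotations),
        "n_any_motif": sum(
            a.has_canonical or a.has_ca_rich for a in annotations
        ),
    }


def annotations_to_frame(annotations: Sequence[MotifAnnotation]
                         ) -> pd.DataFrame:
    records = []
    for ann in annotations:
        for h in ann.hits:
            records.append({
                "event_key": str(ann.event_key),
                "segment": h.segment,
                "motif_id": h.motif_id,
                "offset": h.offset,
                "matched": h.matched,
            })
    return pd.DataFrame(records, columns=[
        "event_key", "segment", "motif_id", "offset", "matched",
    ])


def summary_to_frame(annotations: Sequence[MotifAnnotation]) -> pd.DataFrame:
    records = []
    for ann in annotations:
        counts = ann.segment_counts()
        rec = {
            "event_key": str(ann.event_key),
            "has_canonical": ann.has_canonical,
            "has_ca_rich": ann.has_ca_rich,
        }
        rec.update({f"hits_{name}": counts[name] for name in SEGMENTS})
        records.append(rec)
    return pd.DataFrame(records, columns=[
        "event_key", "has_canonical", "has_ca_rich",
        *[f"hits_{name}" for name in SEGMENTS],
    ])


def write_motif_tables(annotations, hits_path, summary_path,
                       header_comment: str | None = None) -> None:
    write_tsv(annotations_to_frame(annotations), hits_path, header_comment)
    write_tsv(summary_to_frame(annotations), summary_path, header_comment)
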