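"""Differential-splicing filtering and the cross-dataset master table.

A skipped-exon event is identified by the start/end positions of its three
exons (target plus the two flanking exons).  Per dataset the event carries
an oriented inclusion-level difference (ΔPSI, depleted − control), an FDR
and the average junction-read coverage; the filters are the study-wide
thresholds: coverage ≥ 10 average junction reads, 0.10 ≤ |ΔPSI| ≤ 0.95 and
FDR < 0.1 for a differential ("strict") call, FDR < 0.2 for entry into the
master table that the cross-species comparison consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_tables import (
    DatasetSpec,
    SpliceTableRow,
    ValidationError,
    write_tsv,
)

logger = logging.getLogger(__name__)

STRICT_PASS = "strict_pass"
LOOSE_ONLY = "loose_only"
FAIL = "fail"
ABSENT = "absent"


@dataclass(frozen=True, order=True)
class EventKey:
    """Canonical identity of one skipped-exon event within one genome.

    Flanks are stored in genomic orientation (left = smaller coordinates);
    the transcript 5'/3' roles are resolved by the strand when sequences
    are extracted.
    """

    species: str
    gene_id: str
    chrom: str
    strand: str
    target: tuple[int, int]
    left_flank: tuple[int, int]
    right_flank: tuple[int, int]

    @classmethod
    def from_row(cls, row: SpliceTableRow, species: str) -> "EventKey":
        up = (row.upstream_start, row.upstream_end)
        down = (row.downstream_start, row.downstream_end)
        left, right = sorted([up, down])
        return cls(
            species=species,
            gene_id=row.gene_id,
            chrom=row.chrom,
            strand=row.strand,
            target=(row.exon_start, row.exon_end),
            left_flank=left,
            right_flank=right,
        )

    def __str__(self) -> str:
        t, l, r = self.target, self.left_flank, self.right_flank
        return (
            f"{self.species}|{self.gene_id}|{self.chrom}|{self.strand}|"
            f"{t[0]}-{t[1]}|{l[0]}-{l[1]}|{r[0]}-{r[1]}"
        )

    @classmethod
    def parse(cls, text: str) -> "EventKey":
        species, gene, chrom, strand, t, l, r = text.split("|")
        ivals = [tuple(int(x) for x in p.split("-")) for p in (t, l, r)]
        return cls(species, gene, chrom, strand, *ivals)


@dataclass(frozen=True)
class EventStats:
    """Oriented per-dataset statistics of one event."""

    dataset_id: str
    avg_junction_reads: float
    inc_level_diff: float | None
    fdr: float | None
    pvalue: float | None = None


@dataclass(frozen=True)
class FilterThresholds:
    """The study's differential-splicing thresholds.

    ΔPSI bounds are inclusive (printed as ≥/≤); FDR bounds exclusive
    (printed as <).
    """

    min_avg_jc: float = 10.0
    min_abs_dpsi: float = 0.10
    max_abs_dpsi: float = 0.95
    fdr_strict: float = 0.1
    fdr_loose: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.min_abs_dpsi < self.max_abs_dpsi <= 1:
            raise ValidationError("ΔPSI bounds must satisfy 0 ≤ lo < hi ≤ 1")
        if not self.fdr_strict < self.fdr_loose:
            raise ValidationError("fdr_strict must be < fdr_loose")


@dataclass
class MasterRecord:
    """One event of the master table with its per-dataset stats/statuses."""

    key: EventKey
    gene_symbol: str
    stats: dict[str, EventStats] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def status_of(self, dataset_id: str) -> str:
        return self.status.get(dataset_id, ABSENT)


def average_junction_reads(row: SpliceTableRow) -> float:
    """Mean of (IJC + SJC) over all replicates of both groups (JC counts)."""
    totals = [i + s for i, s in zip(row.ijc_group1, row.sjc_group1)]
    totals += [i + s for i, s in zip(row.ijc_group2, row.sjc_group2)]
    if not totals:
        raise ValidationError(
            f"row {row.event_row_id}: no replicates to average over"
        )
    return sum(totals) / len(totals)


def classify_event(stats: EventStats, thresholds: FilterThresholds
                   ) -> str:
    """Classify one dataset's view of an event against the thresholds.

    strict_pass: coverage ≥ min_avg_jc, min ≤ |ΔPSI| ≤ max, FDR < strict.
    loose_only: not strict but FDR < loose (master-table membership).
    """
    fdr = stats.fdr
    dpsi = stats.inc_level_diff
    strict = (
        fdr is not None
        and dpsi is not None
        and stats.avg_junction_reads >= thresholds.min_avg_jc
        and thresholds.min_abs_dpsi <= abs(dpsi) <= thresholds.max_abs_dpsi
        and fdr < thresholds.fdr_strict
    )
    if strict:
        return STRICT_PASS
    if fdr is not None and fdr < thresholds.fdr_loose:
        return LOOSE_ONLY
    return FAIL


def _index_rows(rows: Iterable[SpliceTableRow], species: str,
                dataset_id: str) -> dict[EventKey, SpliceTableRow]:
    index: dict[EventKey, SpliceTableRow] = {}
    collisions: dict[EventKey, list[int]] = {}
    for row in rows:
        key = EventKey.from_row(row, species)
        if key in index:
            collisions.setdefault(key, [index[key].event_row_id]).append(
                row.event_row_id
            )
        else:
            index[key] = row
    if collisions:
        details = "; ".join(
            f"{k}: rows {ids}" for k, ids in list(collisions.items())[:5]
        )
        raise ValidationError(
            f"dataset {dataset_id}: duplicate event key(s): {details}"
        )
    return index


def build_master_table(
    datasets: Sequence[tuple[DatasetSpec, Iterable[SpliceTableRow],
                             Iterable[SpliceTableRow] | None]],
    thresholds: FilterThresholds | None = None,
) -> list[MasterRecord]:
    """Join JC/JCEC rows per dataset and keep events with FDR < loose anywhere.

    The JC dialect supplies the coverage (average junction reads); the JCEC
    dialect, when provided, supplies ΔPSI/p/FDR (junction plus exon-body
    quantification), otherwise JC supplies both.  Joining is by exact
    :class:`EventKey`; quantified rows without a JC counterpart keep
    coverage 0 (they can never be strict_pass) and are logged.
    """
    thresholds = thresholds or FilterThresholds()
    per_key: dict[EventKey, MasterRecord] = {}
    for spec, jc_rows, jcec_rows in datasets:
        jc_index = _index_rows(jc_rows, spec.species, spec.dataset_id)
        if jcec_rows is not None:
            quant_index = _index_rows(jcec_rows, spec.species,
                                      spec.dataset_id)
        else:
            quant_index = jc_index
        unjoined = [k for k in quant_index if k not in jc_index]
        if unjoined and quant_index is not jc_index:
            logger.warning(
                "dataset %s: %d quantified event(s) missing from JC table "
                "(coverage treated as 0)", spec.dataset_id, len(unjoined)
            )
        jc_only = [k for k in jc_index if k not in quant_index]
        if jc_only and quant_index is not jc_index:
            logger.info(
                "dataset %s: %d JC event(s) absent from JCEC table, skipped",
                spec.dataset_id, len(jc_only)
            )
        n_missing_dpsi = 0
        for key in quant_index:
            qrow = quant_index[key]
            if qrow.inc_level_diff is None:
                n_missing_dpsi += 1
                continue
            dpsi = qrow.inc_level_diff
            if spec.flip_sign:
                dpsi = -dpsi
            jc_row = jc_index.get(key)
            avg = average_junction_reads(jc_row) if jc_row is not None else 0.0
            stats = EventStats(
                dataset_id=spec.dataset_id,
                avg_junction_reads=avg,
                inc_level_diff=dpsi,
                fdr=qrow.fdr,
                pvalue=qrow.pvalue,
            )
            rec = per_key.get(key)
            if rec is None:
                rec = MasterRecord(key=key, gene_symbol=qrow.gene_symbol)
                per_key[key] = rec
            rec.stats[spec.dataset_id] = stats
            rec.status[spec.dataset_id] = classify_event(stats, thresholds)
        if n_missing_dpsi:
            logger.info(
                "dataset %s: %d event(s) with missing ΔPSI excluded",
                spec.dataset_id, n_missing_dpsi
            )
    master = [
        rec for key, rec in sorted(per_key.items(), key=lambda kv: kv[0])
        if any(
            st.fdr is not None and st.fdr < thresholds.fdr_loose
            for st in rec.stats.values()
        )
    ]
    logger.info("master table: %d event(s) from %d quantified key(s)",
                len(master), len(per_key))
    return master


# ---------------------------------------------------------------------------
# (de)serialization of the master table
# ---------------------------------------------------------------------------

def master_to_frame(master: Sequence[MasterRecord]) -> pd.DataFrame:
    """Long format: one row per event × dataset."""
    records = []
    for rec in master:
        for dataset_id in sorted(rec.stats):
            st = rec.stats[dataset_id]
            records.append({
                "event_key": str(rec.key),
                "species": rec.key.species,
                "gene_id": rec.key.gene_id,
                "gene_symbol": rec.gene_symbol,
                "dataset_id": dataset_id,
                "avg_junction_reads": st.avg_junction_reads,
                "dpsi": st.inc_level_diff,
                "pvalue": st.pvalue,
                "fdr": st.fdr,
                "status": rec.status[dataset_id],
            })
    return pd.DataFrame(records, columns=[
        "event_key", "species", "gene_id", "gene_symbol", "dataset_id",
        "avg_junction_reads", "dpsi", "pvalue", "fdr", "status",
    ])


def master_from_frame(df: pd.DataFrame) -> list[MasterRecord]:
    per_key: dict[EventKey, MasterRecord] = {}
    for rec in df.itertuples(index=False):
        key = EventKey.parse(rec.event_key)
        mr = per_key.get(key)
        if mr is None:
            mr = MasterRecord(key=key, gene_symbol=str(rec.gene_symbol))
            per_key[key] = mr
        pval = None if pd.isna(rec.pvalue) else float(rec.pvalue)
        fdr = None if pd.isna(rec.fdr) else float(rec.fdr)
        dpsi = None if pd.isna(rec.dpsi) else float(rec.dpsi)
        mr.stats[rec.dataset_id] = EventStats(
            dataset_id=rec.dataset_id,
            avg_junction_reads=float(rec.avg_junction_reads),
            inc_level_diff=dpsi,
            fdr=fdr,
            pvalue=pval,
        )
        mr.status[rec.dataset_id] = str(rec.status)
    return [per_key[k] for k in sorted(per_key)]


def write_master_table(master: Sequence[MasterRecord], path,
                       header_comment: str | None = None) -> None:
    write_tsv(master_to_frame(master), path, header_comment)
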