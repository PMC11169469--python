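"""Readers and writers for every external table format the pipeline touches.

The consumed formats are the rMATS skipped-exon (SE) result tables in their
"JC" (junction counts only) and "JCEC" (junction + exon body counts)
dialects, multi-contig FASTA genomes, BioMart-style two-column ortholog
maps, DESeq2-style differential-expression exports and flat gene→biotype
tables.  Everything downstream works on the plain dataclasses defined here.

Coordinate convention: all intervals are 0-based half-open, exactly as the
``exonStart_0base``/``exonEnd`` columns of rMATS print them.  The
``upstream``/``downstream`` columns are kept verbatim as genomic-coordinate
labels; resolving them to transcript 5'/3' happens later, using the strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: columns a SE table must provide (rMATS naming)
REQUIRED_SE_COLUMNS = (
    "GeneID",
    "geneSymbol",
    "chr",
    "strand",
    "exonStart_0base",
    "exonEnd",
    "upstreamES",
    "upstreamEE",
    "downstreamES",
    "downstreamEE",
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "PValue",
    "FDR",
    "IncLevelDifference",
)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed record violates a type invariant."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSpec:
    """One of the depletion-versus-control RNA-seq datasets.

    ``dpsi_orientation`` states which subtraction the table's inclusion
    level difference encodes; the master-table builder normalizes every
    dataset to (depleted - control).
    """

    dataset_id: str
    species: str
    genome_id: str
    dpsi_orientation: str = "depleted_minus_control"

    def __post_init__(self) -> None:
        if self.dpsi_orientation not in (
            "depleted_minus_control",
            "control_minus_depleted",
        ):
            raise ValidationError(
                f"unknown dpsi_orientation {self.dpsi_orientation!r}"
            )

    @property
    def flip_sign(self) -> bool:
        return self.dpsi_orientation == "control_minus_depleted"


@dataclass(frozen=True)
class SpliceTableRow:
    """One skipped-exon record of an SE.MATS table (either dialect)."""

    event_row_id: int
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_start: int
    upstream_end: int
    downstream_start: int
    downstream_end: int
    ijc_group1: tuple[int, ...]
    sjc_group1: tuple[int, ...]
    ijc_group2: tuple[int, ...]
    sjc_group2: tuple[int, ...]
    pvalue: float | None
    fdr: float | None
    inc_level_diff: float | None

    def validate(self) -> None:
        for name, (s, e) in (
            ("exon", (self.exon_start, self.exon_end)),
            ("upstream", (self.upstream_start, self.upstream_end)),
            ("downstream", (self.downstream_start, self.downstream_end)),
        ):
            if not s < e:
                raise ValidationError(
                    f"row {self.event_row_id}: {name} interval inverted "
                    f"({s} >= {e})"
                )
        if self.strand not in "+-":
            raise ValidationError(
                f"row {self.event_row_id}: bad strand {self.strand!r}"
            )
        if len(self.ijc_group1) != len(self.sjc_group1):
            raise ValidationError(
                f"row {self.event_row_id}: group1 count lists differ in length"
            )
        if len(self.ijc_group2) != len(self.sjc_group2):
            raise ValidationError(
                f"row {self.event_row_id}: group2 count lists differ in length"
            )
        for counts in (self.ijc_group1, self.sjc_group1,
                       self.ijc_group2, self.sjc_group2):
            if any(c < 0 for c in counts):
                raise ValidationError(
                    f"row {self.event_row_id}: negative junction count"
                )
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValidationError(
                f"row {self.event_row_id}: FDR {self.fdr} outside [0, 1]"
            )
        if self.inc_level_diff is not None and abs(self.inc_level_diff) > 1:
            raise ValidationError(
                f"row {self.event_row_id}: |IncLevelDifference| > 1"
            )


@dataclass
class SpliceTable:
    """Parsed SE table plus the count of rejected (unparseable) rows."""

    rows: list[SpliceTableRow]
    dialect: str
    n_rejected: int = 0
    rejected_row_ids: list[int] = field(default_factory=list)

    def __iter__(self) -> Iterator[SpliceTableRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, i):
        return self.rows[i]


@dataclass
class GenomeSource:
    """An in-memory genome: contig name -> uppercase A/C/G/T/N sequence."""

    genome_id: str
    contigs: Mapping[str, str]

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None
                   ) -> "GenomeSource":
        path = Path(path)
        contigs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        if not contigs:
            raise FormatError(f"{path}: no FASTA records")
        return cls(genome_id=genome_id or path.stem, contigs=contigs)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self.contigs:
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


@dataclass(frozen=True)
class HomologPair:
    """One ortholog link between the two species' gene id spaces."""

    gene_id_species_a: str
    gene_id_species_b: str


@dataclass(frozen=True)
class DEGRow:
    gene_id: str
    log2fc: float
    padj: float | None

    def validate(self) -> None:
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValidationError(f"{self.gene_id}: padj outside [0, 1]")


class BiotypeMap:
    """Total gene_id -> biotype function; absent ids map to ``unknown``."""

    UNKNOWN = "unknown"

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        self._map = dict(mapping or {})

    def __getitem__(self, gene_id: str) -> str:
        return self._map.get(gene_id, self.UNKNOWN)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def items(self):
        return self._map.items()


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------

def fetch_sequence(genome: GenomeSource, chrom: str, start: int, end: int,
                   strand: str = "+") -> str:
    """Strand-aware substring of a contig over a 0-based half-open interval.

    For ``-`` the reverse complement of the plus-strand substring is
    returned, i.e. the sequence as transcribed.
    """
    try:
        contig = genome.contigs[chrom]
    except KeyError:
        raise KeyError(
            f"genome {genome.genome_id!r} has no contig {chrom!r}"
        ) from None
    if not 0 <= start < end <= len(contig):
        raise IndexError(
            f"interval [{start}, {end}) outside contig {chrom!r} "
            f"of length {len(contig)}"
        )
    seq = contig[start:end].upper()
    if strand == "-":
        return reverse_complement(seq)
    if strand != "+":
        raise ValidationError(f"bad strand {strand!r}")
    return seq


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_float(text: str) -> float | None:
    text = text.strip()
    if text in ("", "NA", "NaN", "nan", "None"):
        return None
    return float(text)


def _parse_counts(text: str) -> tuple[int, ...]:
    return tuple(int(t) for t in str(text).strip().split(","))


def read_splice_table(path: str | Path, dialect: str = "JC") -> SpliceTable:
    """Parse an rMATS SE.MATS table.

    Coordinates are preserved verbatim under the 0-based half-open
    convention; per-replicate junction counts are split on commas.  Rows
    whose numeric fields cannot be parsed are dropped and counted in
    ``n_rejected``; rows violating coordinate/probability invariants raise
    :class:`ValidationError`.
    """
    if dialect not in ("JC", "JCEC"):
        raise ValueError(f"dialect must be JC or JCEC, got {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    missing = [c for c in REQUIRED_SE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    rows: list[SpliceTableRow] = []
    rejected: list[int] = []
    has_id = "ID" in df.columns
    for i, rec in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, rec))
        row_id = int(rec["ID"]) if has_id else i
        try:
            row = SpliceTableRow(
                event_row_id=row_id,
                gene_id=str(rec["GeneID"]).strip('"'),
                gene_symbol=str(rec["geneSymbol"]).strip('"'),
                chrom=str(rec["chr"]),
                strand=str(rec["strand"]),
                exon_start=int(rec["exonStart_0base"]),
                exon_end=int(rec["exonEnd"]),
                upstream_start=int(rec["upstreamES"]),
                upstream_end=int(rec["upstreamEE"]),
                downstream_start=int(rec["downstreamES"]),
                downstream_end=int(rec["downstreamEE"]),
                ijc_group1=_parse_counts(rec["IJC_SAMPLE_1"]),
                sjc_group1=_parse_counts(rec["SJC_SAMPLE_1"]),
                ijc_group2=_parse_counts(rec["IJC_SAMPLE_2"]),
                sjc_group2=_parse_counts(rec["SJC_SAMPLE_2"]),
                pvalue=_parse_float(rec["PValue"]),
                fdr=_parse_float(rec["FDR"]),
                inc_level_diff=_parse_float(rec["IncLevelDifference"]),
            )
        except (ValueError, TypeError):
            rejected.append(row_id)
            continue
        row.validate()
        rows.append(row)
    if rejected:
        logger.warning(
            "%s: rejected %d unparseable row(s): %s",
            path, len(rejected), rejected[:10],
        )
    return SpliceTable(rows=rows, dialect=dialect,
                       n_rejected=len(rejected), rejected_row_ids=rejected)


def read_homolog_map(path: str | Path) -> list[HomologPair]:
    """Two-column TSV (header line, species-A id, species-B id).

    Duplicate pairs are collapsed; first-seen order is preserved.
    """
    pairs: list[HomologPair] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: no homolog pairs (empty file?)")
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise FormatError(f"{path}: malformed line {lineno}: {line!r}")
        key = (fields[0], fields[1])
        if key not in seen:
            seen.add(key)
            pairs.append(HomologPair(*key))
    return pairs


def read_deg_table(path: str | Path) -> list[DEGRow]:
    """DESeq2-style export: gene_id, log2FoldChange, padj (tab-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                     keep_default_na=False)
    if df.empty:
        raise FormatError(f"{path}: empty DEG table")
    cols = {c.lower(): c for c in df.columns}
    try:
        gene_col = cols.get("gene_id") or cols["gene"]
    except KeyError:
        raise FormatError(f"{path}: missing gene_id column") from None
    fc_col = cols.get("log2foldchange") or cols.get("log2fc")
    padj_col = cols.get("padj") or cols.get("adj_pvalue")
    if fc_col is None or padj_col is None:
        raise FormatError(f"{path}: missing log2FoldChange/padj column")
    rows: list[DEGRow] = []
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, rec))
        try:
            fc = _parse_float(str(rec[fc_col]))
        except ValueError:
            raise FormatError(f"{path}: malformed line {lineno}") from None
        if fc is None:
            continue  # untestable gene, no fold change
        row = DEGRow(gene_id=str(rec[gene_col]), log2fc=fc,
                     padj=_parse_float(str(rec[padj_col])))
        row.validate()
        rows.append(row)
    return rows


def read_biotypes(path: str | Path) -> BiotypeMap:
    """Flat gene_id → biotype TSV with a header line."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: empty biotype table")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: malformed line {lineno}: {line!r}")
        mapping[fields[0]] = fields[1]
    return BiotypeMap(mapping)


# ---------------------------------------------------------------------------
# generic TSV output with provenance header
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path,
              header_comment: str | None = None) -> None:
    """Write a DataFrame as TSV, optionally preceded by '#' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def export_events_bed(events: Sequence, path: str | Path) -> None:
    """BED6 export of the three exons of each event (name = event key)."""
    records = []
    for key in events:
        for label, (s, e) in (
            ("target", key.target),
            ("left", key.left_flank),
            ("right", key.right_flank),
        ):
            records.append(
                (key.chrom, s, e, f"{key}|{label}", 0, key.strand)
            )
    df = pd.DataFrame(
        records, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    df.to_csv(path, sep="\t", index=False, header=False)
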