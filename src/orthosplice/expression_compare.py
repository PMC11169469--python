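"""Cross-dataset differential-expression comparison and lncRNA fractions.

The pipeline consumes DESeq2-style tables; a gene is differentially
expressed in a dataset when |fold-change| ≥ 1.5 and adjusted p < 0.1
(i.e. |log2FC| ≥ log2 1.5 ≈ 0.585, padj < 0.1).  Per dataset the fraction
of up-/down-regulated genes annotated as lncRNA is computed, and genes are
unified across species through the ortholog map to find changes shared by
at least six of the nine datasets with a concordant direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_tables import BiotypeMap, DEGRow, HomologPair, write_tsv

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NS = "ns"

LNCRNA_BIOTYPES = ("lncRNA", "lincRNA")


@dataclass(frozen=True)
class DEGThresholds:
    """|fold-change| ≥ 1.5 (inclusive) and padj < 0.1 (exclusive)."""

    min_fold_change: float = 1.5
    max_padj: float = 0.1

    def __post_init__(self) -> None:
        if not self.min_fold_change > 1:
            raise ValueError("min_fold_change must exceed 1")
        if not 0 < self.max_padj < 1:
            raise ValueError("max_padj must lie in (0, 1)")

    @property
    def min_abs_log2fc(self) -> float:
        return math.log2(self.min_fold_change)


@dataclass(frozen=True)
class DEGCall:
    gene_id: str
    dataset_id: str
    direction: str          # up | down | ns
    is_lncRNA: bool


@dataclass
class FractionResult:
    """Per-dataset lncRNA fractions among up/down genes.

    Fractions are ``None`` when there are no up (or down) genes; genes
    with unknown biotype are excluded from numerator and denominator and
    counted separately.
    """

    dataset_id: str
    fraction_up: float | None
    fraction_down: float | None
    n_up: int
    n_down: int
    n_unknown_excluded: int


def call_deg(row: DEGRow, thresholds: DEGThresholds | None = None) -> str:
    """up/down/ns classification; missing padj is never significant."""
    thresholds = thresholds or DEGThresholds()
    if row.padj is None or not row.padj < thresholds.max_padj:
        return NS
    if row.log2fc >= thresholds.min_abs_log2fc:
        return UP
    if row.log2fc <= -thresholds.min_abs_log2fc:
        return DOWN
    return NS


def make_calls(dataset_id: str, rows: Iterable[DEGRow],
               biotypes: BiotypeMap,
               thresholds: DEGThresholds | None = None,
               lncrna_biotypes: Sequence[str] = LNCRNA_BIOTYPES
               ) -> list[DEGCall]:
    thresholds = thresholds or DEGThresholds()
    return [
        DEGCall(
            gene_id=row.gene_id,
            dataset_id=dataset_id,
            direction=call_deg(row, thresholds),
            is_lncRNA=biotypes[row.gene_id] in lncrna_biotypes,
        )
        for row in rows
    ]


def lncrna_fractions(calls: Sequence[DEGCall], biotypes: BiotypeMap,
                     dataset_id: str | None = None,
                     lncrna_biotypes: Sequence[str] = LNCRNA_BIOTYPES
                     ) -> FractionResult:
    """Fraction of up (and down) regulated genes annotated as lncRNA."""
    if dataset_id is None:
        ids = {c.dataset_id for c in calls}
        if len(ids) > 1:
            raise ValueError("calls span several datasets; pass dataset_id")
        dataset_id = next(iter(ids)) if ids else ""
    n_unknown = 0
    counts = {UP: [0, 0], DOWN: [0, 0]}   # direction -> [lnc, total]
    for call in calls:
        if call.direction == NS:
            continue
        if biotypes[call.gene_id] == BiotypeMap.UNKNOWN:
            n_unknown += 1
            continue
        is_lnc = biotypes[call.gene_id] in lncrna_biotypes
        counts[call.direction][0] += int(is_lnc)
        counts[call.direction][1] += 1
    n_up, n_down = counts[UP][1], counts[DOWN][1]
    if n_unknown:
        logger.info("dataset %s: %d DEG(s) with unknown biotype excluded "
                    "from lncRNA fractions", dataset_id, n_unknown)
    return FractionResult(
        dataset_id=dataset_id,
        fraction_up=counts[UP][0] / n_up if n_up else None,
        fraction_down=counts[DOWN][0] / n_down if n_down else None,
        n_up=n_up,
        n_down=n_down,
        n_unknown_excluded=n_unknown,
    )


def _gene_groups(homologs: Iterable[HomologPair],
                 genes: Iterable[str]) -> dict[str, tuple[str, ...]]:
    """Map each gene id to its ortholog group (connected component)."""
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for pair in homologs:
        graph.add_edge(pair.gene_id_species_a, pair.gene_id_species_b)
    mapping: dict[str, tuple[str, ...]] = {}
    for comp in nx.connected_components(graph):
        group = tuple(sorted(comp))
        for g in comp:
            mapping[g] = group
    return mapping


@dataclass
class OverlapResult:
    """Shared-DEG groups and the full dataset-count distribution."""

    shared: pd.DataFrame          # groups with count >= min_datasets
    distribution: pd.DataFrame    # count -> number of gene groups


def cross_dataset_deg_overlap(
    calls_by_dataset: Mapping[str, Sequence[DEGCall]],
    homologs: Iterable[HomologPair],
    min_datasets: int = 6,
    require_concordance: bool = True,
) -> OverlapResult:
    """Count, per ortholog gene group, the datasets with a concordant call.

    Genes are unified across species into connected components of the
    homolog-pair graph.  A dataset counts toward a group when the group's
    members measured there carry exactly one non-ns direction; when
    ``require_concordance`` the non-ns directions must also agree across
    datasets, otherwise the group is excluded as conflicting.
    """
    all_genes = {
        c.gene_id for calls in calls_by_dataset.values() for c in calls
    }
    groups = _gene_groups(homologs, all_genes)
    # group -> dataset -> set of directions seen
    per_group: dict[tuple[str, ...], dict[str, set[str]]] = {}
    for dataset_id in sorted(calls_by_dataset):
        for call in calls_by_dataset[dataset_id]:
            if call.direction == NS:
                continue
            group = groups.get(call.gene_id, (call.gene_id,))
            per_group.setdefault(group, {}).setdefault(
                dataset_id, set()
            ).add(call.direction)
    records = []
    for group in sorted(per_group):
        dataset_dirs = per_group[group]
        directions: set[str] = set()
        n_datasets = 0
        conflict = False
        for dataset_id, dirs in dataset_dirs.items():
            if len(dirs) > 1:
                conflict = True     # up and down within one dataset
                continue
            directions.update(dirs)
            n_datasets += 1
        if require_concordance and (conflict or len(directions) > 1):
            continue
        records.append({
            "gene_group": ";".join(group),
            "direction": "/".join(sorted(directions)),
            "n_datasets": n_datasets,
            "datasets": ",".join(sorted(dataset_dirs)),
        })
    df = pd.DataFrame(records, columns=[
        "gene_group", "direction", "n_datasets", "datasets",
    ])
    distribution = (
        df.groupby("n_datasets").size().rename("n_gene_groups")
        .reset_index().sort_values("n_datasets", ignore_index=True)
    )
    shared = df[df["n_datasets"] >= min_datasets].sort_values(
        ["n_datasets", "gene_group"], ascending=[False, True],
        ignore_index=True,
    )
    return OverlapResult(shared=shared, distribution=distribution)


def fractions_to_frame(results: Sequence[FractionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "dataset_id": r.dataset_id,
        "fraction_up": r.fraction_up,
        "fraction_down": r.fraction_down,
        "n_up": r.n_up,
        "n_down": r.n_down,
        "n_unknown_excluded": r.n_unknown_excluded,
    } for r in results], columns=[
        "dataset_id", "fraction_up", "fraction_down", "n_up", "n_down",
        "n_unknown_excluded",
    ])


def calls_to_frame(calls_by_dataset: Mapping[str, Sequence[DEGCall]]
                   ) -> pd.DataFrame:
    records = [{
        "dataset_id": c.dataset_id,
        "gene_id": c.gene_id,
        "direction": c.direction,
        "is_lncRNA": c.is_lncRNA,
    } for d in sorted(calls_by_dataset) for c in calls_by_dataset[d]]
    return pd.DataFrame(records, columns=[
        "dataset_id", "gene_id", "direction", "is_lncRNA",
    ])


def write_deg_outputs(calls_by_dataset, fractions, overlap, outdir,
                      header_comment: str | None = None) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    write_tsv(calls_to_frame(calls_by_dataset),
              outdir / "deg_calls.tsv", header_comment)
    write_tsv(fractions_to_frame(fractions),
              outdir / "lncrna_fractions.tsv", header_comment)
    write_tsv(overlap.shared, outdir / "deg_overlap.tsv", header_comment)
    write_tsv(overlap.distribution,
              outdir / "deg_overlap_distribution.tsv", header_comment)
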