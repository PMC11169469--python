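"""Conservation calls over clusters of equivalent splicing events.

Events are grouped into clusters: within one genome an event is identified
by its key, and retained cross-species matches connect keys across
genomes; clusters are the connected components of that graph.  A cluster is
a conserved cross-species splicing change when it passes the strict
differential thresholds in at least ``min_strict_datasets`` of the
datasets, is detected (at the loose FDR cutoff) in at least one mouse
dataset, and the strict ΔPSI values agree in sign ("equally changed").
Clusters strict in ≥ the minimum number of datasets but confined to one
species are called species-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .diff_events import ABSENT, STRICT_PASS, EventKey, MasterRecord
from .ortho_match import EventMatch
from .io_tables import write_tsv

logger = logging.getLogger(__name__)

CONSERVED = "conserved_cross_species"
SPECIES_SPECIFIC = "species_specific"
NOT_CONSERVED = "not_conserved"


@dataclass
class EventCluster:
    """A connected component of equivalent events across datasets/species."""

    cluster_id: int
    members: tuple[EventKey, ...]
    matches: tuple[EventMatch, ...]
    status: dict[str, str] = field(default_factory=dict)
    dpsi: dict[str, float] = field(default_factory=dict)
    gene_symbols: tuple[str, ...] = ()

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({k.species for k in self.members}))

    def status_of(self, dataset_id: str) -> str:
        return self.status.get(dataset_id, ABSENT)


@dataclass(frozen=True)
class ConservationCriteria:
    """The ≥6-of-9-datasets definition with mandatory mouse detection."""

    min_strict_datasets: int = 6
    total_datasets: int = 9
    require_mouse: bool = True
    mouse_species: str = "mouse"

    def __post_init__(self) -> None:
        if not 1 <= self.min_strict_datasets <= self.total_datasets:
            raise ValueError(
                "min_strict_datasets must lie in [1, total_datasets]"
            )


@dataclass(frozen=True)
class ConservationCall:
    cluster_id: int
    n_strict: int
    n_loose: int
    species_with_strict: tuple[str, ...]
    has_mouse_detection: bool
    direction_concordant: bool
    verdict: str


def cluster_events(master: Sequence[MasterRecord],
                   matches: Sequence[EventMatch]) -> list[EventCluster]:
    """Connected components over master-table keys linked by matches."""
    by_key: dict[EventKey, MasterRecord] = {rec.key: rec for rec in master}
    graph = nx.Graph()
    graph.add_nodes_from(by_key)
    for m in matches:
        for k in (m.event_key_a, m.event_key_b):
            if k not in by_key:
                raise KeyError(
                    f"match references event {k} absent from the master table"
                )
        graph.add_edge(m.event_key_a, m.event_key_b)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: comp[0],
    )
    clusters: list[EventCluster] = []
    for cid, comp in enumerate(components):
        keyset = set(comp)
        status: dict[str, str] = {}
        dpsi: dict[str, float] = {}
        symbols: set[str] = set()
        for key in comp:
            rec = by_key[key]
            symbols.add(rec.gene_symbol)
            for dataset_id, st in rec.status.items():
                status[dataset_id] = st
                stat = rec.stats[dataset_id]
                if stat.inc_level_diff is not None:
                    dpsi[dataset_id] = stat.inc_level_diff
        clusters.append(EventCluster(
            cluster_id=cid,
            members=tuple(comp),
            matches=tuple(
                m for m in matches
                if m.event_key_a in keyset and m.event_key_b in keyset
            ),
            status=status,
            dpsi=dpsi,
            gene_symbols=tuple(sorted(symbols)),
        ))
    return clusters


def call_conserved(cluster: EventCluster,
                   criteria: ConservationCriteria,
                   dataset_species: Mapping[str, str]) -> ConservationCall:
    """Apply the conservation definition to one cluster.

    ``dataset_species`` maps dataset_id → species label, used for the
    mouse-detection requirement and the species-specific verdict.
    """
    strict = [d for d, s in cluster.status.items() if s == STRICT_PASS]
    n_strict = len(strict)
    n_loose = sum(1 for s in cluster.status.values() if s != ABSENT)
    species_with_strict = tuple(sorted({dataset_species[d] for d in strict}))
    has_mouse = any(
        dataset_species[d] == criteria.mouse_species
        for d, s in cluster.status.items() if s != ABSENT
    )
    signs = {1 if cluster.dpsi[d] > 0 else -1 for d in strict}
    direction_concordant = len(signs) <= 1
    if (
        n_strict >= criteria.min_strict_datasets
        and direction_concordant
        and (has_mouse or not criteria.require_mouse)
    ):
        verdict = CONSERVED
    elif (
        n_strict >= criteria.min_strict_datasets
        and direction_concordant
        and len(species_with_strict) == 1
    ):
        verdict = SPECIES_SPECIFIC
    else:
        verdict = NOT_CONSERVED
    return ConservationCall(
        cluster_id=cluster.cluster_id,
        n_strict=n_strict,
        n_loose=n_loose,
        species_with_strict=species_with_strict,
        has_mouse_detection=has_mouse,
        direction_concordant=direction_concordant,
        verdict=verdict,
    )


def call_all(clusters: Sequence[EventCluster],
             criteria: ConservationCriteria,
             dataset_species: Mapping[str, str]) -> list[ConservationCall]:
    return [call_conserved(c, criteria, dataset_species) for c in clusters]


def upset_counts(calls: Sequence[ConservationCall],
                 clusters: Sequence[EventCluster],
                 min_set_size: int | None = None,
                 criteria: ConservationCriteria | None = None
                 ) -> pd.DataFrame:
    """Exact-intersection counts of strict-pass dataset sets.

    For each distinct set of datasets (of size ≥ the conservation minimum)
    in which some cluster passes the strict thresholds, the number of
    clusters with exactly that strict-pass set — the tabular equivalent of
    the upset plot of shared events.
    """
    criteria = criteria or ConservationCriteria()
    if min_set_size is None:
        min_set_size = criteria.min_strict_datasets
    counts: dict[tuple[str, ...], int] = {}
    for cluster in clusters:
        strict = tuple(sorted(
            d for d, s in cluster.status.items() if s == STRICT_PASS
        ))
        if len(strict) >= min_set_size:
            counts[strict] = counts.get(strict, 0) + 1
    rows = [
        {"dataset_set": ",".join(s), "set_size": len(s), "count": c}
        for s, c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["dataset_set", "set_size", "count"])
    return df.sort_values(
        ["set_size", "count", "dataset_set"], ignore_index=True
    )


def conservation_to_frame(clusters: Sequence[EventCluster],
                          calls: Sequence[ConservationCall]) -> pd.DataFrame:
    records = []
    for cluster, call in zip(clusters, calls):
        records.append({
            "cluster_id": cluster.cluster_id,
            "members": ";".join(str(k) for k in cluster.members),
            "gene_symbols": ";".join(cluster.gene_symbols),
            "species": ";".join(cluster.species),
            "n_strict": call.n_strict,
            "n_loose": call.n_loose,
            "species_with_strict": ";".join(call.species_with_strict),
            "has_mouse_detection": call.has_mouse_detection,
            "direction_concordant": call.direction_concordant,
            "verdict": call.verdict,
        })
    return pd.DataFrame(records, columns=[
        "cluster_id", "members", "gene_symbols", "species", "n_strict",
        "n_loose", "species_with_strict", "has_mouse_detection",
        "direction_concordant", "verdict",
    ])


def write_conservation(clusters, calls, path,
                       header_comment: str | None = None) -> None:
    write_tsv(conservation_to_frame(clusters, calls), path, header_comment)
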