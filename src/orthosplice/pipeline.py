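"""End-to-end orchestration of the comparative splicing/expression analysis.

``run_study`` executes every stage in memory on a synthetic (or otherwise
assembled) study; ``run_from_workspace`` reads a workspace written by
:func:`orthosplice.synthetic_data.write_workspace` (or hand-assembled in
the same layout) and writes the output TSVs.  Stages are isolated: the
matcher consumes only the master table plus genomes, the conservation
caller only the master table plus matches.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .conservation import (
    CONSERVED,
    NOT_CONSERVED,
    ConservationCall,
    ConservationCriteria,
    EventCluster,
    call_all,
    cluster_events,
    upset_counts,
    write_conservation,
)
from .diff_events import (
    EventKey,
    FilterThresholds,
    MasterRecord,
    build_master_table,
    write_master_table,
)
from .expression_compare import (
    DEGCall,
    DEGThresholds,
    FractionResult,
    OverlapResult,
    cross_dataset_deg_overlap,
    lncrna_fractions,
    make_calls,
    write_deg_outputs,
)
from .io_tables import (
    BiotypeMap,
    DatasetSpec,
    GenomeSource,
    HomologPair,
    read_biotypes,
    read_deg_table,
    read_homolog_map,
    read_splice_table,
    write_tsv,
)
from .motif_scan import (
    MotifAnnotation,
    MotifSpec,
    annotate_events,
    summarize_cohort,
    write_motif_tables,
)
from .ortho_match import (
    AlignmentParams,
    EventMatch,
    match_all,
    write_matches,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    master: list[MasterRecord]
    matches: list[EventMatch]
    clusters: list[EventCluster]
    calls: list[ConservationCall]
    upset: pd.DataFrame
    motif_annotations: list[MotifAnnotation]
    cluster_motifs: dict[int, dict[str, bool]]
    motif_cohort: dict[str, int]
    deg_calls: dict[str, list[DEGCall]]
    fractions: list[FractionResult]
    overlap: OverlapResult

    @property
    def conserved_clusters(self) -> list[EventCluster]:
        by_id = {c.cluster_id: c for c in self.clusters}
        return [by_id[c.cluster_id] for c in self.calls
                if c.verdict == CONSERVED]


@dataclass
class Workspace:
    """Everything the pipeline consumes, resolved into memory."""

    datasets: list[DatasetSpec]
    jc_tables: Mapping[str, Sequence]
    jcec_tables: Mapping[str, Sequence]
    genomes: Mapping[str, GenomeSource]       # species -> genome
    homologs: list[HomologPair]
    deg_tables: Mapping[str, Sequence]
    biotypes: BiotypeMap
    species_a: str = "mouse"
    species_b: str = "human"
    seed: int = 0
    config_hash: str = ""


def load_workspace(config_path: str | Path) -> Workspace:
    """Resolve a workspace ``config.yaml`` into memory, validating paths."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    config_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]
    genomes: dict[str, GenomeSource] = {}
    for genome_id, entry in cfg["genomes"].items():
        fasta = Path(entry["fasta"])
        if not fasta.exists():
            raise FileNotFoundError(f"genome fasta not found: {fasta}")
        genomes[entry["species"]] = GenomeSource.from_fasta(
            fasta, genome_id=genome_id
        )
    datasets: list[DatasetSpec] = []
    jc_tables: dict[str, list] = {}
    jcec_tables: dict[str, list] = {}
    deg_tables: dict[str, list] = {}
    for entry in cfg["datasets"]:
        spec = DatasetSpec(
            dataset_id=entry["dataset_id"],
            species=entry["species"],
            genome_id=entry["genome_id"],
            dpsi_orientation=entry.get(
                "dpsi_orientation", "depleted_minus_control"
            ),
        )
        for key in ("jc_table", "jcec_table", "deg_table"):
            if key in entry and not Path(entry[key]).exists():
                raise FileNotFoundError(
                    f"dataset {spec.dataset_id}: missing {key} "
                    f"{entry[key]}"
                )
        datasets.append(spec)
        jc = read_splice_table(entry["jc_table"], dialect="JC")
        jc_tables[spec.dataset_id] = jc.rows
        if "jcec_table" in entry:
            jcec = read_splice_table(entry["jcec_table"], dialect="JCEC")
            jcec_tables[spec.dataset_id] = jcec.rows
        if "deg_table" in entry:
            deg_tables[spec.dataset_id] = read_deg_table(entry["deg_table"])
    homologs = read_homolog_map(cfg["homolog_map"])
    biotypes = (read_biotypes(cfg["biotypes"])
                if "biotypes" in cfg else BiotypeMap())
    return Workspace(
        datasets=datasets,
        jc_tables=jc_tables,
        jcec_tables=jcec_tables,
        genomes=genomes,
        homologs=homologs,
        deg_tables=deg_tables,
        biotypes=biotypes,
        species_a=cfg.get("species_a", "mouse"),
        species_b=cfg.get("species_b", "human"),
        seed=int(cfg.get("seed", 0)),
        config_hash=config_hash,
    )


def workspace_from_study(study) -> Workspace:
    """Adapt an in-memory :class:`StudySim` to the pipeline input."""
    return Workspace(
        datasets=study.splice.datasets,
        jc_tables=study.splice.jc_tables,
        jcec_tables=study.splice.jcec_tables,
        genomes=study.genome_pair.genomes,
        homologs=study.homologs,
        deg_tables=study.deg.tables,
        biotypes=study.deg.biotypes,
        species_a=study.config.species_a,
        species_b=study.config.species_b,
        seed=study.config.seed,
    )


def run_study(
    workspace: Workspace,
    thresholds: FilterThresholds | None = None,
    align_params: AlignmentParams | None = None,
    criteria: ConservationCriteria | None = None,
    deg_thresholds: DEGThresholds | None = None,
    motif_spec: MotifSpec | None = None,
    match_mode: str = "global",
) -> PipelineResult:
    """Run every stage in dependency order and return all results."""
    thresholds = thresholds or FilterThresholds()
    align_params = align_params or AlignmentParams()
    criteria = criteria or ConservationCriteria(
        mouse_species=workspace.species_a,
        total_datasets=len(workspace.datasets),
    )
    deg_thresholds = deg_thresholds or DEGThresholds()
    motif_spec = motif_spec or MotifSpec()

    triples = [
        (spec,
         workspace.jc_tables[spec.dataset_id],
         workspace.jcec_tables.get(spec.dataset_id))
        for spec in workspace.datasets
    ]
    master = build_master_table(triples, thresholds)
    matches = match_all(
        master, workspace.homologs, workspace.genomes, align_params,
        species_a=workspace.species_a, species_b=workspace.species_b,
        mode=match_mode,
    )
    clusters = cluster_events(master, matches)
    dataset_species = {d.dataset_id: d.species for d in workspace.datasets}
    calls = call_all(clusters, criteria, dataset_species)
    upset = upset_counts(calls, clusters, criteria=criteria)

    # motif annotation of the conserved (inter- and intra-species) cohort
    cohort = [
        (cluster, call) for cluster, call in zip(clusters, calls)
        if call.verdict != NOT_CONSERVED
    ]
    keys: list[EventKey] = sorted(
        {k for cluster, _ in cohort for k in cluster.members}
    )
    annotations = annotate_events(keys, workspace.genomes, motif_spec)
    ann_by_key = {a.event_key: a for a in annotations}
    cluster_motifs: dict[int, dict[str, bool]] = {}
    for cluster, _ in cohort:
        member_anns = [ann_by_key[k] for k in cluster.members]
        cluster_motifs[cluster.cluster_id] = {
            "has_canonical": any(a.has_canonical for a in member_anns),
            "has_ca_rich": any(a.has_ca_rich for a in member_anns),
        }
    motif_cohort = {
        "n_events": len(cluster_motifs),
        "n_canonical": sum(
            flags["has_canonical"] for flags in cluster_motifs.values()
        ),
        "n_ca_rich": sum(
            flags["has_ca_rich"] for flags in cluster_motifs.values()
        ),
    }

    # expression comparison
    deg_calls = {
        dataset_id: make_calls(
            dataset_id, rows, workspace.biotypes, deg_thresholds
        )
        for dataset_id, rows in sorted(workspace.deg_tables.items())
    }
    fractions = [
        lncrna_fractions(calls_, workspace.biotypes, dataset_id=d)
        for d, calls_ in sorted(deg_calls.items())
    ]
    overlap = cross_dataset_deg_overlap(
        deg_calls, workspace.homologs,
        min_datasets=criteria.min_strict_datasets,
    )
    return PipelineResult(
        master=master,
        matches=matches,
        clusters=clusters,
        calls=calls,
        upset=upset,
        motif_annotations=annotations,
        cluster_motifs=cluster_motifs,
        motif_cohort=motif_cohort,
        deg_calls=deg_calls,
        fractions=fractions,
        overlap=overlap,
    )


def write_outputs(result: PipelineResult, workspace: Workspace,
                  outdir: str | Path) -> None:
    """Write every stage's TSV under ``outdir`` with provenance headers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"orthosplice v{__version__}\n"
        f"config_hash={workspace.config_hash or 'in-memory'} "
        f"seed={workspace.seed}"
    )
    write_master_table(result.master, outdir / "master_table.tsv", header)
    write_matches(result.matches, outdir / "matches.tsv", header)
    write_conservation(result.clusters, result.calls,
                       outdir / "conservation.tsv", header)
    write_tsv(result.upset, outdir / "intersections.tsv", header)
    write_motif_tables(result.motif_annotations,
                       outdir / "motif_hits.tsv",
                       outdir / "motif_summary.tsv", header)
    cohort_df = pd.DataFrame([result.motif_cohort])
    write_tsv(cohort_df, outdir / "motif_cohort.tsv", header)
    write_deg_outputs(result.deg_calls, result.fractions, result.overlap,
                      outdir, header)


def run_from_workspace(config_path: str | Path, outdir: str | Path,
                       **kwargs) -> PipelineResult:
    workspace = load_workspace(config_path)
    result = run_study(workspace, **kwargs)
    write_outputs(result, workspace, outdir)
    return result


# ---------------------------------------------------------------------------
# scoring against a planted-truth manifest
# ---------------------------------------------------------------------------

def score_against_truth(result: PipelineResult, truth) -> dict[str, float]:
    """Precision/recall of conserved-event recovery against the manifest."""
    conserved = result.conserved_clusters
    found_pairs = set()
    for cluster in conserved:
        genes = tuple(sorted({k.gene_id for k in cluster.members}))
        found_pairs.add(genes)
    true_pairs = {
        tuple(sorted((e.gene_id_a, e.gene_id_b)))
        for e in truth.planted_events
    }
    tp = len(found_pairs & true_pairs)
    precision = tp / len(found_pairs) if found_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return {
        "n_conserved_found": len(conserved),
        "n_planted": len(true_pairs),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


def upset_matches_truth(result: PipelineResult, truth) -> bool:
    """Does the computed intersection table equal the planted pattern?"""
    expected = truth.expected_upset()
    observed: dict[tuple[str, ...], int] = {}
    for _, row in result.upset.iterrows():
        observed[tuple(row["dataset_set"].split(","))] = int(row["count"])
    return observed == expected
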