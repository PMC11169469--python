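"""Synthetic study generator with planted ground truth.

Emulates the structure of the nine-dataset hnRNPL-depletion comparison
without any external downloads: two "genomes" carrying ortholog gene pairs
with exon-triplet architectures at a controlled per-base divergence, nine
skipped-exon result tables (3 mouse, 6 human) in both rMATS dialects with
planted conserved events among decoys, and DESeq2-style DEG tables with
planted cross-species shared genes and exact per-dataset lncRNA fractions.

Every quantity a pipeline stage should recover is recorded in a
:class:`GroundTruth` manifest, so precision/recall of each stage can be
scored without re-deriving the truth.  Substitutions always change the
base, so the expected per-base exon identity at divergence ``d`` is
``1 - d`` (indels, off by default, additionally shift coordinates).  All
draws come from seeded ``numpy`` generators; equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diff_events import EventKey
from .io_tables import (
    BiotypeMap,
    DatasetSpec,
    DEGRow,
    GenomeSource,
    HomologPair,
    SpliceTableRow,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the real study's design: nine depletion datasets
    (3 mouse, 6 human), strict-pass statistics planted in ≥6 datasets
    including ≥1 mouse dataset, junction coverage well above the 10-read
    floor, and a canonical-motif fraction matching the reported 45/70
    events carrying ACACACA/ACACAAA among conserved events (every planted
    event carries at least a bounded-gap CA repeat).
    """

    seed: int = 0
    n_datasets_mouse: int = 3
    n_datasets_human: int = 6
    n_genes: int = 160
    n_planted_conserved: int = 20
    n_decoy_events: int = 100
    divergence: float = 0.05
    indel_prob: float = 0.0
    exon_len_range: tuple[int, int] = (60, 300)
    intron_len_range: tuple[int, int] = (150, 600)
    planted_dpsi_range: tuple[float, float] = (0.15, 0.80)
    planted_fdr_range: tuple[float, float] = (1e-4, 0.05)
    junction_mean: float = 30.0
    junction_dispersion: float = 10.0
    n_replicates: int = 2
    planted_min_datasets: int = 6
    canonical_motif_fraction: float = 45 / 70
    flip_datasets: tuple[str, ...] = ("human_2",)
    species_a: str = "mouse"
    species_b: str = "human"
    # differential-expression block
    n_planted_shared_degs: int = 2
    deg_up_per_dataset: int = 20
    deg_down_per_dataset: int = 20
    lnc_fraction_up: float = 0.45
    lnc_fraction_down: float = 0.15
    n_null_deg_genes: int = 60
    deg_planted_min_datasets: int = 6

    def __post_init__(self) -> None:
        if self.n_planted_conserved + self.n_decoy_events > self.n_genes:
            raise ConfigError(
                "n_planted_conserved + n_decoy_events exceeds n_genes"
            )
        for lo, hi in (self.exon_len_range, self.intron_len_range):
            if not 0 < lo <= hi:
                raise ConfigError("length ranges must satisfy 0 < lo <= hi")
        if self.exon_len_range[0] < 20:
            raise ConfigError("exons shorter than 20 nt cannot hold motifs")
        lo, hi = self.planted_dpsi_range
        if not 0.10 <= lo <= hi <= 0.95:
            raise ConfigError("planted |ΔPSI| range must lie in [0.10,0.95]")
        lo, hi = self.planted_fdr_range
        if not 0 <= lo <= hi < 0.1:
            raise ConfigError("planted FDR range must lie below 0.1")
        if not 0 <= self.divergence <= 0.5:
            raise ConfigError("divergence must lie in [0, 0.5]")
        if not 0 <= self.indel_prob <= 0.1:
            raise ConfigError("indel_prob must lie in [0, 0.1]")
        if self.junction_mean < 30 / 2 and self.junction_mean < 10:
            raise ConfigError("junction_mean must keep planted coverage ≥10")
        n_total = self.n_datasets_mouse + self.n_datasets_human
        if not 1 <= self.planted_min_datasets <= n_total:
            raise ConfigError("planted_min_datasets out of range")

    @property
    def n_datasets(self) -> int:
        return self.n_datasets_mouse + self.n_datasets_human

    def dataset_specs(self) -> list[DatasetSpec]:
        specs = []
        for i in range(self.n_datasets_mouse):
            did = f"{self.species_a}_{i + 1}"
            specs.append(DatasetSpec(
                dataset_id=did, species=self.species_a, genome_id="genomeA",
                dpsi_orientation=(
                    "control_minus_depleted" if did in self.flip_datasets
                    else "depleted_minus_control"
                ),
            ))
        for i in range(self.n_datasets_human):
            did = f"{self.species_b}_{i + 1}"
            specs.append(DatasetSpec(
                dataset_id=did, species=self.species_b, genome_id="genomeB",
                dpsi_orientation=(
                    "control_minus_depleted" if did in self.flip_datasets
                    else "depleted_minus_control"
                ),
            ))
        return specs


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedEvent:
    gene_id_a: str
    gene_id_b: str
    key_a: EventKey
    key_b: EventKey
    datasets: tuple[str, ...]     # datasets with strict-pass statistics
    sign: int                     # oriented ΔPSI sign (depleted − control)
    has_canonical: bool
    has_ca_rich: bool = True


@dataclass
class DecoyEvent:
    gene_id: str                  # species-A gene id of the gene pair
    datasets: tuple[str, ...]
    decoy_class: str              # null_fdr | loose_fdr | low_dpsi | low_cov


@dataclass
class PlantedDEG:
    gene_id_a: str
    gene_id_b: str
    direction: str
    datasets: tuple[str, ...]


@dataclass
class GroundTruth:
    """Manifest sufficient to score every pipeline stage."""

    planted_events: list[PlantedEvent] = field(default_factory=list)
    decoy_events: list[DecoyEvent] = field(default_factory=list)
    planted_degs: list[PlantedDEG] = field(default_factory=list)
    lnc_fractions: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )                             # dataset -> (fraction_up, fraction_down)

    def expected_upset(self) -> dict[tuple[str, ...], int]:
        """Planted strict-pass intersection pattern (set -> cluster count)."""
        counts: dict[tuple[str, ...], int] = {}
        for ev in self.planted_events:
            key = tuple(sorted(ev.datasets))
            counts[key] = counts.get(key, 0) + 1
        return counts

    @property
    def conserved_gene_pairs(self) -> set[tuple[str, str]]:
        return {(e.gene_id_a, e.gene_id_b) for e in self.planted_events}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_events": [
                {**asdict(e),
                 "key_a": str(e.key_a), "key_b": str(e.key_b)}
                for e in self.planted_events
            ],
            "decoy_events": [asdict(d) for d in self.decoy_events],
            "planted_degs": [asdict(d) for d in self.planted_degs],
            "lnc_fractions": self.lnc_fractions,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls()
        for e in payload["planted_events"]:
            truth.planted_events.append(PlantedEvent(
                gene_id_a=e["gene_id_a"], gene_id_b=e["gene_id_b"],
                key_a=EventKey.parse(e["key_a"]),
                key_b=EventKey.parse(e["key_b"]),
                datasets=tuple(e["datasets"]), sign=int(e["sign"]),
                has_canonical=bool(e["has_canonical"]),
                has_ca_rich=bool(e["has_ca_rich"]),
            ))
        for d in payload["decoy_events"]:
            truth.decoy_events.append(DecoyEvent(
                gene_id=d["gene_id"], datasets=tuple(d["datasets"]),
                decoy_class=d["decoy_class"],
            ))
        for d in payload["planted_degs"]:
            truth.planted_degs.append(PlantedDEG(
                gene_id_a=d["gene_id_a"], gene_id_b=d["gene_id_b"],
                direction=d["direction"], datasets=tuple(d["datasets"]),
            ))
        truth.lnc_fractions = {
            k: tuple(v) for k, v in payload["lnc_fractions"].items()
        }
        return truth


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

@dataclass
class GenePair:
    """One ortholog gene with its event architecture in both species."""

    gene_id_a: str
    gene_id_b: str
    key_a: EventKey
    key_b: EventKey
    role: str = "null"            # planted | decoy | null
    canonical_planted: bool = False


@dataclass
class GenomePairSim:
    genome_a: GenomeSource
    genome_b: GenomeSource
    homologs: list[HomologPair]
    genes: list[GenePair]

    @property
    def genomes(self) -> dict[str, GenomeSource]:
        """Species label -> genome, keyed by the gene keys' species."""
        sp_a = self.genes[0].key_a.species
        sp_b = self.genes[0].key_b.species
        return {sp_a: self.genome_a, sp_b: self.genome_b}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_seq_no_ca(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no CA dinucleotide (motif-free background)."""
    out = []
    prev = ""
    for _ in range(length):
        if prev == "C":
            ch = "CGT"[rng.integers(0, 3)]
        else:
            ch = _BASES[rng.integers(0, 4)]
        out.append(ch)
        prev = ch
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, divergence: float,
            indel_prob: float) -> str:
    """iid substitutions (always to a different base) and optional indels."""
    out = []
    for ch in seq:
        if indel_prob > 0 and rng.random() < indel_prob / 2:
            continue                      # deletion
        if divergence > 0 and rng.random() < divergence:
            alternatives = [b for b in "ACGT" if b != ch]
            ch = alternatives[rng.integers(0, len(alternatives))]
        out.append(ch)
        if indel_prob > 0 and rng.random() < indel_prob / 2:
            out.append("ACGT"[rng.integers(0, 4)])  # insertion
    return "".join(out) or "A"


def _plant(seq: str, motif: str, offset_frac: float = 0.4) -> str:
    # guard Ts keep flanking bases from extending the motif into a longer
    # CA-rich word (e.g. A + CACACA would create a spurious ACACACA)
    motif = f"T{motif}T"
    pos = max(0, min(int(len(seq) * offset_frac), len(seq) - len(motif)))
    return seq[:pos] + motif + seq[pos + len(motif):]


def _assemble_contig(five: str, i1: str, target: str, i2: str, three: str,
                     strand: str, pad: str, pad2: str,
                     ) -> tuple[str, tuple[int, int], tuple[int, int],
                                tuple[int, int]]:
    """Lay the transcript segments onto a plus-strand contig.

    Returns (contig_seq, target_iv, left_flank_iv, right_flank_iv) with
    genomic half-open intervals; for '-' the transcript is written reverse
    complemented, so the genomic-left flank is the 3'-adjacent exon.
    """
    if strand == "+":
        order = [five, i1, target, i2, three]
    else:
        order = [reverse_complement(s)
                 for s in (three, i2, target, i1, five)]
    segs = [pad] + order + [pad2]
    coords = []
    pos = 0
    for s in segs:
        coords.append((pos, pos + len(s)))
        pos += len(s)
    contig = "".join(segs)
    left_iv, target_iv, right_iv = coords[1], coords[3], coords[5]
    return contig, target_iv, left_iv, right_iv


def simulate_genome_pair(config: SimConfig) -> GenomePairSim:
    """Two genomes of ortholog exon-triplet genes at controlled divergence.

    One contig per gene; species-B segments derive from species-A by iid
    substitution/indels; strands are assigned independently per species.
    Planted genes (the future conserved events) get motif-free backgrounds
    with hnRNPL motifs injected into both species: a bounded-gap CA repeat
    in the upstream intron of every planted gene and the ACACACA canonical
    consensus in the target exon of a ``canonical_motif_fraction`` subset.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_genes
    perm = rng.permutation(n)
    roles = {}
    for idx in perm[:config.n_planted_conserved]:
        roles[int(idx)] = "planted"
    for idx in perm[config.n_planted_conserved:
                    config.n_planted_conserved + config.n_decoy_events]:
        roles[int(idx)] = "decoy"
    planted_order = [int(i) for i in perm[:config.n_planted_conserved]]
    n_canonical = round(
        config.canonical_motif_fraction * config.n_planted_conserved
    )
    canonical_set = set(planted_order[:n_canonical])

    contigs_a: dict[str, str] = {}
    contigs_b: dict[str, str] = {}
    genes: list[GenePair] = []
    homologs: list[HomologPair] = []
    elo, ehi = config.exon_len_range
    ilo, ihi = config.intron_len_range
    for g in range(n):
        role = roles.get(g, "null")
        gid_a = f"mmG{g:04d}"
        gid_b = f"hsG{g:04d}"
        sampler = _random_seq_no_ca if role == "planted" else _random_seq
        exon_lens = rng.integers(elo, ehi + 1, size=3)
        intron_lens = rng.integers(ilo, ihi + 1, size=2)
        five = sampler(rng, int(exon_lens[0]))
        target = sampler(rng, int(exon_lens[1]))
        three = sampler(rng, int(exon_lens[2]))
        i1 = sampler(rng, int(intron_lens[0]))
        i2 = sampler(rng, int(intron_lens[1]))
        # species-B transcript segments derive from species A
        segs_b = [
            _mutate(rng, s, config.divergence, config.indel_prob)
            for s in (five, i1, target, i2, three)
        ]
        five_b, i1_b, target_b, i2_b, three_b = segs_b
        if role == "planted":
            canonical = g in canonical_set
            i1, i1_b = _plant(i1, "CACACA"), _plant(i1_b, "CACACA")
            if canonical:
                target = _plant(target, "ACACACA")
                target_b = _plant(target_b, "ACACACA")
        else:
            canonical = False
        strand_a = "+-"[rng.integers(0, 2)]
        strand_b = "+-"[rng.integers(0, 2)]
        chrom_a = f"chrA_{g:04d}"
        chrom_b = f"chrB_{g:04d}"
        pad_a = (_random_seq(rng, 50), _random_seq(rng, 50))
        pad_b = (_random_seq(rng, 50), _random_seq(rng, 50))
        contig_a, t_a, l_a, r_a = _assemble_contig(
            five, i1, target, i2, three, strand_a, *pad_a
        )
        contig_b, t_b, l_b, r_b = _assemble_contig(
            five_b, i1_b, target_b, i2_b, three_b, strand_b, *pad_b
        )
        contigs_a[chrom_a] = contig_a
        contigs_b[chrom_b] = contig_b
        key_a = EventKey(config.species_a, gid_a, chrom_a, strand_a,
                         t_a, l_a, r_a)
        key_b = EventKey(config.species_b, gid_b, chrom_b, strand_b,
                         t_b, l_b, r_b)
        genes.append(GenePair(gid_a, gid_b, key_a, key_b, role=role,
                              canonical_planted=canonical))
        homologs.append(HomologPair(gid_a, gid_b))
    return GenomePairSim(
        genome_a=GenomeSource("genomeA", contigs_a),
        genome_b=GenomeSource("genomeB", contigs_b),
        homologs=homologs,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# splice tables
# ---------------------------------------------------------------------------

@dataclass
class SpliceSim:
    datasets: list[DatasetSpec]
    jc_tables: dict[str, list[SpliceTableRow]]
    jcec_tables: dict[str, list[SpliceTableRow]]
    truth: GroundTruth


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float,
               size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _draw_counts(rng: np.random.Generator, config: SimConfig,
                 mean: float, require_min: float | None,
                 require_max: float | None = None
                 ) -> tuple[tuple[int, ...], ...]:
    """Per-replicate (IJC, SJC) draws with a bound on the average coverage."""
    nrep = config.n_replicates
    for _ in range(200):
        ijc1 = _nb_counts(rng, mean, config.junction_dispersion, nrep)
        sjc1 = _nb_counts(rng, mean, config.junction_dispersion, nrep)
        ijc2 = _nb_counts(rng, mean, config.junction_dispersion, nrep)
        sjc2 = _nb_counts(rng, mean, config.junction_dispersion, nrep)
        avg = (ijc1 + sjc1).sum() + (ijc2 + sjc2).sum()
        avg /= 2 * nrep
        if require_min is not None and avg < require_min:
            continue
        if require_max is not None and avg >= require_max:
            continue
        return tuple(map(tuple, (ijc1, sjc1, ijc2, sjc2)))
    raise ConfigError("could not draw junction counts within bounds")


def _subset_with_mouse(rng: np.random.Generator, config: SimConfig,
                       size: int) -> tuple[str, ...]:
    """A dataset subset of the given size containing ≥1 mouse dataset."""
    mouse = [f"{config.species_a}_{i + 1}"
             for i in range(config.n_datasets_mouse)]
    human = [f"{config.species_b}_{i + 1}"
             for i in range(config.n_datasets_human)]
    lo = max(1, size - len(human))
    hi = min(len(mouse), size)
    n_mouse = int(rng.integers(lo, hi + 1))
    chosen = list(rng.choice(mouse, size=n_mouse, replace=False))
    chosen += list(rng.choice(human, size=size - n_mouse, replace=False))
    return tuple(sorted(chosen))


def _row_from_key(key: EventKey, row_id: int, gene_symbol: str,
                  counts, pvalue: float, fdr: float, dpsi: float
                  ) -> SpliceTableRow:
    # rMATS prints upstream/downstream in transcript orientation
    if key.strand == "+":
        up, down = key.left_flank, key.right_flank
    else:
        up, down = key.right_flank, key.left_flank
    ijc1, sjc1, ijc2, sjc2 = counts
    return SpliceTableRow(
        event_row_id=row_id,
        gene_id=key.gene_id,
        gene_symbol=gene_symbol,
        chrom=key.chrom,
        strand=key.strand,
        exon_start=key.target[0],
        exon_end=key.target[1],
        upstream_start=up[0],
        upstream_end=up[1],
        downstream_start=down[0],
        downstream_end=down[1],
        ijc_group1=ijc1,
        sjc_group1=sjc1,
        ijc_group2=ijc2,
        sjc_group2=sjc2,
        pvalue=pvalue,
        fdr=fdr,
        inc_level_diff=dpsi,
    )


def simulate_splice_tables(config: SimConfig, pair: GenomePairSim
                           ) -> SpliceSim:
    """Nine datasets of JC/JCEC rows with planted conserved events.

    Planted events carry strict-pass statistics (concordant oriented ΔPSI
    sign, FDR below 0.1, coverage ≥ 10) in a ≥6-dataset subset with ≥1
    mouse dataset and are absent elsewhere; decoys carry one of four
    sub-threshold statistic classes in ≤4 datasets.  Tables listed in
    ``flip_datasets`` are written in the (control − depleted) orientation.
    """
    rng = np.random.default_rng([config.seed, 2])
    specs = config.dataset_specs()
    spec_by_id = {s.dataset_id: s for s in specs}
    jc: dict[str, list[SpliceTableRow]] = {s.dataset_id: [] for s in specs}
    jcec: dict[str, list[SpliceTableRow]] = {s.dataset_id: [] for s in specs}
    truth = GroundTruth()
    row_ids = {s.dataset_id: 0 for s in specs}

    def emit(dataset_id: str, key: EventKey, symbol: str, dpsi: float,
             fdr: float, coverage_mean: float, low_coverage: bool = False):
        spec = spec_by_id[dataset_id]
        written_dpsi = -dpsi if spec.flip_sign else dpsi
        counts = _draw_counts(
            rng, config, coverage_mean,
            require_min=None if low_coverage else 10.0,
            require_max=10.0 if low_coverage else None,
        )
        extra = rng.poisson(5, size=4 * config.n_replicates)
        counts_ec = tuple(
            tuple(int(c + e) for c, e in zip(group, extra[k::4]))
            for k, group in enumerate(counts)
        )
        rid = row_ids[dataset_id]
        row_ids[dataset_id] += 1
        dpsi_jc = float(np.clip(
            written_dpsi + rng.normal(0, 0.01), -1, 1
        ))
        fdr_jc = float(min(1.0, fdr * rng.uniform(0.5, 2.0)))
        jc[dataset_id].append(_row_from_key(
            key, rid, symbol, counts, pvalue=fdr_jc / 2, fdr=fdr_jc,
            dpsi=dpsi_jc,
        ))
        jcec[dataset_id].append(_row_from_key(
            key, rid, symbol, counts_ec, pvalue=fdr / 2, fdr=fdr,
            dpsi=written_dpsi,
        ))

    for gene in pair.genes:
        if gene.role == "planted":
            size = int(rng.integers(config.planted_min_datasets,
                                    config.n_datasets + 1))
            subset = _subset_with_mouse(rng, config, size)
            sign = 1 if rng.random() < 0.5 else -1
            for dataset_id in subset:
                spec = spec_by_id[dataset_id]
                key = (gene.key_a if spec.species == config.species_a
                       else gene.key_b)
                dpsi = sign * rng.uniform(*config.planted_dpsi_range)
                fdr = rng.uniform(*config.planted_fdr_range)
                emit(dataset_id, key, gene.gene_id_a.replace("G", "Sym"),
                     dpsi, fdr, config.junction_mean)
            truth.planted_events.append(PlantedEvent(
                gene_id_a=gene.gene_id_a, gene_id_b=gene.gene_id_b,
                key_a=gene.key_a, key_b=gene.key_b,
                datasets=subset, sign=sign,
                has_canonical=gene.canonical_planted,
            ))
        elif gene.role == "decoy":
            n_ds = int(rng.integers(1, 5))
            subset = tuple(sorted(rng.choice(
                [s.dataset_id for s in specs], size=n_ds, replace=False
            )))
            decoy_class = ("null_fdr", "loose_fdr", "low_dpsi",
                           "low_cov")[int(rng.integers(0, 4))]
            for dataset_id in subset:
                spec = spec_by_id[dataset_id]
                key = (gene.key_a if spec.species == config.species_a
                       else gene.key_b)
                if decoy_class == "null_fdr":
                    fdr = rng.uniform(0.2, 1.0)
                    dpsi = rng.uniform(-0.9, 0.9)
                    emit(dataset_id, key, gene.gene_id_a, dpsi, fdr,
                         config.junction_mean)
                elif decoy_class == "loose_fdr":
                    fdr = rng.uniform(0.1, 0.2)
                    dpsi = rng.uniform(-0.9, 0.9)
                    emit(dataset_id, key, gene.gene_id_a, dpsi, fdr,
                         config.junction_mean)
                elif decoy_class == "low_dpsi":
                    fdr = rng.uniform(*config.planted_fdr_range)
                    sign = 1 if rng.random() < 0.5 else -1
                    dpsi = sign * rng.uniform(0.0, 0.09)
                    emit(dataset_id, key, gene.gene_id_a, dpsi, fdr,
                         config.junction_mean)
                else:  # low coverage, otherwise significant
                    fdr = rng.uniform(*config.planted_fdr_range)
                    sign = 1 if rng.random() < 0.5 else -1
                    dpsi = sign * rng.uniform(0.15, 0.8)
                    emit(dataset_id, key, gene.gene_id_a, dpsi, fdr,
                         4.0, low_coverage=True)
            truth.decoy_events.append(DecoyEvent(
                gene_id=gene.gene_id_a, datasets=subset,
                decoy_class=decoy_class,
            ))
    return SpliceSim(datasets=specs, jc_tables=jc, jcec_tables=jcec,
                     truth=truth)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

@dataclass
class DEGSim:
    tables: dict[str, list[DEGRow]]
    biotypes: BiotypeMap
    homologs: list[HomologPair]   # ortholog pairs of the DEG gene universe
    truth: GroundTruth


def _exact_fraction(value: float) -> Fraction:
    frac = Fraction(value).limit_denominator(1000)
    if not 0 <= frac <= 1:
        raise ConfigError(f"lncRNA fraction {value} outside [0, 1]")
    return frac


def simulate_deg_tables(config: SimConfig,
                        homologs: Sequence[HomologPair] | None = None
                        ) -> DEGSim:
    """DESeq2-style tables with planted shared genes and exact lncRNA mixes.

    The DEG gene universe is generated here (ids disjoint from the genome
    genes): per dataset an exclusive pool of up/down genes sized so the
    lncRNA fraction among up (down) calls is exactly the configured value,
    a shared pool of null genes, and ``n_planted_shared_degs`` ortholog
    gene pairs significant with one concordant direction in a ≥6-dataset
    subset spanning both species.  The ortholog pairs of the planted genes
    are returned and must be merged into the homolog map used by the
    overlap stage; ``homologs``, if given, is included in the returned
    list unchanged.
    """
    rng = np.random.default_rng([config.seed, 3])
    specs = config.dataset_specs()
    truth = GroundTruth()
    f_up = _exact_fraction(config.lnc_fraction_up)
    f_down = _exact_fraction(config.lnc_fraction_down)
    tables: dict[str, list[DEGRow]] = {s.dataset_id: [] for s in specs}
    biotypes: dict[str, str] = {}
    deg_homologs: list[HomologPair] = list(homologs or [])

    # planted cross-species shared genes (protein_coding)
    planted_by_dataset: dict[str, list[tuple[str, str]]] = {
        s.dataset_id: [] for s in specs
    }
    for i in range(config.n_planted_shared_degs):
        gid_a, gid_b = f"mmS{i:03d}", f"hsS{i:03d}"
        deg_homologs.append(HomologPair(gid_a, gid_b))
        biotypes[gid_a] = biotypes[gid_b] = "protein_coding"
        size = int(rng.integers(config.deg_planted_min_datasets,
                                config.n_datasets + 1))
        subset = _subset_with_mouse(rng, config, size)
        direction = "up" if rng.random() < 0.5 else "down"
        sign = 1 if direction == "up" else -1
        for spec in specs:
            gid = gid_a if spec.species == config.species_a else gid_b
            if spec.dataset_id in subset:
                lfc = sign * (math.log2(1.5) + rng.uniform(0.2, 1.2))
                padj = rng.uniform(0.001, 0.05)
                planted_by_dataset[spec.dataset_id].append(
                    (gid, direction)
                )
            else:
                lfc = rng.uniform(-0.3, 0.3)
                padj = rng.uniform(0.3, 1.0)
            tables[spec.dataset_id].append(
                DEGRow(gene_id=gid, log2fc=float(lfc), padj=float(padj))
            )
        truth.planted_degs.append(PlantedDEG(
            gene_id_a=gid_a, gene_id_b=gid_b,
            direction=direction, datasets=subset,
        ))

    # per-dataset exclusive up/down pools with exact lncRNA fractions
    for spec in specs:
        rows = tables[spec.dataset_id]
        fracs = []
        for direction, frac, base in (
            ("up", f_up, config.deg_up_per_dataset),
            ("down", f_down, config.deg_down_per_dataset),
        ):
            k_planted = sum(
                1 for _, d in planted_by_dataset[spec.dataset_id]
                if d == direction
            )
            den = frac.denominator
            n_total = den * math.ceil((base + k_planted) / den)
            n_lnc = int(frac * n_total)
            n_coding = n_total - n_lnc - k_planted
            if n_coding < 0:
                raise ConfigError("lncRNA fraction incompatible with "
                                  "planted shared genes")
            sp = "mm" if spec.species == config.species_a else "hs"
            sign = 1 if direction == "up" else -1
            for j in range(n_lnc + n_coding):
                gid = f"{sp}D_{spec.dataset_id}_{direction}{j:03d}"
                biotypes[gid] = "lncRNA" if j < n_lnc else "protein_coding"
                lfc = sign * (math.log2(1.5) + rng.uniform(0.1, 2.0))
                rows.append(DEGRow(gene_id=gid, log2fc=float(lfc),
                                   padj=float(rng.uniform(0.001, 0.05))))
            fracs.append(n_lnc / n_total)
        truth.lnc_fractions[spec.dataset_id] = (fracs[0], fracs[1])

    # shared null genes per species
    for sp_label, sp in ((config.species_a, "mm"), (config.species_b, "hs")):
        for j in range(config.n_null_deg_genes):
            gid = f"{sp}D_null{j:03d}"
            biotypes[gid] = ("lncRNA" if j % 4 == 0 else "protein_coding")
            for spec in specs:
                if spec.species != sp_label:
                    continue
                tables[spec.dataset_id].append(DEGRow(
                    gene_id=gid,
                    log2fc=float(rng.uniform(-0.4, 0.4)),
                    padj=float(rng.uniform(0.2, 1.0)),
                ))
    return DEGSim(tables=tables, biotypes=BiotypeMap(biotypes),
                  homologs=deg_homologs, truth=truth)


# ---------------------------------------------------------------------------
# full study + workspace writer
# ---------------------------------------------------------------------------

@dataclass
class StudySim:
    config: SimConfig
    genome_pair: GenomePairSim
    splice: SpliceSim
    deg: DEGSim

    @property
    def truth(self) -> GroundTruth:
        merged = GroundTruth(
            planted_events=self.splice.truth.planted_events,
            decoy_events=self.splice.truth.decoy_events,
            planted_degs=self.deg.truth.planted_degs,
            lnc_fractions=self.deg.truth.lnc_fractions,
        )
        return merged

    @property
    def homologs(self) -> list[HomologPair]:
        return self.genome_pair.homologs + self.deg.homologs


def simulate_study(config: SimConfig) -> StudySim:
    """Generate the full synthetic study (genomes, splice tables, DEGs)."""
    pair = simulate_genome_pair(config)
    splice = simulate_splice_tables(config, pair)
    deg = simulate_deg_tables(config)
    return StudySim(config=config, genome_pair=pair, splice=splice, deg=deg)


def _se_frame(rows: Sequence[SpliceTableRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        psi_base = 0.5
        records.append({
            "ID": r.event_row_id,
            "GeneID": r.gene_id,
            "geneSymbol": r.gene_symbol,
            "chr": r.chrom,
            "strand": r.strand,
            "exonStart_0base": r.exon_start,
            "exonEnd": r.exon_end,
            "upstreamES": r.upstream_start,
            "upstreamEE": r.upstream_end,
            "downstreamES": r.downstream_start,
            "downstreamEE": r.downstream_end,
            "IJC_SAMPLE_1": ",".join(map(str, r.ijc_group1)),
            "SJC_SAMPLE_1": ",".join(map(str, r.sjc_group1)),
            "IJC_SAMPLE_2": ",".join(map(str, r.ijc_group2)),
            "SJC_SAMPLE_2": ",".join(map(str, r.sjc_group2)),
            "IncFormLen": 100,
            "SkipFormLen": 50,
            "PValue": r.pvalue,
            "FDR": r.fdr,
            "IncLevel1": ",".join(
                f"{min(1.0, max(0.0, psi_base + (r.inc_level_diff or 0))):.3f}"
                for _ in r.ijc_group1
            ),
            "IncLevel2": ",".join(f"{psi_base:.3f}" for _ in r.ijc_group2),
            "IncLevelDifference": r.inc_level_diff,
        })
    return pd.DataFrame(records)


def write_workspace(study: StudySim, outdir: str | Path) -> Path:
    """Write every format the readers consume, plus manifest and config.

    Layout: genomes/ (FASTA), splice/ (SE.MATS.{JC,JCEC}.txt per dataset),
    deg/ (per-dataset DEG TSV), homologs.tsv, biotypes.tsv,
    ground_truth.json and a ready-to-run ``config.yaml``.
    """
    import yaml

    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "splice").mkdir(exist_ok=True)
    (outdir / "deg").mkdir(exist_ok=True)
    study.genome_pair.genome_a.to_fasta(outdir / "genomes" / "genomeA.fa")
    study.genome_pair.genome_b.to_fasta(outdir / "genomes" / "genomeB.fa")
    dataset_entries = []
    for spec in study.splice.datasets:
        jc_path = outdir / "splice" / f"{spec.dataset_id}.SE.MATS.JC.txt"
        jcec_path = outdir / "splice" / f"{spec.dataset_id}.SE.MATS.JCEC.txt"
        _se_frame(study.splice.jc_tables[spec.dataset_id]).to_csv(
            jc_path, sep="\t", index=False)
        _se_frame(study.splice.jcec_tables[spec.dataset_id]).to_csv(
            jcec_path, sep="\t", index=False)
        deg_path = outdir / "deg" / f"{spec.dataset_id}.deg.tsv"
        pd.DataFrame([{
            "gene_id": r.gene_id,
            "log2FoldChange": r.log2fc,
            "padj": "NA" if r.padj is None else r.padj,
        } for r in study.deg.tables[spec.dataset_id]]).to_csv(
            deg_path, sep="\t", index=False)
        dataset_entries.append({
            "dataset_id": spec.dataset_id,
            "species": spec.species,
            "genome_id": spec.genome_id,
            "dpsi_orientation": spec.dpsi_orientation,
            "jc_table": str(jc_path),
            "jcec_table": str(jcec_path),
            "deg_table": str(deg_path),
        })
    with open(outdir / "homologs.tsv", "w") as fh:
        fh.write("gene_id_mouse\tgene_id_human\n")
        for p in study.homologs:
            fh.write(f"{p.gene_id_species_a}\t{p.gene_id_species_b}\n")
    with open(outdir / "biotypes.tsv", "w") as fh:
        fh.write("gene_id\tbiotype\n")
        for gid, bt in sorted(study.deg.biotypes.items()):
            fh.write(f"{gid}\t{bt}\n")
    study.truth.to_json(outdir / "ground_truth.json")
    run_config = {
        "seed": study.config.seed,
        "species_a": study.config.species_a,
        "species_b": study.config.species_b,
        "genomes": {
            "genomeA": {"species": study.config.species_a,
                        "fasta": str(outdir / "genomes" / "genomeA.fa")},
            "genomeB": {"species": study.config.species_b,
                        "fasta": str(outdir / "genomes" / "genomeB.fa")},
        },
        "homolog_map": str(outdir / "homologs.tsv"),
        "biotypes": str(outdir / "biotypes.tsv"),
        "datasets": dataset_entries,
        "thresholds": {},
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return outdir / "config.yaml"
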