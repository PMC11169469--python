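# Methods notes

## Scope and data model

The pipeline starts from rMATS-style skipped-exon result tables; read
alignment, PSI estimation and the splicing test itself are upstream
producers of those tables and are not re-implemented. An event is
identified by the genomic coordinates of its exon triplet
(`EventKey`): species, gene, chromosome, strand, and the three half-open
intervals. The `upstream*`/`downstream*` columns are parsed verbatim and
canonicalized to genomic-left/right flanks; transcript 5′/3′ roles are
resolved from the strand only when sequences are extracted. This keeps
parsing independent of rMATS's strand-dependent column semantics.

Two table dialects are consumed per dataset: JC (junction counts only)
supplies the coverage filter — the mean of IJC+SJC over all replicates of
both groups — and JCEC (junction + exon body) supplies ΔPSI, p and FDR.
When only JC is given it supplies both. JC/JCEC rows are joined by exact
event key; quantified rows without a JC counterpart keep coverage 0 (they
can be detected at the loose FDR cutoff but can never pass the strict
coverage criterion) and are logged, as are rows with missing ΔPSI, which
are excluded from the master table.

## Thresholds and boundary semantics

| parameter | default | unit/meaning |
|---|---|---|
| `min_avg_jc` | 10 | average junction reads, inclusive (≥) |
| `min_abs_dpsi` / `max_abs_dpsi` | 0.10 / 0.95 | ΔPSI band, inclusive |
| `fdr_strict` / `fdr_loose` | 0.1 / 0.2 | exclusive (<) |
| `identity_threshold` | 0.70 | per-exon alignment identity, inclusive |
| `min_strict_datasets` | 6 of 9 | conservation support |
| DEG `min_fold_change` / `max_padj` | 1.5 (inclusive) / 0.1 (exclusive) | |

Inclusive/exclusive choices follow the printed inequalities (≥/≤ vs <)
and are pinned by dedicated boundary tests. ΔPSI is normalized to
(depleted − control) at load via a per-dataset orientation flag, so
"more included upon depletion" is always positive.

## Alignment

The pairwise step is a global Needleman–Wunsch with affine gaps (Gotoh's
three-state recurrence). Scores: match +1, mismatch −1, and a gap of
length L costs `gap_open + L·gap_extend` = −2 − L. The acceptance
quantity of the matching rule is identity, not score, so a simple
symmetric scheme suffices; all four numbers are configurable. Identity is
matched columns divided by total alignment columns (gap columns count in
the denominator, penalizing length-discrepant exons); an alternative
shorter-sequence denominator is switchable. `N` mismatches everything,
including `N`. Traceback ties are broken deterministically — diagonal,
then up (gap in the second sequence), then left — applied both to the
final-state choice and to each predecessor choice, making scores *and*
identities platform-stable. The kernel is plain Python over numpy arrays,
JIT-compiled by numba when available; tests cross-check scores against
Biopython's independent aligner under the equivalent gap parameterization
(open = −3 for the first gap base, −1 per extension).

## Matching

Within one ortholog gene pair, all cross-species event pairs are scored
(target↔target, 5′↔5′, 3′↔3′); a pair is eligible iff all three
identities ≥ 0.70 (conjunctive). Acceptance is greedy best-total-score
first with removal and repetition; ties fall back to the
lexicographically smallest key pair. The prose description of the
original procedure is compatible with either a global best-first order or
a per-mouse-event iteration; the global order is the default because it
is order-independent, and the per-event variant is available behind
`mode="per_event"`. For ≤6×6 instances the iterative greedy provably
equals a single sweep over eligible pairs sorted by (score desc, keys
asc), which the tests use as the reference. An event whose gene has
several homologs competes per pair independently; only its single
highest-scoring match is retained globally.

## Conservation

Clusters are connected components over master-table keys with retained
matches as edges (identical keys within a genome are one node). A cluster
is `conserved_cross_species` iff strict in ≥6 datasets, detected (loose
FDR suffices) in ≥1 mouse dataset, and sign-concordant across strict
ΔPSI values; zero ΔPSI cannot be strict (|ΔPSI| ≥ 0.10), so signs are
well defined. `species_specific` requires the same support confined to
one species (with 3 mouse + 6 human datasets this is reachable only via
the six human datasets); sign concordance is required here too, which is
an interpretive choice — the "equally changed" wording is enforced
uniformly. The upset table counts clusters per *exact* strict-pass
dataset set of size ≥6.

## Motif scanning

The canonical consensus strings ACACACA/ACACAAA contain no degenerate
positions, so consensus scanning is exact substring search (all
overlapping occurrences); the statistical threshold of a PWM scanner is
deliberately not replicated. CA-repeat patterns are the bounded-gap
regular expressions `CA.{0,2}CA.{0,2}CA.{0,2}CA` (≤14 nt) and
`CA.{0,2}CA.{0,2}CA` (≤10 nt) with lazy quantifiers: leftmost,
non-overlapping per pattern, minimal span at each reported offset. Only
the transcribed strand is scanned (the regulator binds RNA). Scanning
covers five segments per event — skipped exon, both adjacent introns and
both adjacent exons — with zero-length introns (abutting exons) retained
and flagged. Event-level flags (`has_canonical`, `has_ca_rich`) are
insensitive to the overlap policy; cohort counts aggregate at cluster
level so one conserved change is counted once across species.

## Expression comparison

DEG tables are consumed, not fitted. Genes are unified across species as
connected components of the ortholog-pair graph (one-to-many homology
folds into one group). A dataset supports a group when its members
measured there carry exactly one non-ns direction; shared groups must be
direction-concordant across datasets by default (switchable), since
mixed-direction "sharing" is biologically incoherent. lncRNA fractions
exclude unknown-biotype genes from numerator and denominator and report
the exclusion count; `lncRNA` and `lincRNA` biotype strings count as
lncRNA by default.

## Synthetic study generator

The generator emulates the study design, not the raw data: nine datasets
(3 mouse + 6 human), one exon-triplet gene per contig, exons 60–300 nt,
introns 150–600 nt, strands independent per species. Species B derives
from species A by iid substitutions that always change the base, so
expected exon identity at divergence d is exactly 1 − d (the tests use
this closed form); optional indels (default off) additionally shift
coordinates. Planted conserved events get strict-pass statistics by
construction — |ΔPSI| in [0.15, 0.80] with one sign, FDR in [1e-4, 0.05],
negative-binomial junction counts (mean 30, dispersion 10, redrawn until
the average clears 10) — in a random ≥6-dataset subset containing ≥1
mouse dataset, and are absent elsewhere so the planted upset pattern is
exact. Decoys occupy ≤4 datasets in one of four sub-threshold classes
(null FDR, loose-only FDR, |ΔPSI| < 0.10, coverage < 10). FDR values are
planted directly rather than derived from a count model: the pipeline
consumes FDRs, it does not compute them. One dataset is written in the
flipped (control − depleted) orientation by default to exercise the
orientation machinery.

Planted genes use a CA-free background so motif counts are exact: every
planted event carries a bounded-gap CA repeat in its upstream intron and
a 45/70 fraction additionally carries ACACACA in the target exon (guard
bases prevent accidental extension into a longer motif), mirroring the
motif composition reported for conserved events in the motivating study.
DEG tables use their own gene universe: per dataset, exclusive up/down
pools sized so the lncRNA fractions are exactly 0.45 (up) and 0.15
(down) — the ~3:1 excess of upregulated lncRNAs — plus two planted
ortholog gene pairs significant with one direction in ≥6 datasets
spanning both species, and shared null genes.

What passing tests therefore show: the pipeline recovers exactly what was
planted under the stated statistical structure, and each computational
primitive agrees with an independent oracle. What they do not show:
robustness to real-data pathologies the generator omits — overlapping
gene models, paralog-rich families beyond the constructed one-to-many
cases, coordinate lift errors, replicate-level PSI noise feeding the FDR,
or annotation disagreements between species.

## Problem sizes and determinism

Default test/acceptance scales: 160 genes (20 planted, 100 decoys) for
the full study, 60 genes for unit-level fixtures, 200 alignment-oracle
pairs (length ≤ 40), 50 matching instances (≤6×6), 500 scanner oracle
sequences. All randomness flows from seeded `numpy` generators with
fixed iteration orders; outputs carry a version/config-hash/seed header
and contain no timestamps, so reruns are byte-identical, which the tests
assert at the file level.

## Known limitations

- Only skipped-exon events are compared; other event classes (MXE, A5SS,
  A3SS, RI) have no cross-species equivalence rule here.
- The consensus-motif scan is exact-match; a PWM scanner with a
  background model would admit near-canonical variants.
- Greedy matching is not a maximum-weight bipartite matching; when two
  mouse events compete for one human event the higher-scoring pair wins
  even if a different assignment would raise the total.
- Identity-based eligibility treats all exon positions equally; no
  splice-site or frame awareness.
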