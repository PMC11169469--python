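import itertools

import pytest

import orthosplice as osp
from orthosplice.conservation import (
    CONSERVED,
    NOT_CONSERVED,
    SPECIES_SPECIFIC,
    EventCluster,
    call_all,
    upset_counts,
)
from orthosplice.diff_events import (
    EventKey,
    EventStats,
    MasterRecord,
    STRICT_PASS,
    LOOSE_ONLY,
)
from orthosplice.ortho_match import EventMatch, PairScore

MOUSE_DS = [f"mouse_{i}" for i in (1, 2, 3)]
HUMAN_DS = [f"human_{i}" for i in range(1, 7)]
SPECIES = {d: "mouse" for d in MOUSE_DS} | {d: "human" for d in HUMAN_DS}
CRITERIA = osp.ConservationCriteria()


def key(species="mouse", gene="G1", chrom="c1"):
    return EventKey(species, gene, chrom, "+", (60, 90), (10, 30),
                    (120, 150))


def record(k, statuses, dpsi=0.3):
    rec = MasterRecord(key=k, gene_symbol=k.gene_id)
    for d, s in statuses.items():
        value = dpsi[d] if isinstance(dpsi, dict) else dpsi
        rec.stats[d] = EventStats(dataset_id=d, avg_junction_reads=20,
                                  inc_level_diff=value, fdr=0.01)
        rec.status[d] = s
    return rec


def match(ka, kb):
    ps = PairScore((10.0, 10.0, 10.0), (1.0, 1.0, 1.0), True)
    return EventMatch(ka, kb, ps, 1)


def cluster_from(statuses, dpsi=0.3, species=("mouse", "human")):
    """A ready-made cluster with a mouse and a human member."""
    km, kh = key("mouse"), key("human")
    members = []
    if "mouse" in species:
        members.append(km)
    if "human" in species:
        members.append(kh)
    cl = EventCluster(cluster_id=0, members=tuple(members), matches=())
    for d, s in statuses.items():
        cl.status[d] = s
        cl.dpsi[d] = dpsi[d] if isinstance(dpsi, dict) else dpsi
    return cl


class TestClusterEvents:
    def test_same_key_across_datasets_is_one_cluster(self):
        k = key()
        rec = record(k, {d: STRICT_PASS for d in MOUSE_DS})
        clusters = osp.cluster_events([rec], [])
        assert len(clusters) == 1
        assert set(clusters[0].status) == set(MOUSE_DS)

    def test_match_bridges_species(self):
        km, kh = key("mouse"), key("human")
        master = [record(km, {"mouse_1": STRICT_PASS}),
                  record(kh, {"human_1": STRICT_PASS})]
        clusters = osp.cluster_events(master, [match(km, kh)])
        assert len(clusters) == 1
        assert set(clusters[0].status) == {"mouse_1", "human_1"}

    def test_disjoint_matches_make_two_clusters(self):
        pairs = [(key("mouse", "G1"), key("human", "H1", "c2")),
                 (key("mouse", "G2", "c3"), key("human", "H2", "c4"))]
        master = [record(k, {"mouse_1": STRICT_PASS})
                  for k, _ in pairs] + [record(k, {"human_1": STRICT_PASS})
                                        for _, k in pairs]
        clusters = osp.cluster_events(master,
                                      [match(a, b) for a, b in pairs])
        assert len(clusters) == 2

    def test_unknown_key_in_match_errors(self):
        km, kh = key("mouse"), key("human")
        with pytest.raises(KeyError):
            osp.cluster_events([record(km, {"mouse_1": STRICT_PASS})],
                               [match(km, kh)])


class TestCallConserved:
    def test_six_datasets_with_mouse_conserved(self):
        cl = cluster_from({d: STRICT_PASS
                           for d in MOUSE_DS[:1] + HUMAN_DS[:5]})
        call = osp.call_conserved(cl, CRITERIA, SPECIES)
        assert call.verdict == CONSERVED
        assert call.n_strict == 6 and call.direction_concordant

    def test_all_human_no_mouse_is_species_specific(self):
        cl = cluster_from({d: STRICT_PASS for d in HUMAN_DS},
                          species=("human",))
        call = osp.call_conserved(cl, CRITERIA, SPECIES)
        assert call.verdict == SPECIES_SPECIFIC
        assert not call.has_mouse_detection

    def test_mixed_signs_not_conserved(self):
        datasets = MOUSE_DS[:1] + HUMAN_DS[:5]
        dpsi = {d: (0.3 if i % 2 else -0.3)
                for i, d in enumerate(datasets)}
        cl = cluster_from({d: STRICT_PASS for d in datasets}, dpsi=dpsi)
        call = osp.call_conserved(cl, CRITERIA, SPECIES)
        assert not call.direction_concordant
        assert call.verdict == NOT_CONSERVED

    def test_loose_mouse_detection_suffices(self):
        statuses = {d: STRICT_PASS for d in HUMAN_DS}
        statuses["mouse_1"] = LOOSE_ONLY
        cl = cluster_from(statuses)
        call = osp.call_conserved(cl, CRITERIA, SPECIES)
        assert call.has_mouse_detection
        assert call.verdict == CONSERVED

    def test_five_strict_not_enough(self):
        cl = cluster_from({d: STRICT_PASS
                           for d in MOUSE_DS[:1] + HUMAN_DS[:4]})
        assert osp.call_conserved(cl, CRITERIA,
                                  SPECIES).verdict == NOT_CONSERVED

    def test_promotion_never_demotes(self):
        """Promoting any dataset fail -> strict (same sign) is monotone."""
        rank = {NOT_CONSERVED: 0, SPECIES_SPECIFIC: 1, CONSERVED: 2}
        base_sets = [MOUSE_DS[:1] + HUMAN_DS[:4],
                     MOUSE_DS[:1] + HUMAN_DS[:5], HUMAN_DS]
        for base in base_sets:
            cl = cluster_from({d: STRICT_PASS for d in base})
            before = osp.call_conserved(cl, CRITERIA, SPECIES)
            for extra in set(MOUSE_DS + HUMAN_DS) - set(base):
                promoted = cluster_from(
                    {d: STRICT_PASS for d in base + [extra]}
                )
                after = osp.call_conserved(promoted, CRITERIA, SPECIES)
                assert rank[after.verdict] >= rank[before.verdict]


class TestUpsetCounts:
    def make(self, strict_sets):
        clusters, calls = [], []
        for i, datasets in enumerate(strict_sets):
            cl = cluster_from({d: STRICT_PASS for d in datasets})
            cl.cluster_id = i
            clusters.append(cl)
            calls.append(osp.call_conserved(cl, CRITERIA, SPECIES))
        return calls, clusters

    def test_two_clusters_same_set_one_row(self):
        six = MOUSE_DS[:1] + HUMAN_DS[:5]
        calls, clusters = self.make([six, six])
        table = upset_counts(calls, clusters)
        assert len(table) == 1
        assert table.iloc[0]["count"] == 2
        assert table.iloc[0]["set_size"] == 6

    def test_below_minimum_empty(self):
        calls, clusters = self.make([MOUSE_DS, HUMAN_DS[:2]])
        assert upset_counts(calls, clusters).empty

    def test_counts_bounded_by_clusters_and_order_invariant(self):
        sets = [MOUSE_DS[:1] + HUMAN_DS[:5], HUMAN_DS,
                MOUSE_DS + HUMAN_DS[:3], MOUSE_DS[:2]]
        calls, clusters = self.make(sets)
        table = upset_counts(calls, clusters)
        assert table["count"].sum() <= len(clusters)
        for perm in ([3, 2, 1, 0], [1, 3, 0, 2]):
            calls_p = [calls[i] for i in perm]
            clusters_p = [clusters[i] for i in perm]
            assert upset_counts(calls_p, clusters_p).equals(table)

    def test_dataset_order_within_cluster_irrelevant(self, small_result,
                                                     small_study):
        expected = small_study.truth.expected_upset()
        observed = {
            tuple(row["dataset_set"].split(",")): int(row["count"])
            for _, row in small_result.upset.iterrows()
        }
        assert observed == expected


def test_verdicts_invariant_to_dataset_permutation(small_study):
    """Feeding datasets in reversed order changes no verdict."""
    from orthosplice.pipeline import run_study, workspace_from_study

    ws = workspace_from_study(small_study)
    ws_rev = workspace_from_study(small_study)
    ws_rev.datasets = list(reversed(ws_rev.datasets))
    verdicts = [c.verdict for c in run_study(ws).calls]
    verdicts_rev = [c.verdict for c in run_study(ws_rev).calls]
    assert verdicts == verdicts_rev
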