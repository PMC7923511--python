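import numpy as np
import pytest

from cytopattern.characterize import (FrequencyTable, cluster_features,
                                      coverage_summary, disease_prevalence,
                                      event_frequency, event_signature,
                                      heatmap_order, top_events)
from cytopattern.cluster import Partition
from cytopattern.exceptions import ValidationError
from cytopattern.io import parse_feature_name
from cytopattern.reduce import DedupMap, collapse_duplicates
from conftest import make_matrix


def singleton_map(raws):
    return DedupMap(groups={r: [parse_feature_name(r, strict=False)] for r in raws})


def ftable(values, sizes=None):
    values = np.asarray(values, float)
    C, G = values.shape
    sizes = sizes or [10] * C
    return FrequencyTable(values=values,
                          counts=(values * np.array(sizes)[:, None]).astype(int),
                          cluster_ids=list(range(1, C + 1)),
                          group_ids=list(range(1, G + 1)),
                          cluster_sizes=list(sizes))


class TestEventSignature:
    @staticmethod
    def _groups(raw_lists):
        labels = {}
        for c, raws in enumerate(raw_lists, start=1):
            for r in raws:
                labels[r] = c
        all_raws = [r for raws in raw_lists for r in raws]
        fp = Partition(labels=labels, medoids=[raws[0] for raws in raw_lists],
                       K=len(raw_lists), cost=0)
        names = [parse_feature_name(r) for r in all_raws]
        return event_signature(fp, singleton_map(all_raws), names)

    def test_loss_only_single_chromosome(self):
        (g,) = self._groups([["13q14.L", "13q13.L", "13q12.L"]])
        assert g.klass == "loss-only"
        assert g.chromosomes == {"13"}
        assert g.types == {"Loss"}

    def test_t8_14_fusion_two_chromosomes(self):
        (g,) = self._groups([["8q24.F", "14q32.F"]])
        assert g.klass == "fusion-only" and g.chromosomes == {"8", "14"}

    def test_three_chromosome_fusion(self):
        (g,) = self._groups([["1q21.F", "11q13.F", "19p13.F"]])
        assert g.klass == "fusion-only" and len(g.chromosomes) == 3

    @pytest.mark.parametrize("raws,klass", [
        (["5q31.G", "5q32.G"], "gain-only"),
        (["8q24.F", "17p13.L"], "fusion+loss"),
        (["8q24.F", "12q13.G"], "fusion+gain"),
        (["17p13.L", "12q13.G"], "mixed"),
    ])
    def test_klass_rule_table(self, raws, klass):
        (g,) = self._groups([raws])
        assert g.klass == klass

    def test_bands_expanded_through_dedup_map(self):
        m = make_matrix(np.array([[1, 1, 0], [0, 0, 1]]),
                        raw_names=["13q14.L", "13q13.L", "8q24.F"])
        reduced, dmap = collapse_duplicates(m)
        fp = Partition(labels={"13q14.L": 1, "8q24.F": 2},
                       medoids=["13q14.L", "8q24.F"], K=2, cost=0)
        groups = event_signature(fp, dmap, reduced.features)
        assert groups[0].bands == {"13q14", "13q13"}  # member recovered


class TestEventFrequency:
    def test_counting(self):
        m = make_matrix(np.array([[1, 0], [1, 0], [0, 1], [0, 0]]),
                        raw_names=["1q1.L", "2q1.G"])
        sp = Partition(labels={s: 1 for s in m.sample_ids},
                       medoids=[m.sample_ids[0]], K=1, cost=0)
        fp = Partition(labels={"1q1.L": 1, "2q1.G": 2},
                       medoids=["1q1.L", "2q1.G"], K=2, cost=0)
        dmap = singleton_map(m.raw_names)
        groups = event_signature(fp, dmap, m.features)
        ft = event_frequency(m, sp, groups, dmap)
        # 2 of 4 samples carry group 1, 1 of 4 group 2
        assert ft.values[0].tolist() == [0.5, 0.25]

    def test_any_member_rule(self):
        # 3 of 4 samples carry >= 1 member of the two-feature group
        m = make_matrix(np.array([[1, 0], [0, 1], [1, 1], [0, 0]]),
                        raw_names=["1q1.L", "1q2.L"])
        sp = Partition(labels={s: 1 for s in m.sample_ids},
                       medoids=[m.sample_ids[0]], K=1, cost=0)
        fp = Partition(labels={"1q1.L": 1, "1q2.L": 1}, medoids=["1q1.L"],
                       K=1, cost=0)
        dmap = singleton_map(m.raw_names)
        groups = event_signature(fp, dmap, m.features)
        ft = event_frequency(m, sp, groups, dmap)
        assert ft.values[0, 0] == pytest.approx(0.75)

    def test_absent_group_scores_zero_and_entries_in_unit_interval(self, rng):
        m = make_matrix(np.hstack([rng.integers(0, 2, (8, 3)), np.zeros((8, 1), int)]))
        sp = Partition(labels={s: 1 + (i % 2) for i, s in enumerate(m.sample_ids)},
                       medoids=m.sample_ids[:2], K=2, cost=0)
        fp = Partition(labels={r: j + 1 for j, r in enumerate(m.raw_names)},
                       medoids=m.raw_names, K=4, cost=0)
        dmap = singleton_map(m.raw_names)
        ft = event_frequency(m, sp, event_signature(fp, dmap, m.features), dmap)
        assert np.all(ft.values >= 0) and np.all(ft.values <= 1)
        assert np.all(ft.values[:, 3] == 0.0)


class TestCoverageSummary:
    def test_hand_example(self):
        ft = ftable([[1.0, 0.2], [0.5, 0.61]])
        assert coverage_summary(ft, [0.99, 0.60]) == {0.99: 1, 0.60: 2}

    def test_empty_threshold_list(self):
        assert coverage_summary(ftable([[0.5, 0.1]]), []) == {}

    def test_monotone_in_threshold(self, rng):
        ft = ftable(rng.random((6, 5)))
        ts = [0.9, 0.7, 0.5, 0.3, 0.1]
        counts = list(coverage_summary(ft, ts).values())
        assert counts == sorted(counts)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            coverage_summary(ftable([[0.5]]), [1.5])


class TestTopEvents:
    def test_cutoff_boundary(self):
        rep = top_events(ftable([[1.0, 0.59]]), cutoff=0.6)
        assert rep.rows[0].events == [(1, 1.0)]

    def test_cutoff_one_keeps_only_full_penetrance(self):
        rep = top_events(ftable([[1.0, 0.99]]), cutoff=1.0)
        assert rep.rows[0].events == [(1, 1.0)]

    def test_uncharacterized_cluster_flagged(self):
        rep = top_events(ftable([[0.2, 0.3]]), cutoff=0.6)
        assert not rep.rows[0].characterized and rep.rows[0].events == []

    def test_frequency_ties_broken_by_group_id(self):
        rep = top_events(ftable([[0.8, 0.8, 0.9]]), cutoff=0.6)
        assert rep.rows[0].events == [(3, 0.9), (1, 0.8), (2, 0.8)]

    def test_nested_in_lower_cutoff(self, rng):
        ft = ftable(rng.random((4, 6)))
        hi = top_events(ft, cutoff=0.7)
        lo = top_events(ft, cutoff=0.4)
        for rh, rl in zip(hi.rows, lo.rows):
            assert set(rh.events) <= set(rl.events)


class TestDiseasePrevalence:
    def test_counting(self):
        ids = [f"s{i}" for i in range(10)]
        sp = Partition(labels={s: 1 for s in ids}, medoids=[ids[0]], K=1, cost=0)
        labels = {s: ("CLL" if i < 6 else "ALL") for i, s in enumerate(ids)}
        prev = disease_prevalence(sp, labels)
        assert prev[1] == {"ALL": 0.4, "CLL": 0.6}

    def test_single_disease_cohort(self):
        ids = ["a", "b", "c", "d"]
        sp = Partition(labels={"a": 1, "b": 1, "c": 2, "d": 2},
                       medoids=["a", "c"], K=2, cost=0)
        prev = disease_prevalence(sp, {s: "MM" for s in ids})
        assert prev[1] == {"MM": 1.0} and prev[2] == {"MM": 1.0}

    def test_unlabeled_fall_into_unknown_and_sum_to_one(self):
        sp = Partition(labels={"a": 1, "b": 1, "c": 1}, medoids=["a"], K=1, cost=0)
        prev = disease_prevalence(sp, {"a": "FL"})
        assert prev[1]["unknown"] == pytest.approx(2 / 3)
        assert sum(prev[1].values()) == pytest.approx(1.0)


class TestHeatmapOrder:
    def test_identical_rows_adjacent_at_height_zero(self):
        ft = ftable([[1.0, 0.1, 0.8], [0.2, 0.9, 0.3],
                     [0.95, 0.15, 0.78], [0.1, 0.2, 0.9]]).values
        tab = ftable(ft.T.tolist())  # groups = original rows
        row_order, col_order, Zr, Zc = heatmap_order(tab)
        assert Zr[0, 2] >= -1e-12
        assert sorted(row_order) == tab.group_ids

    def test_anticorrelated_profiles_split_at_top(self):
        # two "gain-like" profiles vs two anticorrelated "loss-like" profiles
        gains = [0.9, 0.8, 0.1, 0.2]
        losses = [0.1, 0.2, 0.9, 0.8]
        tab = ftable(np.array([gains, [g - 0.05 for g in gains],
                               losses, [l + 0.05 for l in losses]]).T.tolist())
        row_order, _, Zr, _ = heatmap_order(tab)
        pos = {g: i for i, g in enumerate(row_order)}
        side_a = {pos[1], pos[2]}
        side_b = {pos[3], pos[4]}
        assert max(side_a) < min(side_b) or max(side_b) < min(side_a)

    def test_row_order_is_permutation(self, rng):
        tab = ftable(rng.random((5, 4)))
        row_order, col_order, _, _ = heatmap_order(tab)
        assert sorted(row_order) == tab.group_ids
        assert sorted(col_order) == tab.cluster_ids


class TestClusterFeatures:
    def test_noiseless_blocks_collapse_then_cluster_trivially(self):
        rng = np.random.default_rng(5)
        blocks = rng.integers(0, 2, (20, 3))
        X = np.repeat(blocks, 4, axis=1)  # 3 events x 4 identical bands
        m = make_matrix(X)
        reduced, dmap = collapse_duplicates(m)
        assert reduced.d == len(np.unique(blocks, axis=1).T)
        fp, K = cluster_features(reduced, q=reduced.d)
        assert K == reduced.d  # one group per distinct block

    def test_single_feature_forces_one_group(self):
        m = make_matrix(np.array([[1], [0], [1]]))
        fp, K = cluster_features(m)
        assert K == 1 and set(fp.labels.values()) == {1}
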