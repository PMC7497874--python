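"""Duocentric measures: overall measures, 75%-rule characteristics, ADD counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duonet import duo_measures as dm
from duonet.duo_merge import merge_duocentric
from duonet.synthetic_data import CohortSpec, generate_matched_pair
from duonet.types import AlterRecord, TieReport

from conftest import mk_survey


class TestOverallMeasures:
    """The six overall measures for the three worked matched pairs."""

    def test_pair1_measures(self, pair1):
        ya, pa = pair1
        m = dm.duo_measure_set(merge_duocentric(ya, pa), ya, pa)
        assert m["network_size"] == {"ya": 5, "pa": 4}
        assert round(m["network_density"]["ya"], 2) == 0.60
        assert round(m["network_density"]["pa"], 2) == 0.17
        assert m["overlap_count"] == 1
        assert m["unique_counts"] == {"ya": 4, "pa": 3}
        assert m["disconnected_counts"] == {"ya": 1, "pa": 2}
        assert m["parent_centrality"] == pytest.approx(0.75)

    def test_pair2_measures(self, pair2):
        ya, pa = pair2
        m = dm.duo_measure_set(merge_duocentric(ya, pa), ya, pa)
        assert m["network_size"] == {"ya": 5, "pa": 3}
        assert round(m["network_density"]["ya"], 2) == 0.70
        assert round(m["network_density"]["pa"], 2) == 0.67
        assert m["overlap_count"] == 1
        assert m["unique_counts"]["pa"] == 2
        assert m["disconnected_counts"] == {"ya": 0, "pa": 0}
        assert m["parent_centrality"] == pytest.approx(1.0)

    def test_pair3_subset_measures(self, pair3):
        ya, pa = pair3
        m = dm.duo_measure_set(merge_duocentric(ya, pa), ya, pa)
        assert m["network_size"] == {"ya": 5, "pa": 2}
        assert round(m["network_density"]["ya"], 2) == 0.70
        assert m["network_density"]["pa"] == 0.0
        assert m["overlap_count"] == 2
        assert m["unique_counts"] == {"ya": 3, "pa": 0}
        assert m["disconnected_counts"] == {"ya": 0, "pa": 2}
        assert m["parent_centrality"] is None  # parent not in YA network

    def test_overlap_unique_partition_node_count(self, study_pairs):
        for ya, pa in study_pairs:
            duo = merge_duocentric(ya, pa)
            overlap, unique = dm.overlap_and_unique(duo)
            assert overlap + unique["ya"] + unique["pa"] == len(duo.nodes)
            assert overlap + unique["ya"] == ya.n_alters
            assert overlap + unique["pa"] == pa.n_alters


class TestParentCentrality:
    def test_tied_to_three_of_four_is_75_percent(self, pair1):
        duo = merge_duocentric(*pair1)
        assert dm.parent_centrality(duo) == pytest.approx(0.75)

    def test_tied_to_all_others_is_100_percent(self, pair2):
        duo = merge_duocentric(*pair2)
        assert dm.parent_centrality(duo) == pytest.approx(1.0)

    def test_na_when_parent_not_named(self, pair3):
        assert dm.parent_centrality(merge_duocentric(*pair3)) is None

    def test_merged_frame_counts_implicit_parent_ties(self, pair1):
        # merged frame: parent implicitly tied to the 4 alters she named,
        # plus her YA-reported ties; 8 nodes total
        duo = merge_duocentric(*pair1)
        assert dm.parent_centrality(duo, frame="merged") == pytest.approx(6 / 7)

    @given(st.integers(0, 10_000))
    @settings(max_examples=75, deadline=None, derandomize=True)
    def test_matches_brute_force_degree_count(self, seed):
        spec = CohortSpec(seed=seed, parent_named_prob=1.0)
        ya, pa = generate_matched_pair(spec, np.random.default_rng(seed))
        duo = merge_duocentric(ya, pa)
        pc = dm.parent_centrality(duo)
        if duo.parent_node is None or ya.n_alters < 2:
            assert pc is None
            return
        parent_rank = next(
            n.ya_rank for n in duo.nodes if n.unified_id == duo.parent_node)
        deg = sum(
            1 for t in ya.tie_reports
            if t.interacts and parent_rank in t.pair)
        assert pc == pytest.approx(deg / (ya.n_alters - 1))


class TestCharacteristics:
    def test_pair1_and_pair2_codes(self, pair1, pair2):
        for pair in (pair1, pair2):
            c = dm.characteristics(merge_duocentric(*pair))
            assert c.parent_only_alters is True
            assert c.youth_only_alters is True
            assert c.parent_network_is_subset is False
            assert c.parent_high_centrality is True

    def test_pair3_subset_codes(self, pair3):
        c = dm.characteristics(merge_duocentric(*pair3))
        assert c.parent_network_is_subset is True
        assert c.parent_only_alters is False
        assert c.parent_high_centrality is False

    def test_subset_implies_no_parent_only_alters(self, study_pairs):
        for ya, pa in study_pairs:
            c = dm.characteristics(merge_duocentric(ya, pa))
            if c.parent_network_is_subset:
                assert not c.parent_only_alters

    def test_empty_parent_roster_is_vacuous_subset_and_degenerate(self):
        ya = mk_survey("YA", "young_adult",
                       [("A X", "friend", "community", set()),
                        ("B X", "friend", "community", set())], {(1, 2): 1})
        pa = mk_survey("PA", "parent", [], {})
        c = dm.characteristics(merge_duocentric(ya, pa))
        assert c.parent_network_is_subset is True
        assert c.degenerate is True

    def test_overlap_high_tie_threshold(self, pair3):
        # pair 3 overlap alters: 6 merged nodes... here 5 nodes, each overlap
        # alter must reach >= 75% of the other 4 to code yes
        duo = merge_duocentric(*pair3)
        c = dm.characteristics(duo)
        n = len(duo.nodes)
        ok = all(
            sum(1 for v in (m.unified_id for m in duo.nodes)
                if v != u and duo.tied(u, v)) / (n - 1) >= 0.75
            for u in (m.unified_id for m in duo.nodes if m.provenance == "both")
        )
        assert c.overlap_alters_high_tie is ok

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_alter_relabeling(self, seed):
        spec = CohortSpec(seed=seed)
        rng = np.random.default_rng(seed)
        ya, pa = generate_matched_pair(spec, rng)
        base = dm.characteristics(merge_duocentric(ya, pa))
        perm = dm.characteristics(merge_duocentric(_permute(ya, rng), pa))
        assert base == perm


def _permute(survey, rng):
    """Shuffle alter ranks; tie reports follow the permutation."""
    n = survey.n_alters
    new_rank = dict(zip(range(1, n + 1), rng.permutation(n) + 1))
    alters = tuple(
        AlterRecord(a.label, int(new_rank[a.rank]), a.role_raw, a.role_class,
                    a.supports)
        for a in survey.alters
    )
    ties = tuple(
        TieReport(int(new_rank[t.rank_a]), int(new_rank[t.rank_b]), t.frequency)
        for t in survey.tie_reports
    )
    return survey.with_alters(
        tuple(sorted(alters, key=lambda a: a.rank)), ties).validate()


class TestSocialCapitalConfig:
    def test_subset_pair_has_all_zero_add_counts(self, pair3):
        ya, pa = pair3
        cfg = dm.social_capital_config(merge_duocentric(ya, pa), ya, pa)
        assert all(v == 0 for v in cfg["add_counts"].values())

    def test_pair1_three_parent_unique_emotional_alters(self, pair1):
        ya, pa = pair1
        cfg = dm.social_capital_config(merge_duocentric(ya, pa), ya, pa)
        assert cfg["add_counts"]["emotional"] == 3
        assert cfg["add_counts"]["advice"] == 2
        assert cfg["add_counts"]["friendship"] == 1
        assert cfg["pa"]["support_pct"]["emotional"] == 100.0

    def test_pair2_adds_logistical_and_job_support(self, pair2):
        ya, pa = pair2
        cfg = dm.social_capital_config(merge_duocentric(ya, pa), ya, pa)
        assert cfg["add_counts"]["logistical"] >= 1
        assert cfg["add_counts"]["job"] >= 1
        assert cfg["add_counts"] == {
            "family": 1, "community": 0, "professional": 1,
            "friendship": 2, "emotional": 2, "advice": 2,
            "financial": 0, "logistical": 1, "job": 1,
        }

    def test_role_and_support_percentages_come_from_each_survey(self, pair1):
        ya, pa = pair1
        cfg = dm.social_capital_config(merge_duocentric(ya, pa), ya, pa)
        assert cfg["ya"]["role_pct"]["family"] == 100.0
        assert cfg["ya"]["support_pct"]["friendship"] == 100.0
        assert cfg["ya"]["support_pct"]["emotional"] == 60.0
        assert cfg["ya"]["family_friendship_pct"] == 100.0
        assert cfg["pa"]["role_pct"]["community"] == 25.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_add_counts_bounded_by_parent_unique_alters(self, seed):
        spec = CohortSpec(seed=seed)
        ya, pa = generate_matched_pair(spec, np.random.default_rng(seed))
        duo = merge_duocentric(ya, pa)
        cfg = dm.social_capital_config(duo, ya, pa)
        _, unique = dm.overlap_and_unique(duo)
        assert all(v <= unique["pa"] for v in cfg["add_counts"].values())
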