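"""Alter matching, name normalization, and the maximum-value merge."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duonet.duo_merge import (
    DuoNetwork,
    match_alters,
    merge_duocentric,
    normalize_name,
)
from duonet.synthetic_data import CohortSpec, generate_matched_pair
from duonet.types import ValidationError

from conftest import mk_survey


def _surveys(names_ya, names_pa, ties_ya=None, ties_pa=None):
    mk = lambda n: (n, "friend", "community", set())
    ya = mk_survey("YA", "young_adult", [mk(n) for n in names_ya], ties_ya or {})
    pa = mk_survey("PA", "parent", [mk(n) for n in names_pa], ties_pa or {})
    return ya, pa


class TestNormalizeName:
    @pytest.mark.parametrize("raw,key", [
        ("Aunt  Sue ", "aunt sue"),
        ("J. Smith", "j smith"),
        ("J Smith", "j smith"),
        ("MARY-JANE O'Brien", "mary jane o brien"),
    ])
    def test_canonical_key(self, raw, key):
        assert normalize_name(raw) == key

    @pytest.mark.parametrize("variant", [
        "J. Smith", "j smith", " J  SMITH ", "J, Smith", "J;Smith"])
    def test_punctuation_variants_collapse(self, variant):
        assert normalize_name(variant) == "j smith"

    def test_no_fuzzy_matching(self):
        assert normalize_name("Sue") != normalize_name("Susan")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            normalize_name("  ")


class TestMatchAlters:
    def test_one_shared_four_vs_three_unique(self):
        ya, pa = _surveys(["A X", "B X", "C X", "D X", "E X"],
                          ["A X", "F X", "G X", "H X"])
        matches = match_alters(ya, pa)
        by_prov = {p: sum(1 for m in matches if m.provenance == p)
                   for p in ("both", "ya_only", "pa_only")}
        assert by_prov == {"both": 1, "ya_only": 4, "pa_only": 3}
        assert len(matches) == 8
        assert len({m.unified_id for m in matches}) == 8

    def test_parent_roster_subset_of_ya(self):
        ya, pa = _surveys(["A X", "B X", "C X", "D X", "E X"], ["B X", "C X"])
        matches = match_alters(ya, pa)
        provs = [m.provenance for m in matches]
        assert provs.count("both") == 2 and provs.count("pa_only") == 0

    def test_disjoint_rosters(self):
        ya, pa = _surveys(["A X", "B X"], ["C X", "D X"])
        assert all(m.provenance != "both" for m in match_alters(ya, pa))

    def test_matching_survives_case_and_punctuation(self):
        ya, pa = _surveys(["J. Smith"], ["j  smith"])
        assert match_alters(ya, pa)[0].provenance == "both"

    def test_duplicate_key_within_one_survey_is_ambiguous(self):
        ya, pa = _surveys(["A Smith", "a  smith"], ["B X"])
        with pytest.raises(ValidationError, match="twice"):
            match_alters(ya, pa)


class TestMergeMaximumValue:
    def _merge(self, ya_freq, pa_freq):
        ya, pa = _surveys(["A X", "B X"], ["A X", "B X"],
                          {(1, 2): ya_freq}, {(1, 2): pa_freq})
        return merge_duocentric(ya, pa)

    def test_conflicting_binary_reports_resolve_to_tied(self):
        duo = self._merge(0, 1)
        assert len(duo.edges) == 1 and list(duo.edges.values()) == [1]
        (d,) = duo.discrepancies
        assert (d.ya_value, d.pa_value, d.resolved_value) == (0, 1, 1)

    def test_both_report_untied_leaves_no_edge(self):
        duo = self._merge(0, 0)
        assert duo.edges == {} and duo.discrepancies == ()

    def test_ordinal_frequencies_merge_by_max(self):
        duo = self._merge(2, 3)
        assert list(duo.edges.values()) == [3]
        assert duo.discrepancies[0].resolved_value == 3

    def test_agreeing_reports_log_no_discrepancy(self):
        assert self._merge(2, 2).discrepancies == ()

    def test_study_pairs_have_exactly_one_discrepancy(self, study_pairs):
        logs = [merge_duocentric(ya, pa).discrepancies for ya, pa in study_pairs]
        assert sum(len(l) for l in logs) == 1
        (d,) = [d for l in logs for d in l]
        assert d.pa_value == 0 and d.resolved_value == d.ya_value > 0

    def test_single_reporter_pairs_stand_as_reported(self, pair1):
        ya, pa = pair1
        duo = merge_duocentric(ya, pa)
        # PA's single tie is between two parent-only alters; it survives
        pa_only = {n.unified_id for n in duo.nodes if n.provenance == "pa_only"}
        assert any(u in pa_only and v in pa_only for (u, v) in duo.edges)

    def test_unobservable_pairs_have_no_edge(self, pair1):
        ya, pa = pair1
        duo = merge_duocentric(ya, pa)
        assert duo.unobservable_pairs
        for p in duo.unobservable_pairs:
            assert p not in duo.edges

    def test_parent_node_present_only_when_named(self, pair1, pair3):
        duo1 = merge_duocentric(*pair1)
        assert duo1.parent_node is not None
        assert duo1.node(duo1.parent_node).label == "Dana Ashford"
        assert merge_duocentric(*pair3).parent_node is None

    def test_mismatched_match_list_rejected(self, pair1, pair2):
        ya1, pa1 = pair1
        wrong = match_alters(*pair2)
        with pytest.raises(ValidationError, match="cover"):
            merge_duocentric(ya1, pa1, matches=wrong)


def _structure(duo: DuoNetwork):
    """Label-based structural signature, invariant to unified-id naming."""
    label = {n.unified_id: n.label for n in duo.nodes}
    nodes = frozenset((n.label, n.provenance) for n in duo.nodes)
    edges = frozenset(
        (frozenset((label[u], label[v])), w) for (u, v), w in duo.edges.items()
    )
    return nodes, edges


class TestMergeProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=75, deadline=None, derandomize=True)
    def test_node_count_set_arithmetic(self, seed):
        spec = CohortSpec(seed=seed, discrepancy_prob=0.3)
        ya, pa = generate_matched_pair(spec, np.random.default_rng(seed))
        duo = merge_duocentric(ya, pa)
        shared = {a.label for a in ya.alters} & {a.label for a in pa.alters}
        assert len(duo.nodes) == ya.n_alters + pa.n_alters - len(shared)

    @given(st.integers(0, 10_000))
    @settings(max_examples=75, deadline=None, derandomize=True)
    def test_symmetry_of_conflict_rule(self, seed):
        """Swapping which respondent holds the higher report changes nothing."""
        spec = CohortSpec(seed=seed, discrepancy_prob=0.5)
        ya, pa = generate_matched_pair(spec, np.random.default_rng(seed))
        duo = merge_duocentric(ya, pa)
        # swap the two respondents' reports over shared pairs
        swapped = merge_duocentric(
            ya.with_alters(ya.alters, _swap_shared(ya, pa, "ya")),
            pa.with_alters(pa.alters, _swap_shared(ya, pa, "pa")),
        )
        assert _structure(duo)[1] == _structure(swapped)[1]

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotence_merge_of_projections(self, seed):
        spec = CohortSpec(seed=seed, discrepancy_prob=0.3)
        ya, pa = generate_matched_pair(spec, np.random.default_rng(seed))
        duo = merge_duocentric(ya, pa)
        again = merge_duocentric(duo.project("ya"), duo.project("pa"))
        assert _structure(again) == _structure(duo)
        # a re-merge of already-resolved reports carries no discrepancies
        assert again.discrepancies == ()

    @given(st.integers(0, 10_000))
    @settings(max_examples=75, deadline=None, derandomize=True)
    def test_every_discrepancy_resolves_to_max(self, seed):
        spec = CohortSpec(seed=seed, discrepancy_prob=0.6)
        ya, pa = generate_matched_pair(spec, np.random.default_rng(seed))
        duo = merge_duocentric(ya, pa)
        for d in duo.discrepancies:
            assert d.resolved_value == max(d.ya_value, d.pa_value)
            assert duo.edges.get(d.pair, 0) == d.resolved_value or \
                d.resolved_value == 0


def _swap_shared(ya, pa, side):
    """Tie reports for `side` with shared-pair values taken from the other survey."""
    from duonet.duo_merge import normalize_name as norm
    from duonet.types import TieReport

    ya_by_key = {norm(a.label): a.rank for a in ya.alters}
    pa_by_key = {norm(a.label): a.rank for a in pa.alters}
    shared = set(ya_by_key) & set(pa_by_key)
    me, other = (ya, pa) if side == "ya" else (pa, ya)
    me_key = {a.rank: norm(a.label) for a in me.alters}
    other_by_key = pa_by_key if side == "ya" else ya_by_key
    out = []
    for t in me.tie_reports:
        ka, kb = me_key[t.rank_a], me_key[t.rank_b]
        if ka in shared and kb in shared:
            out.append(TieReport(
                t.rank_a, t.rank_b,
                other.tie_frequency(other_by_key[ka], other_by_key[kb])))
        else:
            out.append(t)
    return tuple(out)
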