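"""Shared fixtures: three worked matched-pair examples and survey builders.

The three young-adult/parent pairs reproduce the published worked examples
of the duocentric method: a pair where the parent is central and adds
unique alters with low closure among them (pair 1), a pair where the
parent is tied to every other alter and adds professional resources
(pair 2), and a pair where the parent's roster is a subset of the young
adult's, with the study's single discrepant tie report (pair 3).
"""

from __future__ import annotations

import numpy as np
import pytest

from duonet.types import AlterRecord, EgoSurvey, TieReport


def mk_survey(ego_id, kind, alters, ties, cap=5):
    """alters: list of (label, role_raw, role_class, supports); ties: {(a,b): freq}.

    Unlisted pairs get frequency 0; the tie-report matrix is always complete.
    """
    recs = tuple(
        AlterRecord(label=lab, rank=i + 1, role_raw=raw, role_class=cls,
                    supports=frozenset(sup))
        for i, (lab, raw, cls, sup) in enumerate(alters)
    )
    n = len(recs)
    reports = tuple(
        TieReport(a, b, ties.get((a, b), 0))
        for a in range(1, n + 1)
        for b in range(a + 1, n + 1)
    )
    return EgoSurvey(
        ego_id=ego_id, reporter_kind=kind, alters=recs, tie_reports=reports,
        roster_cap=cap,
    ).validate()


def complete_ties(ranks, freq=1):
    return {(a, b): freq for i, a in enumerate(ranks) for b in ranks[i + 1:]}


@pytest.fixture
def pair1():
    """Parent-central pair: YA density 0.6 (one isolate), PA density 0.17."""
    ya = mk_survey(
        "YA1", "young_adult",
        [
            ("Dana Ashford", "mother", "family",
             {"friendship", "emotional", "advice", "financial", "logistical", "job"}),
            ("Evan Ashford", "father", "family",
             {"friendship", "emotional", "advice", "financial"}),
            ("Lee Ashford", "brother", "family", {"friendship", "emotional"}),
            ("Gwen Ashford", "grandmother", "family", {"friendship"}),
            ("Sue Ashford", "aunt", "family", {"friendship"}),
        ],
        # alters 1-4 mutually tied, alter 5 isolated -> 6/10 ties
        complete_ties([1, 2, 3, 4], freq=2),
    )
    pa = mk_survey(
        "PA1", "parent",
        [
            ("Evan Ashford", "husband", "family",
             {"friendship", "emotional"}),
            ("Rory Birch", "sister", "family",
             {"friendship", "emotional", "advice"}),
            ("Jo Calder", "brother", "family", {"emotional", "advice"}),
            ("Pat Dunmore", "neighbor", "community", {"emotional"}),
        ],
        {(2, 3): 1},  # single tie -> density 1/6, two isolates
    )
    return ya, pa


@pytest.fixture
def pair2():
    """Fully central parent: YA density 0.7, parent tied to all four others."""
    ya = mk_survey(
        "YA2", "young_adult",
        [
            ("Dana Eastwick", "mother", "family",
             {"friendship", "emotional", "advice", "financial", "logistical"}),
            ("Kim Eastwick", "brother", "family",
             {"friendship", "emotional", "advice", "financial", "logistical"}),
            ("Mo Fenwick", "therapist", "professional",
             {"friendship", "emotional", "advice", "financial", "logistical", "job"}),
            ("Ira Garnet", "job coach", "professional",
             {"friendship", "emotional", "advice", "job"}),
            ("Ash Hollis", "counselor", "professional", {"friendship", "job"}),
        ],
        {(1, 2): 3, (1, 3): 3, (1, 4): 2, (1, 5): 1, (2, 3): 1, (2, 4): 1,
         (4, 5): 2},  # 7/10 ties
    )
    pa = mk_survey(
        "PA2", "parent",
        [
            ("Mo Fenwick", "therapist", "professional",
             {"friendship", "emotional", "advice"}),
            ("Vi Ives", "aunt", "family",
             {"friendship", "emotional", "advice", "logistical"}),
            ("Gil Juniper", "job coach", "professional",
             {"friendship", "emotional", "advice", "job"}),
        ],
        {(1, 2): 1, (2, 3): 2},  # 2/3 ties, no isolates
    )
    return ya, pa


@pytest.fixture
def pair3():
    """Subset pair: parent roster contained in YA roster; one discrepant tie.

    The young adult reports the parent's two alters as connected; the
    parent reports the same pair as unconnected.  The young adult did not
    name the parent, so parent centrality is not calculable.
    """
    ya = mk_survey(
        "YA3", "young_adult",
        [
            ("Kai Marsh", "brother", "family",
             {"emotional", "financial", "logistical"}),
            ("Wren Marsh", "sister", "family", {"logistical"}),
            ("Sage Thorne", "aunt", "family", {"logistical"}),
            ("Quinn Vale", "friend", "community", {"friendship", "job"}),
            ("Reese Winslow", "neighbor", "community", {"friendship"}),
        ],
        {(1, 2): 2, (1, 3): 2, (2, 3): 2, (1, 4): 1, (2, 4): 1, (3, 5): 1,
         (4, 5): 1},  # 7/10 ties incl. the (2,3) pair the parent disputes
    )
    pa = mk_survey(
        "PA3", "parent",
        [
            ("Wren Marsh", "sister", "family", {"emotional", "logistical"}),
            ("Sage Thorne", "aunt", "family", {"friendship", "emotional"}),
        ],
        {},  # parent reports the pair as unconnected -> density 0
    )
    return ya, pa


@pytest.fixture
def study_pairs(pair1, pair2, pair3):
    return [pair1, pair2, pair3]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
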