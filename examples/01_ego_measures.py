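"""Egocentric measures for a single respondent.

Builds the survey of a young adult who named five important people —
four mutually tied family members and one friend nobody else interacts
with — and prints the standard egocentric measures.
"""

from duonet import ego_measures as em
from duonet.types import AlterRecord, EgoSurvey, TieReport

alters = (
    AlterRecord("Dana Ashford", 1, "mother", "family",
                frozenset({"friendship", "emotional", "advice", "financial"})),
    AlterRecord("Evan Ashford", 2, "father", "family",
                frozenset({"friendship", "emotional", "financial"})),
    AlterRecord("Lee Ashford", 3, "brother", "family",
                frozenset({"friendship", "emotional"})),
    AlterRecord("Gwen Ashford", 4, "grandmother", "family",
                frozenset({"friendship"})),
    AlterRecord("Quinn Vale", 5, "friend", "community",
                frozenset({"friendship", "job"})),
)
tied = {(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)}
ties = tuple(
    TieReport(a, b, 2 if (a, b) in tied else 0)
    for a in range(1, 6) for b in range(a + 1, 6)
)
survey = EgoSurvey("EGO-01", "young_adult", alters, ties).validate()

net = em.from_survey(survey)
print(f"network size        : {em.network_size(net)}")
print(f"network density     : {em.network_density(net):.2f}")
print(f"disconnected alters : {em.disconnected_count(net)}")
print(f"role composition    : "
      f"{ {k: round(v) for k, v in em.role_composition(net).items()} }")
print(f"support prevalence  : "
      f"{ {k: round(v) for k, v in em.support_prevalence(net).items()} }")
print(f"family friendship % : {em.family_friendship_pct(net):.0f}")

# Density 0.60 means 6 of the 10 possible alter pairs interact; the one
# disconnected alter is the friend with no ties to the family block.
# Family friendship 100 means every family member also provides friendship.
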