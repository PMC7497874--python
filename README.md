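# duonet

Egocentric and duocentric social-network measures for name-generator
surveys, built for health-outcomes research on the personal networks of
autistic young adults and their parents.

A respondent (the *ego*) answers a name generator — "name up to five people
who are very important to you" — and, for each named person (*alter*),
reports their role, the supports they provide, and whether each pair of
alters interacts.  `duonet` turns these wide survey exports into networks
and computes:

- **Egocentric measures** per ego: network size *n*; density
  `D = |ties| / C(n, 2)` over alter–alter ties (the ego is excluded —
  the name generator ties the ego to every alter by construction);
  role composition over {family, community, professional}; prevalence of
  six support types (friendship, emotional, advice, financial, logistical,
  job); percent of family alters providing friendship; and the count of
  disconnected alters.
- **Duocentric merging**: a young adult's and their parent's surveys are
  combined by matching alters on normalized name (role class breaks ties),
  resolving conflicting tie reports with the *maximum value* and logging
  every conflict as a discrepancy.
- **Duocentric measures**: overlap and unique members, per-respondent size,
  density and disconnected counts, parent centrality
  `C_p = (alters tied to the parent) / (n − 1)` on the young adult's
  network (NA when the young adult did not name the parent), five yes/no
  characteristics using a ≥75% rule, and social-capital **ADD counts** —
  how many parent-unique alters contribute each role or support.
- **Synthetic cohorts**: a seeded generator of single egos and matched
  young-adult/parent pairs with the assumed statistical structure, for
  testing every stage without any survey data.
- **Sociogram export**: classical MDS layouts on geodesic distance, with
  role-colored GraphML / DOT / JSON output.

## Worked example

`examples/02_duocentric_merge.py` merges a young adult's five-alter family
network with the mother's four-alter support network (one shared alter, the
father):

```
merged nodes          : 8 (overlap 1, unique YA 4, unique PA 3)
densities             : YA 0.60, PA 0.17
parent centrality     : 75%
discrepancies         : 0
ADD (parent-unique)   : {'family': 2, 'community': 1, 'emotional': 3, 'advice': 1, 'job': 1}
```

YA density 0.60 means 6 of the 10 possible alter pairs interact; PA density
0.17 means the parent's alters are nearly strangers to each other (1 of 6
pairs).  Parent centrality 75% says the mother is tied to 3 of the 4 other
people her child named.  The ADD counts show what the parent's three unique
alters contribute beyond the young adult's own network — here, among other
things, one source of job support.

The other examples cover per-ego measures (`01`), synthetic cohort
generation and cohort summaries (`03`), and sociogram export (`04`).
A thin CLI mirrors the pipeline: `duonet simulate | parse | ego-measures |
merge | export` (see `duonet --help`).

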