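# Methods

## Data model

A survey is one respondent's complete name-generator answers: an ordered
roster of up to `roster_cap` alters (default 5, configurable — small caps
are known to truncate real networks), each with a free-text role, a role
class in {family, community, professional}, and a subset of six support
types {friendship, emotional, advice, financial, logistical, job}; plus
exactly one tie report per unordered alter pair with an ordinal
interaction frequency.

The frequency scale is 0–3 (0 never, 1 rarely, 2 monthly, 3 weekly or
more) and is configurable; nothing downstream depends on the labels, only
on 0 vs >0.  All density and degree computations binarize at frequency ≥ 1.
Surveys are serialized as a flat wide CSV (one row per respondent, columns
documented in `survey_io`) or an equivalent nested JSON; write-then-read
is the identity on every field.

Free-text roles are classified by a vocabulary table; unmapped strings
default to *community* (the residual category for non-kin, non-provider
roles such as friend or neighbor) with a logged warning.

## Egocentric measures

All measures are alter-only: the ego is excluded because the name
generator ties the ego to every alter by construction, so including those
ties would add a constant and compress variation.

- size: number of alters named.
- density: alter–alter ties / C(n, 2).  Undefined (NA) for n < 2: a
  two-alter untied network has density 0, but a one-alter network has no
  possible pairs at all, and the two cases must not be conflated.
- role composition and support prevalence: percentages of the roster;
  composition sums to 100 up to rounding.
- family friendship: percent of *family* alters providing friendship.
  The denominator is family alters only; with no family alters the value
  is NA per ego and coerced to 0 only in cohort means, matching the
  convention of reporting "no family friendship" as 0%.
- disconnected count: alters with zero alter–alter degree.
- cohort summary: unweighted means over egos (plus median size).  NA
  densities are dropped from the density mean rather than imputed.

Reported values keep full precision; display rounding (2 decimals for
densities, whole percents) is left to the caller.

## Duocentric merge

Alters are matched across the young adult's and the parent's rosters by
exact normalized name (NFKC, casefold, punctuation stripped, whitespace
collapsed).  Role class is used only to choose among multiple same-key
candidates; two same-key alters within one survey are an error unless the
policy explicitly allows duplicates.  No fuzzy or phonetic matching: at
the roster sizes involved, silent false matches are worse than a manual
review pass.

The merged network's nodes are the unified alters with provenance
(ya_only / pa_only / both).  Edge resolution:

- both respondents reported the pair → weight = max of the two ordinal
  reports; a discrepancy (ya value, pa value, resolved = max) is logged
  whenever they differ;
- one respondent reported the pair → that report stands;
- neither respondent named both endpoints → the pair is *unobservable*
  and carries no edge (recorded separately from observed non-ties).

The parent respondent appears as a node only when the young adult named
them as an alter.  The parent alter is identified by the raw role string
(mother/father/parent/stepparent/guardian, configurable, with the
most-important match winning) — the survey has no explicit "this alter is
the co-respondent" flag, so role is the only available signal; an explicit
override is accepted where the linkage is known.

`DuoNetwork.project(side)` returns one respondent's view of the *merged*
network (resolved values), so merging the two projections reproduces the
network with an empty discrepancy log — the merge is idempotent, and
symmetric in which respondent held the higher value.  The raw
pre-resolution reports remain available (`ya_reports` / `pa_reports`) for
per-respondent measures.

## Duocentric measures

Size, density and disconnected counts are reported per respondent network
(the merged network's density is available by applying the egocentric
suite to it, but pair-level reporting follows the per-respondent
convention).  Overlap and unique counts partition the merged node set.

Parent centrality = alters tied to the parent / (n − 1), computed on the
young adult's network with the young adult's own tie reports; NA when the
parent was not named.  An optional `frame="merged"` mode computes it on
the full merged node set, counting the parent's implicit ties to every
alter the parent named; this goes beyond the per-respondent convention
and is labeled as such.

The five characteristics: parent-only alters, youth-only alters, parent
network is a subset (no parent-unique alters and every parent alter
overlaps — vacuously true for an empty parent roster, which is flagged
degenerate), overlap alters highly tied, and parent highly central.
"High" codes use ≥ 0.75 ("75% or more").  The overlap code requires every
overlap alter to reach the threshold against all other merged alters,
because the pair gets a single code.

ADD counts count *alters*, not support instances: `add[k]` = number of
parent-unique alters carrying role or support `k`, i.e. the resources
reachable only through the parent's network.  A subset parent network
therefore adds nothing.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: roster
sizes drawn from a distribution concentrated at the cap (default
(0, 0, .02, .02, .02, .94) over sizes 0–5, mean 4.88, median 5); roles
i.i.d. (default ≈ 60/36/4 family/community/professional); supports
per-alter Bernoulli by role class (defaults chosen so cohort prevalences
sit near friendship 75 / emotional 75 / advice 73 / financial 34 /
logistical 31 / job 24, with family providing more financial/logistical
and professionals more job support); ties Bernoulli with role-block
probabilities (family–family 0.95 and the other blocks 0.25–0.45, giving
family closure and cohort densities near 0.67); frequencies uniform 1–3
when a tie exists.

Matched pairs: a fraction of egos (default 3/17) get a parent survey.
Each parent roster slot copies a young-adult alter with `overlap_prob`
(exact name string, or case/punctuation noise in `name_noise` mode to
exercise normalization), otherwise draws a fresh alter.  The young adult
names the parent with `parent_named_prob` (the parent then sits at rank 1
as "mother"); the parent never names themself.  Tie reports over shared
pairs copy the young adult's value and flip interaction status with
`discrepancy_prob`; all other parent pairs are drawn fresh.

Same spec (including seed) ⇒ byte-identical output files.  What the
generator does **not** emulate: real name ambiguity beyond surface noise
(no nicknames or misspellings), correlation between supports within an
alter, degree heterogeneity beyond role blocks, and any association
between ego attributes and network structure.  Passing parameter-recovery
tests therefore shows the pipeline is unbiased under the assumed model,
not that the model captures real cohorts.

## Layout and export

Sociogram coordinates come from classical (Torgerson) MDS on the geodesic
distance matrix: double-center the squared distances and take the top two
eigenvectors, with a fixed sign convention (largest-magnitude entry per
axis positive) for determinism.  Geodesic distance is undefined across
components; connected components are laid out jointly with a finite
pseudo-distance of (largest finite distance + 1), and isolates are placed
on a surrounding ring at 1.2× the core radius.  Exact coordinate
collisions (degenerate eigen-cases) are broken by a seeded 1e-3 jitter.
Exports (GraphML, DOT, JSON) carry role class, provenance, coordinates, a
fixed role→color map, and edge weights; the JSON form round-trips.

## Test problem sizes

Property suites run on a few hundred generated instances per property;
the brute-force oracle suite uses 1,000 random instances (700 single
egos, 300 matched pairs) and parameter recovery uses cohorts of 250–400
egos, large enough that ±3 standard errors separates real bias from
Monte-Carlo noise.

## Known limitations

- Matching is within one matched pair only; no cross-pair entity
  resolution, and no probabilistic record linkage.
- Only two networks merge (the method is strictly duocentric).
- Cohort-level inferential statistics are out of scope; the summary is
  descriptive.
- The five-person cap truncates real rosters; measures are faithful to
  the reported roster, not the true network.
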