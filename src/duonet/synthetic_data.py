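"""Seeded generator of synthetic name-generator surveys and matched pairs.

Emulates the structure of a survey cohort of young adults (and, for a
fraction of them, a parent): a roster of up to five alters ranked by
importance, roles drawn from {family, community, professional}, six binary
support flags per alter, a complete undirected alter–alter tie report per
unique pair with ordinal frequency, partially overlapping parent rosters,
and occasional conflicting tie reports between the two respondents of a
pair.

Tie probabilities are role-block structured (family–family high, the rest
low) to reproduce the family-closure motif typical of these cohorts.
All alter names come from a bundled synthetic name list; matched alters
share exact strings, with an optional perturbation mode that injects
case/punctuation noise to exercise name normalization downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import survey_io
from .types import (
    DEFAULT_FREQUENCY_MAX,
    DEFAULT_ROSTER_CAP,
    ROLE_CLASSES,
    SUPPORT_TYPES,
    AlterRecord,
    EgoSurvey,
    TieReport,
    ValidationError,
)

__all__ = ["CohortSpec", "Cohort", "generate_ego", "generate_matched_pair",
           "generate_cohort", "write_cohort"]

# Synthetic given names and surnames; any resemblance to real people is
# coincidental.  Large enough that a pair's rosters never exhaust the pool.
_FIRST = (
    "Avery", "Blake", "Casey", "Devon", "Emery", "Finley", "Gray", "Harper",
    "Indigo", "Jordan", "Kai", "Lennon", "Morgan", "Noel", "Oakley", "Parker",
    "Quinn", "Reese", "Sage", "Tatum", "Umber", "Vesper", "Wren", "Xan",
    "Yael", "Zephyr", "Arden", "Briar", "Cove", "Dale", "Ellis", "Frankie",
)
_LAST = (
    "Ashford", "Birch", "Calder", "Dunmore", "Eastwick", "Fenwick", "Garnet",
    "Hollis", "Ives", "Juniper", "Kestrel", "Larkspur", "Marsh", "Northgate",
    "Oakhurst", "Pembroke", "Quill", "Rowan", "Setter", "Thorne", "Underhill",
    "Vale", "Winslow", "Yarrow",
)

_ROLE_VOCAB = {
    "family": ("brother", "sister", "grandmother", "grandfather", "aunt", "uncle"),
    "community": ("friend", "neighbor", "coworker", "classmate"),
    "professional": ("therapist", "counselor", "job coach", "teacher"),
}

# Defaults echo a small feasibility cohort: roster sizes concentrated at the
# cap (mean 4.88, median 5), roles ~61/36/4 family/community/professional,
# support prevalences near 75/75/73/34/31/24.
_DEFAULT_ROSTER_DIST = (0.0, 0.0, 0.02, 0.02, 0.02, 0.94)
_DEFAULT_ROLE_PROBS = (0.604, 0.356, 0.040)
_DEFAULT_SUPPORT_PROBS = {
    "family": {
        "friendship": 0.60, "emotional": 0.85, "advice": 0.80,
        "financial": 0.50, "logistical": 0.40, "job": 0.15,
    },
    "community": {
        "friendship": 0.95, "emotional": 0.60, "advice": 0.65,
        "financial": 0.10, "logistical": 0.20, "job": 0.30,
    },
    "professional": {
        "friendship": 0.30, "emotional": 0.70, "advice": 0.80,
        "financial": 0.10, "logistical": 0.30, "job": 0.50,
    },
}
_DEFAULT_TIE_PROBS = {
    ("family", "family"): 0.95,
    ("community", "community"): 0.30,
    ("professional", "professional"): 0.30,
    ("family", "community"): 0.45,
    ("family", "professional"): 0.40,
    ("community", "professional"): 0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic survey cohort.

    ``roster_size_distribution`` gives probabilities over roster sizes
    0..cap; ``alter_tie_prob`` maps unordered role-class pairs to tie
    probabilities; ``support_probs`` maps role class to per-support
    probabilities.  ``pair_fraction`` of egos also get a parent survey, in
    which each parent alter matches a young-adult alter with
    ``overlap_prob``, the young adult names the parent with
    ``parent_named_prob``, and a shared pair's two tie reports conflict
    with ``discrepancy_prob``.
    """

    n_egos: int = 17
    roster_cap: int = DEFAULT_ROSTER_CAP
    roster_size_distribution: tuple[float, ...] = _DEFAULT_ROSTER_DIST
    role_probs: tuple[float, float, float] = _DEFAULT_ROLE_PROBS
    support_probs: dict = field(default_factory=lambda: _DEFAULT_SUPPORT_PROBS)
    alter_tie_prob: dict = field(default_factory=lambda: _DEFAULT_TIE_PROBS)
    frequency_max: int = DEFAULT_FREQUENCY_MAX
    pair_fraction: float = 3 / 17
    overlap_prob: float = 0.4
    parent_named_prob: float = 2 / 3
    discrepancy_prob: float = 0.1
    name_noise: bool = False  # case/punctuation perturbation on matched names
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_egos < 1 or self.roster_cap < 1:
            raise ValidationError("n_egos and roster_cap must be positive")
        dist = np.asarray(self.roster_size_distribution, dtype=float)
        if len(dist) != self.roster_cap + 1:
            raise ValidationError(
                "roster_size_distribution must cover sizes 0..roster_cap"
            )
        if (dist < 0).any() or not np.isclose(dist.sum(), 1.0):
            raise ValidationError("roster_size_distribution must be a simplex")
        rp = np.asarray(self.role_probs, dtype=float)
        if len(rp) != 3 or (rp < 0).any() or not np.isclose(rp.sum(), 1.0):
            raise ValidationError("role_probs must be a 3-simplex")
        for p in (
            self.pair_fraction,
            self.overlap_prob,
            self.parent_named_prob,
            self.discrepancy_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        for role, probs in self.support_probs.items():
            if role not in ROLE_CLASSES:
                raise ValidationError(f"unknown role class {role!r}")
            for s, p in probs.items():
                if s not in SUPPORT_TYPES or not 0.0 <= p <= 1.0:
                    raise ValidationError(f"bad support prob {role}/{s}={p}")
        for key, p in self.alter_tie_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"bad tie prob {key}={p}")
        return self


def _tie_prob(spec: CohortSpec, role_a: str, role_b: str) -> float:
    key = (role_a, role_b) if (role_a, role_b) in spec.alter_tie_prob else (role_b, role_a)
    return spec.alter_tie_prob[key]


def _draw_names(rng: np.random.Generator, k: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < k:
        name = f"{_FIRST[rng.integers(len(_FIRST))]} {_LAST[rng.integers(len(_LAST))]}"
        if name not in taken:
            taken.add(name)
            out.append(name)
    return out


def _perturb(name: str, rng: np.random.Generator) -> str:
    """Case/punctuation noise that normalization must undo."""
    choice = rng.integers(3)
    if choice == 0:
        return name.upper()
    if choice == 1:
        return name.replace(" ", ".  ")
    return " " + name.lower() + " "


def _draw_supports(
    spec: CohortSpec, role_class: str, rng: np.random.Generator
) -> frozenset[str]:
    probs = spec.support_probs[role_class]
    return frozenset(
        s for s in SUPPORT_TYPES if rng.random() < probs.get(s, 0.0)
    )


def _draw_ties(
    spec: CohortSpec, alters: tuple[AlterRecord, ...], rng: np.random.Generator
) -> tuple[TieReport, ...]:
    ties = []
    by_rank = {a.rank: a for a in alters}
    ranks = sorted(by_rank)
    for i, a in enumerate(ranks):
        for b in ranks[i + 1 :]:
            p = _tie_prob(spec, by_rank[a].role_class, by_rank[b].role_class)
            freq = int(rng.integers(1, spec.frequency_max + 1)) if rng.random() < p else 0
            ties.append(TieReport(a, b, freq))
    return tuple(ties)


def generate_ego(
    spec: CohortSpec,
    rng: np.random.Generator,
    ego_id: str = "EGO",
    taken_names: Optional[set[str]] = None,
    force_parent_first: bool = False,
) -> EgoSurvey:
    """Draw one young-adult survey from the cohort distribution.

    Roster size follows ``roster_size_distribution``; roles are i.i.d.
    ``role_probs``; supports are per-alter Bernoulli by role; ties are
    Bernoulli by role-block with ordinal frequency uniform on 1..K when
    present.  ``force_parent_first`` makes alter 1 the ego's mother (used
    when building matched pairs where the young adult names the parent).
    """
    spec.validate()
    taken = taken_names if taken_names is not None else set()
    size = int(rng.choice(spec.roster_cap + 1, p=spec.roster_size_distribution))
    if force_parent_first:
        size = max(size, 1)
    names = _draw_names(rng, size, taken)
    alters = []
    for i in range(size):
        if i == 0 and force_parent_first:
            role_class, role_raw = "family", "mother"
        else:
            role_class = str(rng.choice(ROLE_CLASSES, p=spec.role_probs))
            vocab = _ROLE_VOCAB[role_class]
            role_raw = vocab[rng.integers(len(vocab))]
        alters.append(
            AlterRecord(
                label=names[i],
                rank=i + 1,
                role_raw=role_raw,
                role_class=role_class,
                supports=_draw_supports(spec, role_class, rng),
            )
        )
    alters = tuple(alters)
    return EgoSurvey(
        ego_id=ego_id,
        reporter_kind="young_adult",
        alters=alters,
        tie_reports=_draw_ties(spec, alters, rng),
        ego_attributes={"age": str(int(rng.integers(19, 28)))},
        roster_cap=spec.roster_cap,
    ).validate()


def generate_matched_pair(
    spec: CohortSpec, rng: np.random.Generator, pair_id: str = "P1"
) -> tuple[EgoSurvey, EgoSurvey]:
    """Draw a young-adult survey and the matched parent survey.

    Parent alters match young-adult alters with ``overlap_prob`` (names
    copied exactly, or perturbed when ``name_noise`` is on); tie reports
    over shared alter pairs are copied from the young adult and then
    flipped with ``discrepancy_prob``; remaining parent pairs are drawn
    fresh from the role-block tie model.
    """
    spec.validate()
    taken: set[str] = set()
    names_parent = rng.random() < spec.parent_named_prob
    ya = generate_ego(
        spec, rng, ego_id=f"{pair_id}-YA", taken_names=taken,
        force_parent_first=names_parent,
    )

    pa_size = int(rng.choice(spec.roster_cap + 1, p=spec.roster_size_distribution))
    # overlap candidates: YA alters other than the parent respondent herself
    candidates = [a for a in ya.alters if not (names_parent and a.rank == 1)]
    rng.shuffle(candidates)
    pa_alters: list[AlterRecord] = []
    copied_from: dict[int, int] = {}  # pa rank -> ya rank
    n_new = 0
    for i in range(pa_size):
        take_overlap = candidates and rng.random() < spec.overlap_prob
        if take_overlap:
            src = candidates.pop()
            label = _perturb(src.label, rng) if spec.name_noise else src.label
            pa_alters.append(
                AlterRecord(
                    label=label,
                    rank=i + 1,
                    role_raw=src.role_raw,
                    role_class=src.role_class,
                    supports=_draw_supports(spec, src.role_class, rng),
                )
            )
            copied_from[i + 1] = src.rank
        else:
            n_new += 1
            role_class = str(rng.choice(ROLE_CLASSES, p=spec.role_probs))
            vocab = _ROLE_VOCAB[role_class]
            pa_alters.append(
                AlterRecord(
                    label=_draw_names(rng, 1, taken)[0],
                    rank=i + 1,
                    role_raw=vocab[rng.integers(len(vocab))],
                    role_class=role_class,
                    supports=_draw_supports(spec, role_class, rng),
                )
            )

    ties = []
    for i in range(1, pa_size + 1):
        for j in range(i + 1, pa_size + 1):
            if i in copied_from and j in copied_from:
                # shared pair: duplicate the YA report, then maybe flip it
                freq = ya.tie_frequency(copied_from[i], copied_from[j])
                if rng.random() < spec.discrepancy_prob:
                    freq = (
                        0 if freq > 0 else int(rng.integers(1, spec.frequency_max + 1))
                    )
            else:
                a, b = pa_alters[i - 1], pa_alters[j - 1]
                p = _tie_prob(spec, a.role_class, b.role_class)
                freq = (
                    int(rng.integers(1, spec.frequency_max + 1))
                    if rng.random() < p
                    else 0
                )
            ties.append(TieReport(i, j, freq))

    pa = EgoSurvey(
        ego_id=f"{pair_id}-PA",
        reporter_kind="parent",
        alters=tuple(pa_alters),
        tie_reports=tuple(ties),
        roster_cap=spec.roster_cap,
    ).validate()
    return ya, pa


@dataclass(frozen=True)
class Cohort:
    """A generated cohort plus its ground-truth manifest."""

    surveys: tuple[EgoSurvey, ...]  # all young-adult surveys
    pairs: tuple[tuple[EgoSurvey, EgoSurvey], ...]
    manifest: dict


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate ``n_egos`` young-adult surveys; the first ``round(n_egos *
    pair_fraction)`` egos also get a matched parent survey."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_paired = int(round(spec.n_egos * spec.pair_fraction))
    surveys: list[EgoSurvey] = []
    pairs: list[tuple[EgoSurvey, EgoSurvey]] = []
    for i in range(spec.n_egos):
        if i < n_paired:
            ya, pa = generate_matched_pair(spec, rng, pair_id=f"P{i + 1:03d}")
            surveys.append(ya)
            pairs.append((ya, pa))
        else:
            surveys.append(
                generate_ego(spec, rng, ego_id=f"E{i + 1:03d}", taken_names=set())
            )
    manifest = {
        "spec": _spec_to_jsonable(spec),
        "n_egos": spec.n_egos,
        "n_pairs": n_paired,
        "total_alters": sum(s.n_alters for s in surveys),
        "roster_sizes": [s.n_alters for s in surveys],
        "parent_roster_sizes": [pa.n_alters for _, pa in pairs],
        "overlap_counts": [
            sum(
                1
                for b in pa.alters
                if any(a.label == b.label for a in ya.alters)
            )
            for ya, pa in pairs
        ],
    }
    return Cohort(tuple(surveys), tuple(pairs), manifest)


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["alter_tie_prob"] = {
        "|".join(k): v for k, v in spec.alter_tie_prob.items()
    }
    return d


def write_cohort(cohort: Cohort, outdir: Union[str, Path]) -> dict[str, Path]:
    """Emit young-adult and parent survey CSVs plus a manifest JSON.

    Output is byte-identical for a fixed spec (including seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "young_adults": outdir / "young_adult_surveys.csv",
        "parents": outdir / "parent_surveys.csv",
        "manifest": outdir / "manifest.json",
    }
    survey_io.write_surveys(list(cohort.surveys), paths["young_adults"])
    survey_io.write_surveys([pa for _, pa in cohort.pairs], paths["parents"])
    paths["manifest"].write_text(
        json.dumps(cohort.manifest, indent=1, sort_keys=True) + "\n"
    )
    return paths
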