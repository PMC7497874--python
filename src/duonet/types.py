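"""Core domain types for egocentric and duocentric network surveys.

An *ego* is a survey respondent; *alters* are the people the ego names in
response to a name generator ("Please name up to five people who are very
important to you").  Each alter carries a role (classified into family /
community / professional), a set of support types the alter provides, and
the ego reports an interaction frequency for every unordered alter pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "ROLE_CLASSES",
    "SUPPORT_TYPES",
    "ReporterKind",
    "AlterRecord",
    "TieReport",
    "EgoSurvey",
    "ValidationError",
    "DEFAULT_FREQUENCY_MAX",
    "DEFAULT_ROSTER_CAP",
]

#: The three role classes alters are binned into.
ROLE_CLASSES: tuple[str, ...] = ("family", "community", "professional")

#: The six support types an alter can provide to the ego.
SUPPORT_TYPES: tuple[str, ...] = (
    "friendship",
    "emotional",
    "advice",
    "financial",
    "logistical",
    "job",
)

#: Ordinal interaction-frequency ceiling: 0 never, 1 rarely, 2 monthly, 3 weekly+.
DEFAULT_FREQUENCY_MAX = 3

#: Name-generator roster cap used by the study design.
DEFAULT_ROSTER_CAP = 5


class ValidationError(ValueError):
    """A survey or record violates a structural invariant."""


class ReporterKind(str, Enum):
    YOUNG_ADULT = "young_adult"
    PARENT = "parent"


@dataclass(frozen=True)
class AlterRecord:
    """One named alter: label, importance rank (1 = most important), role, supports."""

    label: str
    rank: int
    role_raw: str
    role_class: str
    supports: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"alter rank must be >= 1, got {self.rank}")
        if self.role_class not in ROLE_CLASSES:
            raise ValidationError(
                f"role_class {self.role_class!r} not in {ROLE_CLASSES}"
            )
        bad = set(self.supports) - set(SUPPORT_TYPES)
        if bad:
            raise ValidationError(f"unknown support types: {sorted(bad)}")
        object.__setattr__(self, "supports", frozenset(self.supports))

    def provides(self, support: str) -> bool:
        return support in self.supports


@dataclass(frozen=True)
class TieReport:
    """Ego-reported interaction between two alters, identified by rank.

    ``frequency`` is ordinal 0..K with 0 meaning "they do not interact";
    ``interacts`` is derived (frequency > 0).  Pairs are stored with
    rank_a < rank_b.
    """

    rank_a: int
    rank_b: int
    frequency: int

    def __post_init__(self) -> None:
        if self.rank_a == self.rank_b:
            raise ValidationError("tie report between an alter and itself")
        if self.rank_a > self.rank_b:
            a, b = self.rank_b, self.rank_a
            object.__setattr__(self, "rank_a", a)
            object.__setattr__(self, "rank_b", b)
        if self.frequency < 0:
            raise ValidationError(f"negative tie frequency {self.frequency}")

    @property
    def interacts(self) -> bool:
        return self.frequency > 0

    @property
    def pair(self) -> tuple[int, int]:
        return (self.rank_a, self.rank_b)


@dataclass(frozen=True)
class EgoSurvey:
    """One respondent's complete name-generator answers.

    Invariants (checked by :func:`validate`): at most ``roster_cap`` alters,
    ranks 1..n each used once, and exactly one tie report per unordered
    alter pair.
    """

    ego_id: str
    reporter_kind: ReporterKind
    alters: tuple[AlterRecord, ...]
    tie_reports: tuple[TieReport, ...]
    ego_attributes: dict = field(default_factory=dict)
    roster_cap: int = DEFAULT_ROSTER_CAP

    def __post_init__(self) -> None:
        object.__setattr__(self, "alters", tuple(self.alters))
        object.__setattr__(self, "tie_reports", tuple(self.tie_reports))
        if isinstance(self.reporter_kind, str):
            object.__setattr__(self, "reporter_kind", ReporterKind(self.reporter_kind))

    # -- convenience accessors -------------------------------------------------
    @property
    def n_alters(self) -> int:
        return len(self.alters)

    def alter_by_rank(self, rank: int) -> AlterRecord:
        for a in self.alters:
            if a.rank == rank:
                return a
        raise KeyError(rank)

    def tie_frequency(self, rank_a: int, rank_b: int) -> int:
        pair = (min(rank_a, rank_b), max(rank_a, rank_b))
        for t in self.tie_reports:
            if t.pair == pair:
                return t.frequency
        raise KeyError(pair)

    def validate(self) -> "EgoSurvey":
        """Check structural invariants; return self for chaining."""
        if self.roster_cap < 1:
            raise ValidationError("roster_cap must be positive")
        if self.n_alters > self.roster_cap:
            raise ValidationError(
                f"{self.ego_id}: {self.n_alters} alters exceeds roster cap "
                f"{self.roster_cap}"
            )
        ranks = [a.rank for a in self.alters]
        if len(set(ranks)) != len(ranks):
            dupes = sorted({r for r in ranks if ranks.count(r) > 1})
            raise ValidationError(f"{self.ego_id}: duplicate alter rank(s) {dupes}")
        if ranks and set(ranks) != set(range(1, self.n_alters + 1)):
            raise ValidationError(
                f"{self.ego_id}: alter ranks {sorted(ranks)} are not 1..{self.n_alters}"
            )
        expected_pairs = {
            (a, b)
            for i, a in enumerate(sorted(ranks))
            for b in sorted(ranks)[i + 1 :]
        }
        seen = [t.pair for t in self.tie_reports]
        if len(set(seen)) != len(seen):
            raise ValidationError(f"{self.ego_id}: duplicate tie report pair")
        missing = expected_pairs - set(seen)
        if missing:
            raise ValidationError(
                f"{self.ego_id}: missing tie report for pair(s) {sorted(missing)}"
            )
        extra = set(seen) - expected_pairs
        if extra:
            raise ValidationError(
                f"{self.ego_id}: tie report for unnamed alter pair(s) {sorted(extra)}"
            )
        return self

    def with_alters(
        self,
        alters: tuple[AlterRecord, ...],
        tie_reports: tuple[TieReport, ...],
    ) -> "EgoSurvey":
        return replace(self, alters=tuple(alters), tie_reports=tuple(tie_reports))


def complete_tie_reports(
    n_alters: int, frequencies: Optional[dict[tuple[int, int], int]] = None
) -> tuple[TieReport, ...]:
    """Build a full tie-report set for ranks 1..n, defaulting to no interaction."""
    frequencies = frequencies or {}
    out = []
    for a in range(1, n_alters + 1):
        for b in range(a + 1, n_alters + 1):
            out.append(TieReport(a, b, frequencies.get((a, b), 0)))
    return tuple(out)
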