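"""Merge a young-adult and a parent egocentric survey into a duocentric network.

Alters are matched across the two rosters by exact normalized name, with
role class used only to disambiguate; conflicting tie reports over shared
alter pairs are resolved by taking the maximum ordinal value, and every
conflict is logged as a :class:`Discrepancy`.  The parent respondent
appears as a node only when the young adult named them as an alter.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .types import AlterRecord, EgoSurvey, TieReport, ValidationError

__all__ = [
    "normalize_name",
    "MatchPolicy",
    "AlterMatch",
    "Discrepancy",
    "UnifiedAlter",
    "DuoNetwork",
    "match_alters",
    "merge_duocentric",
    "find_parent_rank",
    "DEFAULT_PARENT_ROLES",
]

#: Role strings treated as "this alter is the parent respondent".
DEFAULT_PARENT_ROLES = frozenset(
    {"mother", "mom", "father", "dad", "parent", "stepmother", "stepfather", "guardian"}
)

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_name(label: str) -> str:
    """Canonical matching key: casefolded, punctuation-free, single-spaced."""
    if not label or not label.strip():
        raise ValidationError("cannot normalize an empty name")
    s = unicodedata.normalize("NFKC", label)
    s = _PUNCT.sub(" ", s.casefold())
    return _WS.sub(" ", s).strip()


@dataclass(frozen=True)
class MatchPolicy:
    """How alters are matched across the two rosters.

    Matching is exact on the normalized name; ``use_role_tiebreak`` lets a
    shared role class confirm a match when the same key occurs more than
    once on one side (otherwise such keys are an error).  No fuzzy or
    phonetic matching.
    """

    use_role_tiebreak: bool = True
    allow_duplicate_keys: bool = False


@dataclass(frozen=True)
class AlterMatch:
    """One unified alter: a YA roster slot, a parent roster slot, or both."""

    unified_id: str
    ya_rank: Optional[int]
    pa_rank: Optional[int]
    match_basis: str = "name_exact"  # name_exact | name_plus_role | manual

    @property
    def provenance(self) -> str:
        if self.ya_rank is not None and self.pa_rank is not None:
            return "both"
        return "ya_only" if self.ya_rank is not None else "pa_only"


@dataclass(frozen=True)
class Discrepancy:
    """A shared alter pair whose two tie reports disagree."""

    pair: tuple[str, str]  # unified ids
    ya_value: int
    pa_value: int

    @property
    def resolved_value(self) -> int:
        return max(self.ya_value, self.pa_value)


@dataclass(frozen=True)
class UnifiedAlter:
    unified_id: str
    label: str
    role_class: str
    provenance: str
    ya_rank: Optional[int]
    pa_rank: Optional[int]
    supports_ya: frozenset[str] = frozenset()
    supports_pa: frozenset[str] = frozenset()
    ya_role_raw: str = ""
    pa_role_raw: str = ""
    is_parent: bool = False


@dataclass(frozen=True)
class DuoNetwork:
    """Merged young-adult + parent alter network with provenance.

    ``edges`` holds resolved alter–alter ties (max of the two ordinal
    reports for shared pairs).  ``unobservable_pairs`` are pairs where no
    respondent named both endpoints, so no report exists; they carry no
    edge.  Implicit respondent-to-alter ties (each respondent is tied by
    construction to every alter they named) are not stored as edges; they
    are recovered from provenance where needed.
    """

    pair_id: str
    nodes: tuple[UnifiedAlter, ...]
    edges: dict[tuple[str, str], int]
    discrepancies: tuple[Discrepancy, ...]
    unobservable_pairs: tuple[tuple[str, str], ...]
    parent_node: Optional[str] = None  # unified id, present iff YA named the parent
    # per-respondent raw reports over unified ids, kept for per-frame measures
    ya_reports: dict[tuple[str, str], int] = field(default_factory=dict)
    pa_reports: dict[tuple[str, str], int] = field(default_factory=dict)

    def node(self, unified_id: str) -> UnifiedAlter:
        for n in self.nodes:
            if n.unified_id == unified_id:
                return n
        raise KeyError(unified_id)

    def tied(self, u: str, v: str) -> bool:
        key = (min(u, v), max(u, v))
        return self.edges.get(key, 0) > 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.unified_id,
                label=n.label,
                role_class=n.role_class,
                provenance=n.provenance,
                is_parent=n.is_parent,
            )
        for (u, v), w in sorted(self.edges.items()):
            if w > 0:
                g.add_edge(u, v, weight=w)
        return g

    def project(self, side: str) -> EgoSurvey:
        """One respondent's view of the *merged* network as an egocentric survey.

        ``side`` is "ya" or "pa".  Tie frequencies are the resolved merged
        values (so merging the two projections reproduces the duocentric
        network with an empty discrepancy log — the merge is idempotent);
        the raw pre-resolution reports stay available in ``ya_reports`` /
        ``pa_reports``.
        """
        if side not in ("ya", "pa"):
            raise ValueError("side must be 'ya' or 'pa'")
        keep = ("ya_only", "both") if side == "ya" else ("pa_only", "both")
        members = [n for n in self.nodes if n.provenance in keep]
        rank_of = {
            n.unified_id: (n.ya_rank if side == "ya" else n.pa_rank) for n in members
        }
        alters = tuple(
            AlterRecord(
                label=n.label,
                rank=rank_of[n.unified_id],
                role_raw=(n.ya_role_raw if side == "ya" else n.pa_role_raw),
                role_class=n.role_class,
                supports=(n.supports_ya if side == "ya" else n.supports_pa),
            )
            for n in sorted(members, key=lambda n: rank_of[n.unified_id])
        )
        observed = self.ya_reports if side == "ya" else self.pa_reports
        ties = tuple(
            TieReport(rank_of[u], rank_of[v], self.edges.get(key, 0))
            for key in sorted(observed)
            for u, v in [key]
        )
        ya_id, _, pa_id = self.pair_id.partition("+")
        return EgoSurvey(
            ego_id=ya_id if side == "ya" else (pa_id or f"{ya_id}-pa"),
            reporter_kind="young_adult" if side == "ya" else "parent",
            alters=alters,
            tie_reports=ties,
            roster_cap=max(len(alters), 5),
        ).validate()


def find_parent_rank(
    ya: EgoSurvey, parent_roles: frozenset[str] = DEFAULT_PARENT_ROLES
) -> Optional[int]:
    """Rank of the YA alter who is the parent respondent, by role string.

    Returns the highest-importance (lowest rank) alter whose raw role is a
    parent role; None when the young adult did not name the parent.
    """
    hits = [
        a.rank
        for a in sorted(ya.alters, key=lambda a: a.rank)
        if a.role_raw.strip().lower() in parent_roles
    ]
    return hits[0] if hits else None


def match_alters(
    ya: EgoSurvey, pa: EgoSurvey, policy: MatchPolicy = MatchPolicy()
) -> list[AlterMatch]:
    """Match the two rosters by normalized name; returns one AlterMatch per
    unified alter so that every alter of either survey appears exactly once.

    Raises :class:`~duonet.types.ValidationError` when one survey names two
    alters with the same key and the policy does not allow duplicates.
    """
    ya_keys = {a.rank: normalize_name(a.label) for a in ya.alters}
    pa_keys = {a.rank: normalize_name(a.label) for a in pa.alters}

    for name, keys in (("young adult", ya_keys), ("parent", pa_keys)):
        vals = list(keys.values())
        dupes = sorted({k for k in vals if vals.count(k) > 1})
        if dupes and not policy.allow_duplicate_keys:
            raise ValidationError(
                f"{name} survey names the same person twice (keys {dupes}); "
                "cannot auto-match"
            )

    ya_by_key: dict[str, list[int]] = {}
    for rank, key in ya_keys.items():
        ya_by_key.setdefault(key, []).append(rank)
    pa_by_key: dict[str, list[int]] = {}
    for rank, key in pa_keys.items():
        pa_by_key.setdefault(key, []).append(rank)

    matches: list[AlterMatch] = []
    matched_pa: set[int] = set()
    counter = 1

    def next_id() -> str:
        nonlocal counter
        uid = f"{ya.ego_id}+{pa.ego_id}:U{counter:02d}"
        counter += 1
        return uid

    for a in sorted(ya.alters, key=lambda a: a.rank):
        key = ya_keys[a.rank]
        candidates = [r for r in pa_by_key.get(key, []) if r not in matched_pa]
        basis = "name_exact"
        if len(candidates) > 1 and policy.use_role_tiebreak:
            role_hits = [
                r
                for r in candidates
                if pa.alter_by_rank(r).role_class == a.role_class
            ]
            if role_hits:
                candidates = role_hits
                basis = "name_plus_role"
        if candidates:
            pa_rank = candidates[0]
            matched_pa.add(pa_rank)
            matches.append(AlterMatch(next_id(), a.rank, pa_rank, basis))
        else:
            matches.append(AlterMatch(next_id(), a.rank, None))
    for b in sorted(pa.alters, key=lambda a: a.rank):
        if b.rank not in matched_pa:
            matches.append(AlterMatch(next_id(), None, b.rank))
    return matches


def merge_duocentric(
    ya: EgoSurvey,
    pa: EgoSurvey,
    matches: Optional[list[AlterMatch]] = None,
    pair_id: Optional[str] = None,
    parent_roles: frozenset[str] = DEFAULT_PARENT_ROLES,
) -> DuoNetwork:
    """Build the merged duocentric network under the maximum-value rule.

    For alter pairs reported by both respondents the merged weight is the
    maximum of the two ordinal reports, and a discrepancy is logged when
    they differ; pairs reported by one respondent stand as reported; pairs
    where neither respondent named both endpoints are unobservable.
    """
    ya.validate()
    pa.validate()
    if matches is None:
        matches = match_alters(ya, pa)

    ya_ranks = {m.ya_rank for m in matches if m.ya_rank is not None}
    pa_ranks = {m.pa_rank for m in matches if m.pa_rank is not None}
    if ya_ranks != {a.rank for a in ya.alters} or pa_ranks != {
        a.rank for a in pa.alters
    }:
        raise ValidationError("match list does not cover both rosters exactly")

    parent_rank = find_parent_rank(ya, parent_roles)
    nodes = []
    by_ya: dict[int, str] = {}
    by_pa: dict[int, str] = {}
    for m in matches:
        ya_alter = ya.alter_by_rank(m.ya_rank) if m.ya_rank is not None else None
        pa_alter = pa.alter_by_rank(m.pa_rank) if m.pa_rank is not None else None
        primary = ya_alter or pa_alter
        assert primary is not None
        nodes.append(
            UnifiedAlter(
                unified_id=m.unified_id,
                label=primary.label,
                role_class=primary.role_class,
                provenance=m.provenance,
                ya_rank=m.ya_rank,
                pa_rank=m.pa_rank,
                supports_ya=ya_alter.supports if ya_alter else frozenset(),
                supports_pa=pa_alter.supports if pa_alter else frozenset(),
                ya_role_raw=ya_alter.role_raw if ya_alter else "",
                pa_role_raw=pa_alter.role_raw if pa_alter else "",
                is_parent=(m.ya_rank is not None and m.ya_rank == parent_rank),
            )
        )
        if m.ya_rank is not None:
            by_ya[m.ya_rank] = m.unified_id
        if m.pa_rank is not None:
            by_pa[m.pa_rank] = m.unified_id

    ya_freq = {
        (by_ya[t.rank_a], by_ya[t.rank_b]): t.frequency for t in ya.tie_reports
    }
    pa_freq = {
        (by_pa[t.rank_a], by_pa[t.rank_b]): t.frequency for t in pa.tie_reports
    }

    def canon(d: dict) -> dict[tuple[str, str], int]:
        return {(min(u, v), max(u, v)): w for (u, v), w in d.items()}

    ya_freq = canon(ya_freq)
    pa_freq = canon(pa_freq)

    edges: dict[tuple[str, str], int] = {}
    discrepancies: list[Discrepancy] = []
    unobservable: list[tuple[str, str]] = []
    ids = sorted(n.unified_id for n in nodes)
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            key = (u, v)
            in_ya = key in ya_freq
            in_pa = key in pa_freq
            if in_ya and in_pa:
                w = max(ya_freq[key], pa_freq[key])
                if ya_freq[key] != pa_freq[key]:
                    discrepancies.append(Discrepancy(key, ya_freq[key], pa_freq[key]))
                if w > 0:
                    edges[key] = w
            elif in_ya:
                if ya_freq[key] > 0:
                    edges[key] = ya_freq[key]
            elif in_pa:
                if pa_freq[key] > 0:
                    edges[key] = pa_freq[key]
            else:
                unobservable.append(key)

    return DuoNetwork(
        pair_id=pair_id or f"{ya.ego_id}+{pa.ego_id}",
        nodes=tuple(nodes),
        edges=edges,
        discrepancies=tuple(discrepancies),
        unobservable_pairs=tuple(unobservable),
        parent_node=by_ya.get(parent_rank) if parent_rank is not None else None,
        ya_reports=ya_freq,
        pa_reports=pa_freq,
    )
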