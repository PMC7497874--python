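"""Duocentric network measures, characteristics and social-capital accounting.

Six overall measures per matched pair: per-respondent network size and
density, overlap members, unique members, disconnected members, and parent
centrality.  Five yes/no characteristics use a 75%-or-more threshold for
the "high tie" codes.  The social-capital configuration reports role and
support percentages per respondent plus ADD counts — the number of
parent-unique alters contributing each role or support, i.e. the resources
the parent's network adds beyond the young adult's own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import ego_measures
from .duo_merge import DuoNetwork
from .ego_measures import EgoNetwork, from_survey
from .types import ROLE_CLASSES, SUPPORT_TYPES, EgoSurvey

__all__ = [
    "overlap_and_unique",
    "parent_centrality",
    "characteristics",
    "social_capital_config",
    "duo_measure_set",
    "DuoCharacteristics",
    "HIGH_TIE_THRESHOLD",
]

HIGH_TIE_THRESHOLD = 0.75


def overlap_and_unique(duo: DuoNetwork) -> tuple[int, dict[str, int]]:
    """(overlap_count, {"ya": unique_ya, "pa": unique_pa}) by node provenance."""
    overlap = sum(1 for n in duo.nodes if n.provenance == "both")
    unique = {
        "ya": sum(1 for n in duo.nodes if n.provenance == "ya_only"),
        "pa": sum(1 for n in duo.nodes if n.provenance == "pa_only"),
    }
    return overlap, unique


def _ya_frame(duo: DuoNetwork) -> tuple[list[str], dict[tuple[str, str], int]]:
    ids = [n.unified_id for n in duo.nodes if n.ya_rank is not None]
    return ids, duo.ya_reports


def parent_centrality(
    duo: DuoNetwork, frame: str = "ya"
) -> Optional[float]:
    """Share of the other alters tied to the parent node; None (NA) when the
    young adult did not name the parent.

    The default frame is the young adult's alter network with the young
    adult's own tie reports: alters tied to the parent / (n - 1).  The
    ``"merged"`` frame instead uses the full duocentric node set with
    resolved ties plus the parent's implicit ties to every alter the parent
    named; this mode goes beyond the per-respondent convention and is
    labeled accordingly in outputs.
    """
    if duo.parent_node is None:
        return None
    if frame == "ya":
        ids, reports = _ya_frame(duo)
        n = len(ids)
        if n < 2:
            return None
        others = [u for u in ids if u != duo.parent_node]
        tied = sum(
            1
            for u in others
            if reports.get((min(u, duo.parent_node), max(u, duo.parent_node)), 0) > 0
        )
        return tied / (n - 1)
    if frame == "merged":
        ids = [n_.unified_id for n_ in duo.nodes]
        n = len(ids)
        if n < 2:
            return None
        named_by_parent = {
            n_.unified_id for n_ in duo.nodes if n_.pa_rank is not None
        }
        tied = 0
        for u in ids:
            if u == duo.parent_node:
                continue
            if duo.tied(u, duo.parent_node) or u in named_by_parent:
                tied += 1
        return tied / (n - 1)
    raise ValueError(f"unknown frame {frame!r}")


@dataclass(frozen=True)
class DuoCharacteristics:
    parent_only_alters: bool
    youth_only_alters: bool
    parent_network_is_subset: bool
    overlap_alters_high_tie: bool
    parent_high_centrality: bool
    degenerate: bool = False  # e.g. empty parent roster


def characteristics(
    duo: DuoNetwork, threshold: float = HIGH_TIE_THRESHOLD
) -> DuoCharacteristics:
    """The five yes/no pair-level characteristics.

    High-tie codes use >= threshold (default 0.75).  The overlap code
    requires *every* overlap alter to be tied to at least the threshold
    share of the other merged alters (one code per pair).  The subset code
    is yes when the parent named no unique alters and every parent alter
    overlaps.
    """
    overlap, unique = overlap_and_unique(duo)
    pa_roster = overlap + unique["pa"]
    subset = unique["pa"] == 0 and overlap == pa_roster

    n_merged = len(duo.nodes)
    overlap_ids = [n.unified_id for n in duo.nodes if n.provenance == "both"]
    if overlap_ids and n_merged > 1:
        high = True
        for u in overlap_ids:
            tied = sum(
                1 for v in (n.unified_id for n in duo.nodes) if v != u and duo.tied(u, v)
            )
            if tied / (n_merged - 1) < threshold:
                high = False
                break
    else:
        high = False

    pc = parent_centrality(duo)
    return DuoCharacteristics(
        parent_only_alters=unique["pa"] > 0,
        youth_only_alters=unique["ya"] > 0,
        parent_network_is_subset=subset,
        overlap_alters_high_tie=high,
        parent_high_centrality=(pc is not None and pc >= threshold),
        degenerate=(pa_roster == 0),
    )


def social_capital_config(
    duo: DuoNetwork, ya: EgoSurvey, pa: EgoSurvey
) -> dict:
    """Role/support percentages per respondent plus ADD counts.

    ``add_counts[k]`` is the number of parent-unique (pa_only) alters
    carrying role or support ``k`` — resources reachable only through the
    parent's network.  When the parent network is a subset of the young
    adult's, every ADD count is 0.
    """
    ya_net = from_survey(ya)
    pa_net = from_survey(pa)
    pa_only = [n for n in duo.nodes if n.provenance == "pa_only"]
    add_counts: dict[str, int] = {}
    for r in ROLE_CLASSES:
        add_counts[r] = sum(1 for n in pa_only if n.role_class == r)
    for s in SUPPORT_TYPES:
        add_counts[s] = sum(1 for n in pa_only if s in n.supports_pa)
    return {
        "ya": {
            "role_pct": ego_measures.role_composition(ya_net),
            "support_pct": ego_measures.support_prevalence(ya_net),
            "family_friendship_pct": ego_measures.family_friendship_pct(ya_net),
        },
        "pa": {
            "role_pct": ego_measures.role_composition(pa_net),
            "support_pct": ego_measures.support_prevalence(pa_net),
            "family_friendship_pct": ego_measures.family_friendship_pct(pa_net),
        },
        "add_counts": add_counts,
    }


def duo_measure_set(duo: DuoNetwork, ya: EgoSurvey, pa: EgoSurvey) -> dict:
    """The six overall measures for one matched pair, per-respondent where
    the convention reports them that way (size, density, disconnected)."""
    ya_net: EgoNetwork = from_survey(ya)
    pa_net: EgoNetwork = from_survey(pa)
    overlap, unique = overlap_and_unique(duo)
    return {
        "pair_id": duo.pair_id,
        "network_size": {
            "ya": ego_measures.network_size(ya_net),
            "pa": ego_measures.network_size(pa_net),
        },
        "network_density": {
            "ya": ego_measures.network_density(ya_net),
            "pa": ego_measures.network_density(pa_net),
        },
        "overlap_count": overlap,
        "unique_counts": unique,
        "disconnected_counts": {
            "ya": ego_measures.disconnected_count(ya_net),
            "pa": ego_measures.disconnected_count(pa_net),
        },
        "parent_centrality": parent_centrality(duo),
        "n_discrepancies": len(duo.discrepancies),
    }
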