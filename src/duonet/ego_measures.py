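"""Egocentric network measures.

All measures follow the alter-only convention: the ego is excluded, because
the name generator ties the ego to every named alter by construction.
Density is therefore ties among alters over C(n, 2) possible alter pairs;
it is undefined (NA) for networks with fewer than two alters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .types import ROLE_CLASSES, SUPPORT_TYPES, AlterRecord, EgoSurvey

__all__ = [
    "EgoNetwork",
    "from_survey",
    "network_size",
    "network_density",
    "role_composition",
    "support_prevalence",
    "family_friendship_pct",
    "disconnected_count",
    "measure_set",
    "cohort_summary",
]


@dataclass(frozen=True)
class EgoNetwork:
    """Alter-only undirected graph for one ego.

    Nodes are alter ranks; ``edges`` holds binarized ties (frequency >= 1)
    with their ordinal weights.
    """

    ego_id: str
    alters: tuple[AlterRecord, ...]
    edges: frozenset[tuple[int, int]]
    weights: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = {a.rank for a in self.alters}
        for a, b in self.edges:
            if a == b or a not in ranks or b not in ranks:
                raise ValueError(f"edge ({a},{b}) not between listed alters")

    def degree(self, rank: int) -> int:
        return sum(1 for e in self.edges if rank in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.alters:
            g.add_node(
                a.rank,
                label=a.label,
                role_class=a.role_class,
                supports=",".join(sorted(a.supports)),
            )
        for (u, v) in sorted(self.edges):
            g.add_edge(u, v, weight=self.weights.get((u, v), 1))
        return g


def from_survey(survey: EgoSurvey) -> EgoNetwork:
    """Binarize a validated survey's tie reports into an alter network."""
    edges = set()
    weights = {}
    for t in survey.tie_reports:
        if t.interacts:
            edges.add(t.pair)
            weights[t.pair] = t.frequency
    return EgoNetwork(
        ego_id=survey.ego_id,
        alters=tuple(survey.alters),
        edges=frozenset(edges),
        weights=weights,
    )


def network_size(net: EgoNetwork) -> int:
    """Number of alters named (ego not counted)."""
    return len(net.alters)


def network_density(net: EgoNetwork) -> Optional[float]:
    """Ties among alters / C(n, 2); None (NA) when n < 2."""
    n = network_size(net)
    if n < 2:
        return None
    return len(net.edges) / (n * (n - 1) / 2)


def role_composition(net: EgoNetwork) -> dict[str, Optional[float]]:
    """Percent of alters in each role class; NA map for an empty roster."""
    n = network_size(net)
    if n == 0:
        return {r: None for r in ROLE_CLASSES}
    return {
        r: 100.0 * sum(1 for a in net.alters if a.role_class == r) / n
        for r in ROLE_CLASSES
    }


def support_prevalence(net: EgoNetwork) -> dict[str, Optional[float]]:
    """Percent of alters providing each support type; NA map when empty.

    Support is the number of alters providing a given support divided by
    the number of alters named, as a percentage.
    """
    n = network_size(net)
    if n == 0:
        return {s: None for s in SUPPORT_TYPES}
    return {
        s: 100.0 * sum(1 for a in net.alters if a.provides(s)) / n
        for s in SUPPORT_TYPES
    }


def family_friendship_pct(net: EgoNetwork) -> Optional[float]:
    """Percent of *family* alters who provide friendship; NA with no family.

    The denominator is family alters only.  Networks without family yield
    None, coerced to 0 in cohort means (see :func:`cohort_summary`).
    """
    fam = [a for a in net.alters if a.role_class == "family"]
    if not fam:
        return None
    return 100.0 * sum(1 for a in fam if a.provides("friendship")) / len(fam)


def disconnected_count(net: EgoNetwork) -> int:
    """Number of alters with no ties to any other alter (ego tie ignored)."""
    return sum(1 for a in net.alters if net.degree(a.rank) == 0)


def measure_set(net: EgoNetwork) -> dict:
    """All per-ego measures as a flat dict (raw, unrounded values)."""
    out: dict = {
        "ego_id": net.ego_id,
        "network_size": network_size(net),
        "density": network_density(net),
        "disconnected_count": disconnected_count(net),
        "family_friendship_pct": family_friendship_pct(net),
    }
    for r, v in role_composition(net).items():
        out[f"pct_{r}"] = v
    for s, v in support_prevalence(net).items():
        out[f"pct_support_{s}"] = v
    return out


def cohort_summary(nets: Sequence[EgoNetwork]) -> dict:
    """Unweighted cohort means of each per-ego measure, plus median size.

    NA densities (rosters of 0 or 1 alters) are dropped from the density
    mean; NA family-friendship values (no family alters) are coerced to 0,
    matching the convention of reporting "no family friendship" as 0%.
    """
    if not nets:
        raise ValueError("cohort_summary requires a nonempty list of networks")
    rows = pd.DataFrame([measure_set(n) for n in nets])
    out = {"n_egos": len(nets)}
    out["mean_network_size"] = float(rows["network_size"].mean())
    out["median_network_size"] = float(rows["network_size"].median())
    out["mean_density"] = (
        float(rows["density"].dropna().mean())
        if rows["density"].notna().any()
        else math.nan
    )
    out["mean_disconnected"] = float(rows["disconnected_count"].mean())
    out["mean_family_friendship_pct"] = float(
        rows["family_friendship_pct"].astype(float).fillna(0.0).mean()
    )
    for r in ROLE_CLASSES:
        out[f"mean_pct_{r}"] = float(rows[f"pct_{r}"].dropna().mean())
    for s in SUPPORT_TYPES:
        out[f"mean_pct_support_{s}"] = float(rows[f"pct_support_{s}"].dropna().mean())
    return out


def measures_frame(nets: Iterable[EgoNetwork]) -> pd.DataFrame:
    """One row of measures per ego (for CSV export)."""
    return pd.DataFrame([measure_set(n) for n in nets])
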