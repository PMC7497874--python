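"""Read, validate and write name-generator survey exports.

The on-disk dialect is a flat wide CSV (one row per respondent) emulating a
Qualtrics-style export, plus an equivalent nested JSON form.  Columns:

``ego_id, reporter_kind, roster_cap,`` ego attribute columns
(``gender, age, dating, employed, college, independent_living``), then for
each roster slot ``N`` in 1..cap: ``alterN_name, alterN_role,
alterN_role_class, alterN_support_<type>`` (six 0/1 flags), and for each
unordered slot pair ``tieN_M`` holding the ordinal interaction frequency
(blank when either slot is empty).
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .types import (
    DEFAULT_ROSTER_CAP,
    ROLE_CLASSES,
    SUPPORT_TYPES,
    AlterRecord,
    EgoSurvey,
    ReporterKind,
    TieReport,
    ValidationError,
)

__all__ = [
    "DEFAULT_ROLE_MAP",
    "classify_role",
    "read_surveys",
    "write_surveys",
    "to_edge_list",
    "edge_list_frame",
    "ParseError",
]

logger = logging.getLogger(__name__)

EGO_ATTRIBUTE_COLUMNS = (
    "gender",
    "age",
    "dating",
    "employed",
    "college",
    "independent_living",
)

#: Role vocabulary observed in this kind of survey, mapped to the three classes.
DEFAULT_ROLE_MAP: dict[str, str] = {
    # family / kin
    "mother": "family",
    "mom": "family",
    "father": "family",
    "dad": "family",
    "parent": "family",
    "stepmother": "family",
    "stepfather": "family",
    "brother": "family",
    "sister": "family",
    "sibling": "family",
    "grandmother": "family",
    "grandfather": "family",
    "grandparent": "family",
    "aunt": "family",
    "uncle": "family",
    "cousin": "family",
    "spouse": "family",
    "wife": "family",
    "husband": "family",
    "guardian": "family",
    # community
    "friend": "community",
    "best friend": "community",
    "neighbor": "community",
    "neighbour": "community",
    "roommate": "community",
    "coworker": "community",
    "co-worker": "community",
    "colleague": "community",
    "classmate": "community",
    "partner": "community",
    "boyfriend": "community",
    "girlfriend": "community",
    "mentor": "community",
    "coach": "community",
    # professional service providers
    "therapist": "professional",
    "counselor": "professional",
    "psychologist": "professional",
    "psychiatrist": "professional",
    "doctor": "professional",
    "nurse": "professional",
    "teacher": "professional",
    "professor": "professional",
    "job coach": "professional",
    "case manager": "professional",
    "social worker": "professional",
    "support worker": "professional",
    "aide": "professional",
}


class ParseError(ValueError):
    """A file does not conform to the documented survey dialect."""


def classify_role(
    role_raw: str,
    mapping: Optional[dict[str, str]] = None,
    unmapped_default: str = "community",
) -> str:
    """Map a free-text role string onto {family, community, professional}.

    Unmapped strings fall back to ``unmapped_default`` (community, because
    the residual roles in this survey type — friend, neighbor — are
    community) with a logged warning.
    """
    if not role_raw or not role_raw.strip():
        raise ValidationError("empty role string")
    mapping = DEFAULT_ROLE_MAP if mapping is None else mapping
    key = role_raw.strip().lower()
    if key in ROLE_CLASSES:
        return key
    if key in mapping:
        return mapping[key]
    logger.warning("unmapped role %r routed to %r", role_raw, unmapped_default)
    return unmapped_default


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _pair_columns(cap: int) -> list[tuple[int, int]]:
    return [(a, b) for a in range(1, cap + 1) for b in range(a + 1, cap + 1)]


def _header(cap: int) -> list[str]:
    cols = ["ego_id", "reporter_kind", "roster_cap", *EGO_ATTRIBUTE_COLUMNS]
    for n in range(1, cap + 1):
        cols += [f"alter{n}_name", f"alter{n}_role", f"alter{n}_role_class"]
        cols += [f"alter{n}_support_{s}" for s in SUPPORT_TYPES]
    cols += [f"tie{a}_{b}" for a, b in _pair_columns(cap)]
    return cols


def _survey_to_row(survey: EgoSurvey, cap: int) -> dict[str, str]:
    row = {
        "ego_id": survey.ego_id,
        "reporter_kind": survey.reporter_kind.value,
        "roster_cap": str(survey.roster_cap),
    }
    for col in EGO_ATTRIBUTE_COLUMNS:
        val = survey.ego_attributes.get(col, "")
        row[col] = "" if val is None else str(val)
    by_rank = {a.rank: a for a in survey.alters}
    for n in range(1, cap + 1):
        a = by_rank.get(n)
        row[f"alter{n}_name"] = a.label if a else ""
        row[f"alter{n}_role"] = a.role_raw if a else ""
        row[f"alter{n}_role_class"] = a.role_class if a else ""
        for s in SUPPORT_TYPES:
            row[f"alter{n}_support_{s}"] = ("1" if a.provides(s) else "0") if a else ""
    freq = {t.pair: t.frequency for t in survey.tie_reports}
    for a, b in _pair_columns(cap):
        row[f"tie{a}_{b}"] = str(freq[(a, b)]) if (a, b) in freq else ""
    return row


def _row_to_survey(
    row: dict[str, str], cap: int, role_map: Optional[dict[str, str]]
) -> EgoSurvey:
    ego_id = (row.get("ego_id") or "").strip()
    if not ego_id:
        raise ParseError("row with empty ego_id")
    alters = []
    for n in range(1, cap + 1):
        name = (row.get(f"alter{n}_name") or "").strip()
        if not name:
            continue
        role_raw = (row.get(f"alter{n}_role") or "").strip()
        role_class = (row.get(f"alter{n}_role_class") or "").strip()
        if not role_class:
            role_class = classify_role(role_raw, role_map)
        supports = frozenset(
            s
            for s in SUPPORT_TYPES
            if (row.get(f"alter{n}_support_{s}") or "").strip() in ("1", "true", "True")
        )
        alters.append(
            AlterRecord(
                label=name,
                rank=n,
                role_raw=role_raw,
                role_class=role_class,
                supports=supports,
            )
        )
    ties = []
    for a, b in _pair_columns(cap):
        cell = (row.get(f"tie{a}_{b}") or "").strip()
        if cell:
            ties.append(TieReport(a, b, int(cell)))
    attrs = {}
    for col in EGO_ATTRIBUTE_COLUMNS:
        cell = (row.get(col) or "").strip()
        if cell:
            attrs[col] = cell
    return EgoSurvey(
        ego_id=ego_id,
        reporter_kind=ReporterKind(row.get("reporter_kind", "young_adult").strip()),
        alters=tuple(alters),
        tie_reports=tuple(ties),
        ego_attributes=attrs,
        roster_cap=int(row.get("roster_cap", cap) or cap),
    ).validate()


def _survey_to_json_obj(survey: EgoSurvey) -> dict:
    return {
        "ego_id": survey.ego_id,
        "reporter_kind": survey.reporter_kind.value,
        "roster_cap": survey.roster_cap,
        "ego_attributes": dict(survey.ego_attributes),
        "alters": [
            {
                "label": a.label,
                "rank": a.rank,
                "role_raw": a.role_raw,
                "role_class": a.role_class,
                "supports": sorted(a.supports),
            }
            for a in survey.alters
        ],
        "tie_reports": [
            {"rank_a": t.rank_a, "rank_b": t.rank_b, "frequency": t.frequency}
            for t in survey.tie_reports
        ],
    }


def _json_obj_to_survey(obj: dict) -> EgoSurvey:
    try:
        alters = tuple(
            AlterRecord(
                label=a["label"],
                rank=a["rank"],
                role_raw=a.get("role_raw", ""),
                role_class=a["role_class"],
                supports=frozenset(a.get("supports", ())),
            )
            for a in obj["alters"]
        )
        ties = tuple(
            TieReport(t["rank_a"], t["rank_b"], t["frequency"])
            for t in obj["tie_reports"]
        )
        return EgoSurvey(
            ego_id=obj["ego_id"],
            reporter_kind=ReporterKind(obj["reporter_kind"]),
            alters=alters,
            tie_reports=ties,
            ego_attributes=dict(obj.get("ego_attributes", {})),
            roster_cap=obj.get("roster_cap", DEFAULT_ROSTER_CAP),
        ).validate()
    except KeyError as e:
        raise ParseError(f"missing JSON field {e}") from e


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def read_surveys(
    path: Union[str, Path],
    fmt: Optional[str] = None,
    role_map: Optional[dict[str, str]] = None,
) -> list[EgoSurvey]:
    """Read a survey export (CSV or JSON dialect) into validated surveys.

    Format is inferred from the suffix when ``fmt`` is None.  Raises
    :class:`ParseError` for malformed headers and
    :class:`~duonet.types.ValidationError` for rows violating survey
    invariants (duplicate ranks, missing tie reports, ...).
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise ParseError("JSON survey file must contain a list of surveys")
        return [_json_obj_to_survey(obj) for obj in data]
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for required in ("ego_id", "reporter_kind"):
            if required not in header:
                raise ParseError(f"malformed header: missing column {required!r}")
        cap = 0
        n = 1
        while f"alter{n}_name" in header:
            cap = n
            n += 1
        if cap == 0:
            raise ParseError("malformed header: no alterN_name columns found")
        return [_row_to_survey(row, cap, role_map) for row in reader]


def write_surveys(
    surveys: Sequence[EgoSurvey],
    path: Union[str, Path],
    fmt: Optional[str] = None,
) -> Path:
    """Write surveys to the CSV or JSON dialect; returns the path written."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        payload = [_survey_to_json_obj(s) for s in surveys]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    cap = max([s.roster_cap for s in surveys], default=DEFAULT_ROSTER_CAP)
    cols = _header(cap)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, lineterminator="\n")
        writer.writeheader()
        for s in surveys:
            writer.writerow(_survey_to_row(s, cap))
    return path


def to_edge_list(survey: EgoSurvey) -> list[tuple[str, int, int, int]]:
    """Reshape one survey into undirected edge rows.

    One row ``(ego_id, rank_a, rank_b, weight)`` per tie report with
    ``interacts`` true, in canonical (rank_a < rank_b) order.  Isolated
    alters and non-interacting pairs produce no rows.
    """
    return [
        (survey.ego_id, t.rank_a, t.rank_b, t.frequency)
        for t in survey.tie_reports
        if t.interacts
    ]


def edge_list_frame(surveys: Iterable[EgoSurvey]) -> pd.DataFrame:
    """Stack per-survey edge lists into one DataFrame (ego_id, node_a, node_b, weight)."""
    rows = [r for s in surveys for r in to_edge_list(s)]
    return pd.DataFrame(rows, columns=["ego_id", "node_a", "node_b", "weight"])
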