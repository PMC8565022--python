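"""Data model and I/O for health states, respondent profiles, and elicited values.

The catalog holds the health states being valued, each identified by an
integer id, a human-readable label, and one or more SNOMED CT ``code|term|``
tokens (post-coordinated states carry several tokens). Elicited utility
coefficients are stored in a flat CSV repository, one row per
(respondent, state, method) triple.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

METHODS = ("SG", "RS", "TTO")
SEXES = ("male", "female")
EDUCATION_LEVELS = ("secondary school", "high school", "university")
FAMILY_SITUATIONS = (
    "has_dependant_child",
    "has_adult_non_self-sufficient_dependant",
    "none_of_the_above",
)

REPOSITORY_HEADER = ["respondent_id", "state_id", "method", "value", "n_steps", "refused_gamble"]

# one SNOMED token: all-digit concept id, '|', non-empty term, '|'
_SNOMED_TOKEN = re.compile(r"\d+\|[^|]+\|")


class CatalogError(ValueError):
    """Malformed or inconsistent health-state catalog."""


class RepositoryError(ValueError):
    """Malformed or invalid utility-record repository."""


def validate_snomed_expression(expr: str) -> bool:
    """True iff *expr* is a ``|``-delimited sequence of one or more code|term pairs.

    Concept codes must be all digits; terms non-empty and free of ``|``.
    Post-coordinated expressions simply concatenate several pairs, e.g.
    ``"25173007|Recurrent tumor|255470001|Local|"``.
    """
    if not isinstance(expr, str) or not expr:
        return False
    return re.fullmatch(rf"(?:{_SNOMED_TOKEN.pattern})+", expr) is not None


@dataclass
class HealthState:
    """One health state to be valued, with its SNOMED CT coding."""

    state_id: int
    label: str
    snomed_exprs: list[str]
    scenario_ref: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.state_id, int) or isinstance(self.state_id, bool) or self.state_id < 1:
            raise CatalogError(f"state_id must be a positive integer, got {self.state_id!r}")
        if not self.label:
            raise CatalogError(f"state {self.state_id}: empty label")
        if not self.snomed_exprs:
            raise CatalogError(f"state {self.state_id}: snomed_exprs must be non-empty")
        for tok in self.snomed_exprs:
            if not validate_snomed_expression(tok):
                raise CatalogError(f"state {self.state_id}: malformed SNOMED token {tok!r}")

    @property
    def is_post_coordinated(self) -> bool:
        return len(self.snomed_exprs) > 1


@dataclass
class RespondentProfile:
    """Basic profile of an interviewed (or simulated) individual."""

    respondent_id: str
    age: float
    sex: str
    education: str
    family_situation: str
    profession: str = "unspecified"
    marital_status: str = "unspecified"
    is_patient: bool = False
    country: str = "Switzerland"

    def __post_init__(self) -> None:
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age) and self.age > 0):
            raise ValueError(f"respondent {self.respondent_id}: age must be finite and > 0")
        if self.sex not in SEXES:
            raise ValueError(f"respondent {self.respondent_id}: sex must be one of {SEXES}")
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(
                f"respondent {self.respondent_id}: education must be one of {EDUCATION_LEVELS}"
            )
        if self.family_situation not in FAMILY_SITUATIONS:
            raise ValueError(
                f"respondent {self.respondent_id}: family_situation must be one of {FAMILY_SITUATIONS}"
            )


@dataclass
class UCRecord:
    """One elicited utility coefficient.

    ``n_steps`` counts the titration questions asked (0 for the rating
    scale). A refused gamble is recorded as an SG value of exactly 1: a
    respondent unwilling to accept any risk of death values the state as
    perfect health.
    """

    respondent_id: str
    state_id: int
    method: str
    value: float
    n_steps: int = 0
    refused_gamble: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise RepositoryError(f"method must be one of {METHODS}, got {self.method!r}")
        if not (isinstance(self.value, (int, float)) and 0.0 <= self.value <= 1.0):
            raise RepositoryError(
                f"utility value must lie in [0, 1], got {self.value!r} "
                f"(respondent {self.respondent_id}, state {self.state_id})"
            )
        if not (isinstance(self.n_steps, int) and self.n_steps >= 0):
            raise RepositoryError(f"n_steps must be a non-negative integer, got {self.n_steps!r}")
        if self.refused_gamble and (self.method != "SG" or self.value != 1.0):
            raise RepositoryError(
                "refused_gamble requires method='SG' and value=1.0 "
                f"(respondent {self.respondent_id}, state {self.state_id})"
            )


def load_state_catalog(path: str | Path) -> list[HealthState]:
    """Load a JSON health-state catalog and validate it.

    An empty file yields an empty catalog; duplicate state ids are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        return []
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(raw, list):
        raise CatalogError(f"{path}: expected a JSON list of state records")
    states: list[HealthState] = []
    seen: set[int] = set()
    for i, rec in enumerate(raw, start=1):
        try:
            state = HealthState(
                state_id=rec["state_id"],
                label=rec["label"],
                snomed_exprs=list(rec["snomed_exprs"]),
                scenario_ref=rec.get("scenario_ref"),
            )
        except (KeyError, TypeError) as exc:
            raise CatalogError(f"{path}: malformed state record #{i}: {exc}") from exc
        if state.state_id in seen:
            raise CatalogError(f"{path}: duplicate state_id {state.state_id} (record #{i})")
        seen.add(state.state_id)
        states.append(state)
    return states


def write_state_catalog(states: Sequence[HealthState], path: str | Path) -> None:
    payload = [
        {
            "state_id": s.state_id,
            "label": s.label,
            "snomed_exprs": s.snomed_exprs,
            "scenario_ref": s.scenario_ref,
        }
        for s in states
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_uc_repository(path: str | Path) -> list[UCRecord]:
    """Read a CSV repository of elicited utility coefficients."""
    path = Path(path)
    records: list[UCRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != REPOSITORY_HEADER:
            raise RepositoryError(
                f"{path}: unexpected header {reader.fieldnames!r}; expected {REPOSITORY_HEADER!r}"
            )
        for row in reader:
            lineno = reader.line_num
            try:
                records.append(
                    UCRecord(
                        respondent_id=row["respondent_id"],
                        state_id=int(row["state_id"]),
                        method=row["method"],
                        value=float(row["value"]),
                        n_steps=int(row["n_steps"]),
                        refused_gamble=row["refused_gamble"].lower() in ("true", "1"),
                    )
                )
            except (RepositoryError, ValueError, TypeError) as exc:
                raise RepositoryError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_uc_repository(records: Iterable[UCRecord], path: str | Path) -> None:
    """Write records as CSV; ``read_uc_repository`` round-trips bit-exactly.

    Values are serialised with ``repr`` so the stored decimal expansion
    re-parses to the identical float.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPOSITORY_HEADER)
        for rec in records:
            if not isinstance(rec, UCRecord):
                rec = UCRecord(**rec)  # re-validate plain mappings
            writer.writerow(
                [
                    rec.respondent_id,
                    rec.state_id,
                    rec.method,
                    repr(float(rec.value)),
                    rec.n_steps,
                    str(rec.refused_gamble).lower(),
                ]
            )


def read_profiles(path: str | Path) -> list[RespondentProfile]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return [RespondentProfile(**rec) for rec in raw]


def write_profiles(profiles: Sequence[RespondentProfile], path: str | Path) -> None:
    payload = [vars(p) for p in profiles]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
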