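"""Cohort CSV reading/writing, run reports, and predicate parsing."""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Mapping, Sequence

from .bayes import ConditionalEstimate
from .cohort import CohortTable, PatientRecord
from .errors import SchemaError
from .network_model import DIET_CATEGORIES, MARKERS

__all__ = [
    "COHORT_COLUMNS",
    "write_cohort",
    "read_cohort",
    "parse_predicate",
    "RunReport",
]

#: Exact CSV header: id plus the 17 published cohort columns.
COHORT_COLUMNS: tuple[str, ...] = (
    ("id",) + MARKERS + ("diet", "age", "fusion", "fission", "AD")
)

# the 'none' diet renders as the literal token "0"
_DIET_TOKENS = {d: d for d in DIET_CATEGORIES} | {"none": "0"}
_TOKEN_DIETS = {v: k for k, v in _DIET_TOKENS.items()}


def format_probability(p: float) -> str:
    """Probability at 3-decimal precision with trailing zeros trimmed."""
    text = f"{p:.3f}".rstrip("0").rstrip(".")
    return text or "0"


def _record_row(record: PatientRecord) -> list[str]:
    row = [str(record.id)]
    row += [str(getattr(record, m)) for m in MARKERS]
    row += [
        _DIET_TOKENS[record.diet],
        str(record.age),
        str(record.fusion),
        str(record.fission),
        format_probability(record.ad_probability),
    ]
    return row


def write_cohort(cohort: CohortTable, path: str) -> None:
    """Write a cohort as CSV with the exact 18-column header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_COLUMNS)
        for record in cohort:
            writer.writerow(_record_row(record))


def _parse_flag(value: str, row: int, column: str) -> int:
    if value not in ("0", "1"):
        raise SchemaError(f"row {row}, column {column!r}: {value!r} is not a binary flag")
    return int(value)


def read_cohort(path: str) -> CohortTable:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    SchemaError
        Missing/extra column, non-binary flag, out-of-range age or
        probability, non-sequential ids; messages name row and column.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: missing header") from None
        if tuple(header) != COHORT_COLUMNS:
            raise SchemaError(
                f"bad header {header!r}; expected {list(COHORT_COLUMNS)}"
            )
        records = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(COHORT_COLUMNS):
                raise SchemaError(f"row {i}: {len(row)} fields, expected {len(COHORT_COLUMNS)}")
            cells = dict(zip(COHORT_COLUMNS, row))
            try:
                pid = int(cells["id"])
            except ValueError:
                raise SchemaError(f"row {i}, column 'id': {cells['id']!r} is not an integer") from None
            flags = {m: _parse_flag(cells[m], i, m) for m in MARKERS}
            diet = _TOKEN_DIETS.get(cells["diet"])
            if diet is None:
                raise SchemaError(f"row {i}, column 'diet': unknown token {cells['diet']!r}")
            try:
                age = int(cells["age"])
            except ValueError:
                raise SchemaError(f"row {i}, column 'age': {cells['age']!r} is not an integer") from None
            if not 30 <= age <= 95:
                raise SchemaError(f"row {i}, column 'age': {age} outside [30, 95]")
            try:
                ad = float(cells["AD"])
            except ValueError:
                raise SchemaError(f"row {i}, column 'AD': {cells['AD']!r} is not a number") from None
            if not 0.0 <= ad <= 1.0 or math.isnan(ad):
                raise SchemaError(f"row {i}, column 'AD': {ad} outside [0, 1]")
            records.append(
                PatientRecord(
                    id=pid,
                    diet=diet,
                    age=age,
                    fusion=_parse_flag(cells["fusion"], i, "fusion"),
                    fission=_parse_flag(cells["fission"], i, "fission"),
                    ad_probability=ad,
                    **flags,
                )
            )
    try:
        return CohortTable(records=tuple(records), n=len(records), seed=None)
    except Exception as exc:
        raise SchemaError(str(exc)) from None


_OPS: dict[str, Callable[[float, float], bool]] = {
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
    "=": lambda a, b: a == b,
}

_FIELD_ALIASES = {"AD": "ad_probability", "ad": "ad_probability"}


def parse_predicate(expr: str) -> Callable[[PatientRecord], bool]:
    """Compile a comma-separated clause list into a record predicate.

    Each clause is ``field OP value`` with OP one of ``= >= <= > <``; clauses
    are conjoined.  ``diet`` compares category tokens (``0`` means no diet);
    ``AD`` refers to the progression probability.  Example:
    ``"diet=HL,drp1=1,AD>=0.5"``.
    """
    clauses = []
    for raw in expr.split(","):
        clause = raw.strip()
        if not clause:
            continue
        for op in (">=", "<=", ">", "<", "="):
            if op in clause:
                name, _, value = clause.partition(op)
                break
        else:
            raise SchemaError(f"cannot parse predicate clause {clause!r}")
        name = name.strip()
        value = value.strip()
        attr = _FIELD_ALIASES.get(name, name)
        if attr not in PatientRecord.__dataclass_fields__:
            raise SchemaError(f"unknown field {name!r} in predicate")
        if attr == "diet":
            if op != "=":
                raise SchemaError("diet only supports '=' comparison")
            diet = _TOKEN_DIETS.get(value, value)
            clauses.append(lambda r, d=diet: r.diet == d)
        else:
            try:
                target = float(value)
            except ValueError:
                raise SchemaError(f"non-numeric value {value!r} for field {name!r}") from None
            clauses.append(
                lambda r, a=attr, o=_OPS[op], t=target: o(float(getattr(r, a)), t)
            )
    if not clauses:
        raise SchemaError("empty predicate")
    return lambda record: all(c(record) for c in clauses)


@dataclass(frozen=True)
class RunReport:
    """Summary of one simulation run; serializes to JSON and round-trips."""

    n: int
    seed: int | None
    config_digest: str
    marker_frequencies: Mapping[str, float]
    estimates: Sequence[Mapping[str, float]] = field(default_factory=tuple)
    timestamp: str = ""

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortTable,
        estimates: Sequence[ConditionalEstimate] = (),
    ) -> "RunReport":
        return cls(
            n=cohort.n,
            seed=cohort.seed,
            config_digest=cohort.config_digest,
            marker_frequencies=cohort.marker_frequencies(),
            estimates=tuple(
                {"estimate": e.estimate, "n_evidence": e.n_evidence, "mc_error": e.mc_error}
                for e in estimates
            ),
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "seed": self.seed,
                "config_digest": self.config_digest,
                "marker_frequencies": dict(self.marker_frequencies),
                "estimates": [dict(e) for e in self.estimates],
                "timestamp": self.timestamp,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        doc = json.loads(text)
        return cls(
            n=doc["n"],
            seed=doc["seed"],
            config_digest=doc["config_digest"],
            marker_frequencies=doc["marker_frequencies"],
            estimates=tuple(doc["estimates"]),
            timestamp=doc["timestamp"],
        )
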