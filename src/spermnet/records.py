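"""Curated molecular-interaction tables.

A curated signaling database is a flat table with one interaction per row
and seven fields: source molecule, nature of the interaction (activation,
inhibition, ...), target molecule, biological function, species, reference
and notes.  Only the first three are mandatory.  Nodes may be molecules
("ATP", "[Ca2+]i") or complex cellular events ("membrane fusion"), so labels
are trimmed of surrounding whitespace but otherwise preserved verbatim —
case, brackets and internal punctuation all distinguish biological species.
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "ACTIVATION",
    "INHIBITION",
    "InteractionRecord",
    "SchemaError",
    "RowError",
    "SignVocabulary",
    "read_interaction_table",
    "write_interaction_table",
    "validate_records",
    "ValidationReport",
    "filter_records",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: Default case-insensitive synonyms for the two sign categories.
DEFAULT_ACTIVATION_SYNONYMS = ("activation", "activates", "promotes", "+")
DEFAULT_INHIBITION_SYNONYMS = ("inhibition", "inhibits", "represses", "-", "−")

#: Accepted header spellings for the three mandatory columns.
DEFAULT_HEADER_SYNONYMS: Mapping[str, tuple[str, ...]] = {
    "source": ("source", "source molecule", "src", "from"),
    "interaction": ("interaction", "sign", "effect", "relation"),
    "target": ("target", "target molecule", "tgt", "to"),
}

OPTIONAL_FIELDS = ("biological_function", "species", "reference", "notes")


class SchemaError(ValueError):
    """A mandatory column is missing from the table header."""


class RowError(ValueError):
    """A data row violates the schema (e.g. empty mandatory cell)."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class SignVocabulary:
    """Maps free-text interaction descriptions onto sign categories.

    Anything not recognised as activation or inhibition is preserved
    verbatim and treated as an "other" sign.
    """

    activation: tuple[str, ...] = DEFAULT_ACTIVATION_SYNONYMS
    inhibition: tuple[str, ...] = DEFAULT_INHIBITION_SYNONYMS

    def canonical(self, text: str) -> str:
        low = text.strip().lower()
        if low in (s.lower() for s in self.activation):
            return ACTIVATION
        if low in (s.lower() for s in self.inhibition):
            return INHIBITION
        return text.strip()


@dataclass(frozen=True)
class InteractionRecord:
    """One row of a curated interaction table."""

    source: str
    interaction: str
    target: str
    biological_function: str = ""
    species: str = ""
    reference: str = ""
    notes: str = ""

    def __post_init__(self):
        if not self.source.strip():
            raise ValueError("source must be non-empty")
        if not self.target.strip():
            raise ValueError("target must be non-empty")
        # normalise: trim surrounding whitespace only
        object.__setattr__(self, "source", self.source.strip())
        object.__setattr__(self, "target", self.target.strip())
        object.__setattr__(self, "interaction", self.interaction.strip())

    @property
    def triple(self) -> tuple[str, str, str]:
        """(source, interaction, target) — identity of the signed edge."""
        return (self.source, self.interaction, self.target)


def _resolve_header(
    header: Sequence[str], synonyms: Mapping[str, tuple[str, ...]]
) -> dict[str, int]:
    """Map canonical column names to indices, matching case-insensitively."""
    cleaned = [h.strip().lower() for h in header]
    mapping: dict[str, int] = {}
    for canon, names in synonyms.items():
        for i, h in enumerate(cleaned):
            if h in (n.lower() for n in names):
                mapping[canon] = i
                break
    for canon in ("source", "interaction", "target"):
        if canon not in mapping:
            raise SchemaError(f"mandatory column {canon!r} not found in header {list(header)!r}")
    # optional annotation columns are matched by their own names
    for i, h in enumerate(cleaned):
        for opt in OPTIONAL_FIELDS:
            if h == opt or h == opt.replace("_", " "):
                mapping.setdefault(opt, i)
    return mapping


def read_interaction_table(
    path: str | Path | io.TextIOBase,
    *,
    delimiter: str = ",",
    header: bool = True,
    header_synonyms: Mapping[str, tuple[str, ...]] = DEFAULT_HEADER_SYNONYMS,
    sign_vocabulary: SignVocabulary | None = None,
) -> list[InteractionRecord]:
    """Read a delimited interaction table into records, preserving row order.

    Without a header the first three columns are taken as source,
    interaction, target and any further columns as the optional annotations
    in schema order.  Interaction text is mapped onto the sign vocabulary;
    unrecognised signs are preserved verbatim.
    """
    vocab = sign_vocabulary or SignVocabulary()
    if isinstance(path, (str, Path)):
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh, delimiter=delimiter))
    else:
        rows = list(csv.reader(path, delimiter=delimiter))
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        return []
    if header:
        colmap = _resolve_header(rows[0], header_synonyms)
        data = rows[1:]
        first_row_number = 2
    else:
        colmap = {"source": 0, "interaction": 1, "target": 2}
        for i, opt in enumerate(OPTIONAL_FIELDS):
            colmap[opt] = 3 + i
        data = rows
        first_row_number = 1

    def cell(row: Sequence[str], name: str) -> str:
        i = colmap.get(name)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    records = []
    for offset, row in enumerate(data):
        rownum = first_row_number + offset
        src = cell(row, "source")
        tgt = cell(row, "target")
        if not src:
            raise RowError("empty mandatory cell 'source'", rownum)
        if not tgt:
            raise RowError("empty mandatory cell 'target'", rownum)
        records.append(
            InteractionRecord(
                source=src,
                interaction=vocab.canonical(cell(row, "interaction")),
                target=tgt,
                biological_function=cell(row, "biological_function"),
                species=cell(row, "species"),
                reference=cell(row, "reference"),
                notes=cell(row, "notes"),
            )
        )
    return records


def write_interaction_table(
    records: Iterable[InteractionRecord],
    path: str | Path | io.TextIOBase,
    *,
    delimiter: str = ",",
) -> None:
    """Write records as a delimited table with the canonical seven-field header."""
    fields = ("source", "interaction", "target") + OPTIONAL_FIELDS

    def _write(fh):
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(fields)
        for rec in records:
            w.writerow([getattr(rec, f) for f in fields])

    if isinstance(path, (str, Path)):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            _write(fh)
    else:
        _write(path)


@dataclass
class ValidationReport:
    """Report-only summary of table hygiene issues; input is never mutated."""

    n_records: int = 0
    duplicate_count: int = 0
    unknown_sign_count: int = 0
    self_interaction_count: int = 0
    issues: list[str] = field(default_factory=list)


def validate_records(records: Sequence[InteractionRecord]) -> ValidationReport:
    """Flag exact duplicate triples, unknown signs and self-interactions."""
    report = ValidationReport(n_records=len(records))
    seen: dict[tuple[str, str, str], int] = {}
    for i, rec in enumerate(records, start=1):
        if rec.triple in seen:
            report.duplicate_count += 1
            report.issues.append(
                f"row {i}: duplicate of row {seen[rec.triple]} {rec.triple!r}"
            )
        else:
            seen[rec.triple] = i
        if rec.interaction not in (ACTIVATION, INHIBITION):
            report.unknown_sign_count += 1
            report.issues.append(f"row {i}: unknown sign {rec.interaction!r}")
        if rec.source == rec.target:
            report.self_interaction_count += 1
            report.issues.append(f"row {i}: self-interaction on {rec.source!r}")
    return report


def filter_records(
    records: Sequence[InteractionRecord],
    *,
    species: str | None = None,
    biological_function: str | None = None,
    predicate: Callable[[InteractionRecord], bool] | None = None,
) -> list[InteractionRecord]:
    """Order-preserving subset of records; an empty filter is the identity.

    ``species`` and ``biological_function`` match their fields exactly
    (after trimming); ``predicate`` is an arbitrary record test and is
    AND-combined with the field filters.
    """
    out = []
    for rec in records:
        if species is not None and rec.species != species:
            continue
        if biological_function is not None and rec.biological_function != biological_function:
            continue
        if predicate is not None and not predicate(rec):
            continue
        out.append(rec)
    return out
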