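"""Reading, validation and canonicalization of clinical-trial registry exports.

Registries are CSV files with one row per trial and seven required columns
(NCT Number, Study Title, Conditions, Interventions, Sponsor, Collaborators,
Locations); multi-valued cells use ``|`` as the intra-cell delimiter.  An
extended dialect may carry a registration-date column, which is required only
for temporal train/test splitting.

Affiliation names in real registries are noisy (a hospital may appear under
its own name and under its parent university's).  Cleaning here is strictly
deterministic: unicode normalization, whitespace collapse, then lookup in a
user-supplied alias map (raw -> canonical).  No fuzzy entity resolution is
attempted.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import AliasValidationError, SchemaError

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = (
    "NCT Number",
    "Study Title",
    "Conditions",
    "Interventions",
    "Sponsor",
    "Collaborators",
    "Locations",
)

#: Category assigned to interventions written without a "CATEGORY:" prefix.
DEFAULT_CATEGORY = "OTHER"

_CATEGORY_RE = re.compile(r"^([A-Za-z][A-Za-z_ ]*):\s*(.+)$")


@dataclass(frozen=True)
class TrialRecord:
    """One registry row after parsing.

    ``affiliations`` is the ordered, duplicate-free union of the sponsor
    (first) and the collaborators; the two roles are not distinguished
    downstream because the collaboration graph is undirected.
    """

    nct_id: str
    title: str
    conditions: tuple[str, ...]
    interventions: tuple[tuple[str, str], ...]  # (category, name)
    affiliations: tuple[str, ...]
    countries: tuple[str, ...]
    year: Optional[int] = None


@dataclass(frozen=True)
class RegistryDialect:
    """CSV dialect parameters for registry exports."""

    delimiter: str = "|"
    date_column: str = "Registration Date"


@dataclass
class AliasMap:
    """Mapping of raw affiliation spellings to canonical names.

    Canonical targets must be fixed points: if a canonical name itself
    appears as a key it must map to itself, otherwise chained (or cyclic)
    renames would make the result order-dependent.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for raw, canon in self.entries.items():
            target = self.entries.get(canon)
            if target is not None and target != canon:
                raise AliasValidationError(
                    f"canonical target {canon!r} (from {raw!r}) is itself "
                    f"remapped to {target!r}; canonical names must be fixed points"
                )

    def resolve(self, name: str) -> str:
        return self.entries.get(name, name)

    @classmethod
    def from_file(cls, path: str | Path) -> "AliasMap":
        """Load from a JSON object or a two-column TSV (raw<TAB>canonical)."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            entries = dict(json.loads(text))
        else:
            entries = {}
            for line in text.splitlines():
                if not line.strip():
                    continue
                raw, canon = line.split("\t", 1)
                entries[raw.strip()] = canon.strip()
        amap = cls(entries)
        amap.validate()
        return amap


def _clean_name(name: str) -> str:
    """Deterministic string normalization: NFKC + whitespace collapse."""
    name = unicodedata.normalize("NFKC", name)
    return " ".join(name.split())


def _split_cell(cell: object, delimiter: str = "|") -> list[str]:
    """Split a multi-valued cell, trim tokens, drop empties."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    tokens = str(cell).split(delimiter)
    return [t for t in (tok.strip() for tok in tokens) if t]


def _parse_intervention(token: str) -> tuple[str, str]:
    m = _CATEGORY_RE.match(token)
    if m:
        return m.group(1).strip().upper(), m.group(2).strip()
    return DEFAULT_CATEGORY, token


def _parse_year(value: object) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    m = re.match(r"^(\d{4})", s)
    return int(m.group(1)) if m else None


def extract_countries(location_cell: str) -> list[str]:
    """Extract country names from a Locations cell.

    Each ``|``-separated entry is of the form "City, Region, Country"; the
    final comma-separated token is taken as the country.  Duplicates are
    removed keeping first-occurrence order.
    """
    countries: list[str] = []
    for entry in _split_cell(location_cell):
        country = entry.rsplit(",", 1)[-1].strip()
        if country and country not in countries:
            countries.append(country)
    return countries


def _dedupe(names: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for n in names:
        if n and n not in seen:
            seen[n] = None
    return tuple(seen)


def read_registry(
    path: str | Path, dialect: RegistryDialect | None = None
) -> list[TrialRecord]:
    """Read a registry CSV into trial records.

    The header must contain the seven required field names (matched
    case-insensitively).  Rows listing no affiliation at all are dropped
    with a logged warning — they cannot contribute to the collaboration
    graph.
    """
    dialect = dialect or RegistryDialect()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    except OSError as exc:
        raise OSError(f"{path}: cannot read registry file: {exc}") from exc

    colmap = {c.strip().lower(): c for c in df.columns}
    missing = [f for f in REQUIRED_FIELDS if f.lower() not in colmap]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    date_col = colmap.get(dialect.date_column.lower())

    def cell(row, name: str) -> str:
        return row[colmap[name.lower()]]

    records: list[TrialRecord] = []
    for _, row in df.iterrows():
        sponsor = [_clean_name(s) for s in _split_cell(cell(row, "Sponsor"), dialect.delimiter)]
        collaborators = [
            _clean_name(s)
            for s in _split_cell(cell(row, "Collaborators"), dialect.delimiter)
        ]
        affiliations = _dedupe(sponsor + collaborators)
        nct = str(cell(row, "NCT Number")).strip()
        if not affiliations:
            logger.warning("dropping trial %s: no affiliations listed", nct)
            continue
        records.append(
            TrialRecord(
                nct_id=nct,
                title=str(cell(row, "Study Title")).strip(),
                conditions=tuple(_split_cell(cell(row, "Conditions"), dialect.delimiter)),
                interventions=tuple(
                    _parse_intervention(t)
                    for t in _split_cell(cell(row, "Interventions"), dialect.delimiter)
                ),
                affiliations=affiliations,
                countries=tuple(extract_countries(cell(row, "Locations"))),
                year=_parse_year(row[date_col]) if date_col is not None else None,
            )
        )
    return records


def write_registry(
    records: Sequence[TrialRecord],
    path: str | Path,
    dialect: RegistryDialect | None = None,
) -> None:
    """Write records back out in the registry CSV dialect (fixture writer).

    The sponsor is emitted as the first affiliation, the rest as
    collaborators; a date column is included when any record carries a year.
    """
    dialect = dialect or RegistryDialect()
    has_year = any(r.year is not None for r in records)
    rows = []
    for r in records:
        row = {
            "NCT Number": r.nct_id,
            "Study Title": r.title,
            "Conditions": dialect.delimiter.join(r.conditions),
            "Interventions": dialect.delimiter.join(
                f"{cat}: {name}" for cat, name in r.interventions
            ),
            "Sponsor": r.affiliations[0] if r.affiliations else "",
            "Collaborators": dialect.delimiter.join(r.affiliations[1:]),
            "Locations": dialect.delimiter.join(f"City, {c}" for c in r.countries),
        }
        if has_year:
            row[dialect.date_column] = "" if r.year is None else f"{r.year}-01-01"
        rows.append(row)
    columns = list(REQUIRED_FIELDS) + ([dialect.date_column] if has_year else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def canonicalize(
    records: Sequence[TrialRecord], aliases: AliasMap | Mapping[str, str] | None = None
) -> list[TrialRecord]:
    """Clean and canonicalize affiliation names in every record.

    Each affiliation is normalized (NFKC, whitespace collapse) and then
    passed through the alias map; duplicates created by the merge collapse
    to the first occurrence.  Idempotent.
    """
    if aliases is None:
        amap = AliasMap()
    elif isinstance(aliases, AliasMap):
        amap = aliases
    else:
        amap = AliasMap(dict(aliases))
    amap.validate()
    out = []
    for r in records:
        # the resolved target is cleaned as well, so idempotence survives
        # alias maps whose canonical spellings are themselves un-normalized
        cleaned = [_clean_name(amap.resolve(_clean_name(a))) for a in r.affiliations]
        out.append(replace(r, affiliations=_dedupe(cleaned)))
    return out


def filter_by_condition(
    records: Sequence[TrialRecord], keywords: Sequence[str]
) -> list[TrialRecord]:
    """Keep records whose title or any condition mentions any keyword.

    Matching is case-insensitive substring, mirroring how disease-specific
    registry exports are pulled by search term (e.g. "diabetes", "stroke").
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    kws = [k.lower() for k in keywords]

    def matches(r: TrialRecord) -> bool:
        haystacks = [r.title.lower()] + [c.lower() for c in r.conditions]
        return any(k in h for k in kws for h in haystacks)

    return [r for r in records if matches(r)]
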