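"""Reading and writing pathways and interaction catalogs.

A pathway is an ordered, nonempty sequence of directed interactions, each
carrying an ST code.  Two text dialects mirror the system's input box —
comma-separated ST-code strings and comma-separated entity-name strings
(resolved against an interaction catalog) — plus a structured TSV format
for pathway sets and catalogs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .st_core import STCode, parse_st_code

__all__ = [
    "Interaction",
    "Pathway",
    "InteractionCatalog",
    "PathwayLoadError",
    "ChainWarning",
    "read_pathway_tsv",
    "write_pathway_tsv",
    "read_catalog_tsv",
    "write_catalog_tsv",
    "parse_code_string",
    "resolve_entity_string",
]


class PathwayLoadError(ValueError):
    """Structural problem in an input file or string (row/position cited)."""


class ChainWarning(UserWarning):
    """Consecutive steps of a pathway do not chain target→source."""


@dataclass(frozen=True)
class Interaction:
    """One directed entity→entity step carrying an ST code."""

    source: str
    target: str
    code: STCode

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise PathwayLoadError("interaction endpoints must be nonempty")

    @property
    def is_self_loop(self) -> bool:
        """Self-interactions (e.g. autophosphorylation) are legal, just flagged."""
        return self.source == self.target


@dataclass(frozen=True)
class Pathway:
    """An ordered, nonempty sequence of interactions."""

    id: str
    steps: tuple[Interaction, ...]

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise PathwayLoadError(f"pathway {self.id!r} has no steps")

    def __len__(self) -> int:
        return len(self.steps)

    def chain_breaks(self) -> list[int]:
        """Indices i where step i's target differs from step i+1's source."""
        return [
            i
            for i in range(len(self.steps) - 1)
            if self.steps[i].target != self.steps[i + 1].source
        ]

    @property
    def codes(self) -> tuple[STCode, ...]:
        return tuple(s.code for s in self.steps)

    def code_string(self) -> str:
        """The pathway's coded string, e.g. ``"1.2.1.1,4.1.1.1"``."""
        return ",".join(str(c) for c in self.codes)


class InteractionCatalog:
    """Lookup from an ordered (source, target) entity pair to its ST code.

    The in-memory form of the interaction sub-database; at most one entry
    per ordered pair.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], tuple[STCode, str | None]] = {}

    def add(
        self,
        source: str,
        target: str,
        code: STCode,
        interaction_id: str | None = None,
    ) -> None:
        key = (source, target)
        if key in self._entries:
            raise PathwayLoadError(f"duplicate catalog entry for pair {key}")
        self._entries[key] = (code, interaction_id)

    def lookup(self, source: str, target: str) -> Interaction | None:
        hit = self._entries.get((source, target))
        if hit is None:
            return None
        return Interaction(source, target, hit[0])

    def interaction_id(self, source: str, target: str) -> str | None:
        hit = self._entries.get((source, target))
        return None if hit is None else hit[1]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._entries

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._entries)

    def items(self) -> Iterator[tuple[tuple[str, str], tuple[STCode, str | None]]]:
        return iter(self._entries.items())

    @property
    def entities(self) -> set[str]:
        out: set[str] = set()
        for s, t in self._entries:
            out.add(s)
            out.add(t)
        return out


# ---------------------------------------------------------------------------
# TSV formats.  Pathway TSV columns: pathway_id, step_index (0-based,
# contiguous), source, target, st_code.  Catalog TSV columns: source,
# target, st_code, interaction_id (optional).
# ---------------------------------------------------------------------------

_PATHWAY_COLS = ["pathway_id", "step_index", "source", "target", "st_code"]
_CATALOG_COLS = ["source", "target", "st_code"]


def _open_maybe(file: str | Path | IO[str], mode: str):
    if hasattr(file, "read") or hasattr(file, "write"):
        return file, False
    return open(file, mode, newline="", encoding="utf-8"), True


def read_pathway_tsv(file: str | Path | IO[str]) -> list[Pathway]:
    """Load a pathway TSV; pathways grouped by id, steps ordered by index.

    Raises :class:`PathwayLoadError` citing the data row number for missing
    columns, invalid codes, or non-contiguous step indices.  A header-only
    file yields an empty list.
    """
    fh, close = _open_maybe(file, "r")
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_PATHWAY_COLS) - set(reader.fieldnames)
        if missing:
            raise PathwayLoadError(f"pathway TSV missing columns: {sorted(missing)}")
        rows: dict[str, list[tuple[int, Interaction]]] = {}
        order: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                idx = int(row["step_index"])
                inter = Interaction(
                    row["source"], row["target"], parse_st_code(row["st_code"])
                )
            except ValueError as exc:
                raise PathwayLoadError(f"row {lineno}: {exc}") from exc
            pid = row["pathway_id"]
            if pid not in rows:
                rows[pid] = []
                order.append(pid)
            rows[pid].append((idx, inter))
        pathways = []
        for pid in order:
            steps = sorted(rows[pid], key=lambda t: t[0])
            indices = [i for i, _ in steps]
            if indices != list(range(len(indices))):
                raise PathwayLoadError(
                    f"pathway {pid!r}: step_index values {indices} are not "
                    f"contiguous from 0"
                )
            pw = Pathway(pid, tuple(s for _, s in steps))
            breaks = pw.chain_breaks()
            if breaks:
                # branching upstream networks are legal; flag, don't reject
                warnings.warn(
                    f"pathway {pid!r} has non-chaining steps at positions {breaks}",
                    ChainWarning,
                    stacklevel=2,
                )
            pathways.append(pw)
        return pathways
    finally:
        if close:
            fh.close()


def write_pathway_tsv(
    pathways: Iterable[Pathway], file: str | Path | IO[str]
) -> None:
    """Inverse of :func:`read_pathway_tsv` (field-exact round-trip)."""
    fh, close = _open_maybe(file, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PATHWAY_COLS)
        for pw in pathways:
            for i, step in enumerate(pw.steps):
                writer.writerow([pw.id, i, step.source, step.target, str(step.code)])
    finally:
        if close:
            fh.close()


def read_catalog_tsv(file: str | Path | IO[str]) -> InteractionCatalog:
    """Load an interaction catalog; duplicate (source, target) pairs are an error.

    Wildcard codes are rejected: catalog entries must be fully specified.
    """
    fh, close = _open_maybe(file, "r")
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return InteractionCatalog()
        missing = set(_CATALOG_COLS) - set(reader.fieldnames)
        if missing:
            raise PathwayLoadError(f"catalog TSV missing columns: {sorted(missing)}")
        catalog = InteractionCatalog()
        seen_row: dict[tuple[str, str], int] = {}
        for lineno, row in enumerate(reader, start=2):
            key = (row["source"], row["target"])
            if key in seen_row:
                raise PathwayLoadError(
                    f"duplicate catalog pair {key} on rows {seen_row[key]} "
                    f"and {lineno}"
                )
            if "*" in row["st_code"]:
                raise PathwayLoadError(
                    f"row {lineno}: wildcard code {row['st_code']!r} not allowed "
                    f"in a catalog; entries must be fully specified"
                )
            try:
                code = parse_st_code(row["st_code"])
            except ValueError as exc:
                raise PathwayLoadError(f"row {lineno}: {exc}") from exc
            catalog.add(key[0], key[1], code, row.get("interaction_id") or None)
            seen_row[key] = lineno
        return catalog
    finally:
        if close:
            fh.close()


def write_catalog_tsv(
    catalog: InteractionCatalog, file: str | Path | IO[str]
) -> None:
    fh, close = _open_maybe(file, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CATALOG_COLS + ["interaction_id"])
        for (source, target), (code, iid) in catalog.items():
            writer.writerow([source, target, str(code), iid or ""])
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# The two input-box dialects: ST-code strings and entity strings, commas as
# separation.
# ---------------------------------------------------------------------------


def parse_code_string(text: str, id: str = "query") -> Pathway:
    """Parse a comma-separated ST-code string into a pathway.

    Steps get synthetic endpoint names ``<id>_n0, <id>_n1, …`` so code-only
    pathways can still enter network construction.  Whitespace around each
    code is tolerated; empty fields are an error naming their 1-based
    position.
    """
    fields = text.split(",")
    if not text.strip():
        raise PathwayLoadError("empty code string")
    steps = []
    for pos, fieldtext in enumerate(fields, start=1):
        fieldtext = fieldtext.strip()
        if not fieldtext:
            raise PathwayLoadError(f"empty ST code at position {pos}")
        try:
            code = parse_st_code(fieldtext)
        except ValueError as exc:
            raise PathwayLoadError(f"position {pos}: {exc}") from exc
        steps.append(Interaction(f"{id}_n{pos - 1}", f"{id}_n{pos}", code))
    return Pathway(id, tuple(steps))


def resolve_entity_string(
    text: str, catalog: InteractionCatalog, id: str = "query"
) -> Pathway:
    """Resolve a comma-separated entity-name string via the catalog.

    Consecutive name pairs must each exist in the catalog; all missing
    pairs are reported together, not just the first.
    """
    names = [n.strip() for n in text.split(",")]
    if any(not n for n in names):
        raise PathwayLoadError("empty entity name in entity string")
    if len(names) < 2:
        raise PathwayLoadError(
            "entity string needs at least two entities to form an interaction"
        )
    steps = []
    missing = []
    for a, b in zip(names, names[1:]):
        hit = catalog.lookup(a, b)
        if hit is None:
            missing.append((a, b))
        else:
            steps.append(hit)
    if missing:
        raise PathwayLoadError(
            "entity pairs not in the interaction catalog: "
            + ", ".join(f"({a}, {b})" for a, b in missing)
        )
    return Pathway(id, tuple(steps))
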