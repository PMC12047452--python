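"""ST classification codes and their hierarchical similarity.

Every interaction in a signal-transduction pathway carries a four-level
dot-separated *ST code* ``a.b.c.d`` (in the style of EC enzyme numbers):

* level 1 — cellular location of the event (1..6, e.g. 1 = extracellular
  signal reception, 4 = intracellular signal transduction);
* level 2 — action type within that location (range depends on level 1,
  e.g. 4.5 = ubiquitination);
* level 3 — characteristic of the entity pair involved;
* level 4 — serial number of the action within its type.

Levels 1 and 2 form a closed taxonomy (29 labelled rows); levels 3 and 4
are open-ended positive integers.  Two codes are compared by the length of
their common prefix, quantized to {0, 0.25, 0.5, 0.75, 1} — the
substitution score used by pathway alignment.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "STCode",
    "STPattern",
    "CategoryTable",
    "STCodeError",
    "TaxonomyError",
    "parse_st_code",
    "parse_st_pattern",
    "st_similarity",
    "category_labels",
    "default_category_table",
]

#: Valid level-2 range per level-1 category (closed taxonomy).
LEVEL2_RANGES: Mapping[int, range] = {
    1: range(1, 7),
    2: range(1, 8),
    3: range(1, 3),
    4: range(1, 13),
    5: range(1, 2),
    6: range(1, 6),
}


class STCodeError(ValueError):
    """Malformed ST code text (wrong field count, non-integer field)."""


class TaxonomyError(ValueError):
    """Syntactically valid code whose (level1, level2) pair is not in the taxonomy."""


@dataclass(frozen=True, order=True)
class STCode:
    """A fully specified four-level classification code.

    Instances are immutable, hashable and ordered lexicographically by
    level, so they can key dictionaries and sort deterministically.
    """

    level1: int
    level2: int
    level3: int
    level4: int

    def __post_init__(self) -> None:
        if self.level1 not in LEVEL2_RANGES:
            raise TaxonomyError(
                f"level1 must be in 1..6, got {self.level1}"
            )
        valid2 = LEVEL2_RANGES[self.level1]
        if self.level2 not in valid2:
            raise TaxonomyError(
                f"level2 for level1={self.level1} must be in "
                f"{valid2.start}..{valid2.stop - 1}, got {self.level2}"
            )
        if self.level3 < 1:
            raise TaxonomyError(f"level3 must be >= 1, got {self.level3}")
        if self.level4 < 1:
            raise TaxonomyError(f"level4 must be >= 1, got {self.level4}")

    @property
    def levels(self) -> tuple[int, int, int, int]:
        return (self.level1, self.level2, self.level3, self.level4)

    def __str__(self) -> str:
        return f"{self.level1}.{self.level2}.{self.level3}.{self.level4}"


@dataclass(frozen=True)
class STPattern:
    """A wildcard code pattern such as ``1.2.*.*`` for catalog queries.

    Wildcards (``None``) may appear at any level but must be suffix-closed:
    once a level is a wildcard all deeper levels are too, mirroring how the
    taxonomy prints its rows.  Patterns never appear inside pathways.
    """

    level1: int | None
    level2: int | None
    level3: int | None
    level4: int | None

    def __post_init__(self) -> None:
        seen_wild = False
        for lv in (self.level1, self.level2, self.level3, self.level4):
            if lv is None:
                seen_wild = True
            elif seen_wild:
                raise STCodeError(
                    "wildcard pattern must not specify a level below a '*'"
                )

    def matches(self, code: STCode) -> bool:
        for pat, val in zip(
            (self.level1, self.level2, self.level3, self.level4), code.levels
        ):
            if pat is not None and pat != val:
                return False
        return True

    def __str__(self) -> str:
        return ".".join(
            "*" if lv is None else str(lv)
            for lv in (self.level1, self.level2, self.level3, self.level4)
        )


_FIELD_NAMES = ("level1", "level2", "level3", "level4")


def _split_fields(text: str) -> list[str]:
    fields = text.strip().split(".")
    if len(fields) != 4:
        raise STCodeError(
            f"ST code must have 4 dot-separated fields, got {len(fields)}: {text!r}"
        )
    return fields


def parse_st_code(text: str) -> STCode:
    """Parse ``"a.b.c.d"`` into a validated :class:`STCode`.

    Leading/trailing whitespace is tolerated.  Raises :class:`STCodeError`
    for malformed text (naming the offending field) and
    :class:`TaxonomyError` for a (level1, level2) pair outside the taxonomy.
    """
    values = []
    for name, field in zip(_FIELD_NAMES, _split_fields(text)):
        try:
            values.append(int(field))
        except ValueError:
            raise STCodeError(
                f"field {name} of ST code {text!r} is not an integer: {field!r}"
            ) from None
        if values[-1] < 0:
            raise STCodeError(f"field {name} of ST code {text!r} is negative")
    return STCode(*values)


def parse_st_pattern(text: str) -> STPattern:
    """Parse a wildcard pattern such as ``"1.2.*.*"``."""
    values: list[int | None] = []
    for name, field in zip(_FIELD_NAMES, _split_fields(text)):
        if field == "*":
            values.append(None)
            continue
        try:
            values.append(int(field))
        except ValueError:
            raise STCodeError(
                f"field {name} of pattern {text!r} is not an integer or '*'"
            ) from None
    return STPattern(*values)


def st_similarity(a: STCode, b: STCode) -> float:
    """Hierarchical similarity σ(a, b) = 0.25 × common-prefix length.

    0 when the level-1 digits differ, 0.25 when only level 1 agrees, 0.5
    through levels 1–2, 0.75 through levels 1–3, and 1 for identical codes.
    Symmetric in its arguments.
    """
    prefix = 0
    for x, y in zip(a.levels, b.levels):
        if x != y:
            break
        prefix += 1
    return 0.25 * prefix


class CategoryTable:
    """Label map for the (level1, level2) taxonomy.

    Backed by the packaged TSV (columns ``level1``, ``level2``, ``label``;
    level2 ``*`` marks a level-1 row) so the taxonomy is auditable and can
    be overridden from a file of the same shape.
    """

    def __init__(self, entries: Mapping[tuple[int, int | None], str]):
        self._entries = dict(entries)
        for l1, rng in LEVEL2_RANGES.items():
            if (l1, None) not in self._entries:
                raise TaxonomyError(f"category table missing level-1 row {l1}.*")
            for l2 in rng:
                if (l1, l2) not in self._entries:
                    raise TaxonomyError(
                        f"category table missing level-2 row {l1}.{l2}"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryTable":
        entries: dict[tuple[int, int | None], str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                l1 = int(row["level1"])
                l2 = None if row["level2"] == "*" else int(row["level2"])
                key = (l1, l2)
                if key in entries:
                    raise TaxonomyError(f"duplicate category row {l1}.{row['level2']}")
                entries[key] = row["label"]
        return cls(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[int, int | None]]:
        return iter(self._entries)

    def level1_label(self, level1: int) -> str:
        return self._entries[(level1, None)]

    def level2_label(self, level1: int, level2: int) -> str:
        return self._entries[(level1, level2)]

    def labels(self, code: STCode) -> tuple[str, str]:
        return (
            self.level1_label(code.level1),
            self.level2_label(code.level1, code.level2),
        )


_default_table: CategoryTable | None = None


def default_category_table() -> CategoryTable:
    """The packaged taxonomy table (loaded once, cached)."""
    global _default_table
    if _default_table is None:
        ref = importlib.resources.files("stpath") / "data" / "st_categories.tsv"
        with importlib.resources.as_file(ref) as path:
            _default_table = CategoryTable.from_tsv(path)
    return _default_table


def category_labels(
    code: STCode, table: CategoryTable | None = None
) -> tuple[str, str]:
    """(level-1 label, level-2 label) for a valid code."""
    return (table or default_category_table()).labels(code)
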