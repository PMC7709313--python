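"""Entity registries, association tables and binary incidence matrices.

The raw inputs are three two-column association tables (miRNA-disease,
miRNA-lncRNA, lncRNA-disease).  Names are canonicalized (case-folded,
trimmed, internal whitespace collapsed) before deduplication, registries fix
a stable integer index for every entity, and incidence matrices record known
associations as 0/1 entries with labelled axes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")

#: header tokens that mark a first line as a column header rather than data
_HEADER_TOKENS = ("mirna", "lncrna", "disease")


def canonicalize(name: str) -> str:
    """Case-fold, strip, and collapse internal whitespace runs."""
    return _WS.sub(" ", name.strip()).casefold()


class EntityRegistry:
    """Ordered universe of entity names with a 0-based index.

    Names are canonicalized on construction; duplicates (after
    canonicalization) are rejected.
    """

    def __init__(self, kind: str, names: Iterable[str]):
        self.kind = kind
        self.names: list[str] = []
        self._index: dict[str, int] = {}
        for raw in names:
            name = canonicalize(raw)
            if name in self._index:
                raise ValueError(f"duplicate {kind} name after canonicalization: {name!r}")
            self._index[name] = len(self.names)
            self.names.append(name)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return canonicalize(name) in self._index

    def __iter__(self):
        return iter(self.names)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EntityRegistry)
            and self.kind == other.kind
            and self.names == other.names
        )

    def index_of(self, name: str) -> int:
        key = canonicalize(name)
        if key not in self._index:
            raise KeyError(f"unknown {self.kind} name: {name!r}")
        return self._index[key]

    def __repr__(self) -> str:
        return f"EntityRegistry(kind={self.kind!r}, n={len(self)})"

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.names) + "\n", encoding="utf-8")

    @classmethod
    def read_tsv(cls, kind: str, path: str | Path) -> "EntityRegistry":
        lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
        return cls(kind, lines)


@dataclass
class AssociationTable:
    """Deduplicated, canonicalized (left, right) name pairs in first-seen order."""

    records: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        out: list[tuple[str, str]] = []
        for left, right in self.records:
            pair = (canonicalize(left), canonicalize(right))
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
        self.records = out

    def __len__(self) -> int:
        return len(self.records)

    def left_names(self) -> list[str]:
        """Distinct left-entity names in first-seen order."""
        return list(dict.fromkeys(left for left, _ in self.records))

    def right_names(self) -> list[str]:
        return list(dict.fromkeys(right for _, right in self.records))


@dataclass
class IncidenceMatrix:
    """Binary association matrix with registries labelling both axes."""

    rows: EntityRegistry
    cols: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"shape {self.values.shape} does not match registries "
                f"({len(self.rows)} x {len(self.cols)})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("incidence matrix entries must be exactly 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows.names, columns=self.cols.names)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def read_association_table(
    path: str | Path,
    provenance: str = "",
    sep: str | None = None,
) -> AssociationTable:
    """Read a two-column association table (TSV by default, comma accepted).

    The first column is the left entity, the second the right entity.  A
    first line containing a literal "mirna"/"lncrna"/"disease" token is
    treated as a header and dropped.  Lines with fewer than two fields raise
    a parse error naming the offending line number.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty association table")

    records: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        delim = sep if sep is not None else ("\t" if "\t" in line else ",")
        fields = [f for f in line.split(delim)]
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}:{lineno}: expected at least two fields, got {line!r}")
        if lineno == 1:
            low = line.casefold()
            if any(tok in low for tok in _HEADER_TOKENS):
                continue
        records.append((fields[0], fields[1]))
    if not records:
        raise ValueError(f"{path}: no data rows")
    return AssociationTable(records, provenance=provenance or str(path))


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    """Write a table as two tab-separated columns, one pair per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for left, right in table.records:
            fh.write(f"{left}\t{right}\n")


def build_incidence(
    table: AssociationTable,
    rows: EntityRegistry,
    cols: EntityRegistry,
    on_unknown: str = "error",
) -> IncidenceMatrix:
    """Build the 0/1 incidence matrix of a table over given registries.

    ``on_unknown`` is "error" (default: any unresolvable name raises) or
    "drop" (pairs with unknown names are dropped with a logged warning).
    """
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    values = np.zeros((len(rows), len(cols)))
    dropped = 0
    for left, right in table.records:
        try:
            i = rows.index_of(left)
            j = cols.index_of(right)
        except KeyError:
            if on_unknown == "error":
                raise
            dropped += 1
            continue
        values[i, j] = 1.0
    if dropped:
        logger.warning("build_incidence: dropped %d pairs with unregistered names", dropped)
    return IncidenceMatrix(rows, cols, values)


def filter_ld_associations(
    raw_ld: AssociationTable,
    lnc_universe: EntityRegistry,
    dis_universe: EntityRegistry,
) -> tuple[AssociationTable, EntityRegistry, EntityRegistry]:
    """Restrict lncRNA-disease pairs to entities seen in the miRNA tables.

    Only pairs whose lncRNA occurs in ``lnc_universe`` (the lncRNAs of the
    miRNA-lncRNA table) and whose disease occurs in ``dis_universe`` (the
    diseases of the miRNA-disease table) survive.  Fresh registries are
    rebuilt from the surviving pairs alone, so the returned registries define
    the working lncRNA/disease universes of the association matrix.
    """
    kept = [
        (left, right)
        for left, right in raw_ld.records
        if left in lnc_universe and right in dis_universe
    ]
    table = AssociationTable(kept, provenance=raw_ld.provenance)
    lnc_reg = EntityRegistry("lncRNA", table.left_names())
    dis_reg = EntityRegistry("disease", table.right_names())
    return table, lnc_reg, dis_reg
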