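"""Identifier conversion among gene locus, gene symbol and array probe set.

Relations are many-to-many in both directions (one probe set can measure
several loci and one locus can be covered by several probes), so conversion
keeps every target rather than electing a "best" hit — any arbitration
would silently bias the enrichment counts.  Enrichment always runs in
locus space; probe queries are expanded first and the expansion is audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "IdKind",
    "MappingRecord",
    "IdMappingTable",
    "ConversionEntry",
    "ConversionReport",
    "read_mapping",
    "write_mapping",
    "convert",
    "query_to_locus",
    "detect_id_kind",
]

_KINDS = ("locus", "symbol", "probe")


class IdKind(str):
    """One of 'locus', 'symbol', 'probe'."""

    def __new__(cls, value: str):
        if value not in _KINDS:
            raise ValueError(f"ID kind must be one of {_KINDS}, got {value!r}")
        return str.__new__(cls, value)


@dataclass(frozen=True)
class MappingRecord:
    locus: str
    symbol: Optional[str] = None
    probe: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.locus:
            raise ValueError("locus field must be non-empty")

    def get(self, kind: str) -> Optional[str]:
        return getattr(self, kind)


@dataclass
class IdMappingTable:
    """Deduplicated (locus, symbol?, probe?) records."""

    records: frozenset[MappingRecord]

    def __post_init__(self) -> None:
        self.records = frozenset(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def targets(self, id_: str, from_kind: str, to_kind: str) -> list[str]:
        """All to_kind IDs sharing a record with id_ on the from_kind side, sorted."""
        out = {
            t for r in self.records
            if r.get(from_kind) == id_ and (t := r.get(to_kind)) is not None
        }
        return sorted(out)


def read_mapping(path: str | Path) -> IdMappingTable:
    """Read a mapping TSV with header columns from {locus, symbol, probe}.

    Blank cells become missing values; fully duplicated rows collapse.
    A missing ``locus`` column is a format error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "locus" not in df.columns:
        raise ValueError(f"{path}: mapping file must have a 'locus' column")
    unknown = set(df.columns) - set(_KINDS)
    if unknown:
        raise ValueError(f"{path}: unknown mapping columns {sorted(unknown)}")
    records = set()
    for _, row in df.iterrows():
        locus = row["locus"].strip()
        if not locus:
            raise ValueError(f"{path}: row with empty locus field")
        records.add(MappingRecord(
            locus=locus,
            symbol=row["symbol"].strip() or None if "symbol" in df.columns else None,
            probe=row["probe"].strip() or None if "probe" in df.columns else None,
        ))
    return IdMappingTable(records=frozenset(records))


def write_mapping(table: IdMappingTable, path: str | Path) -> None:
    """Write the table back as a three-column TSV in deterministic order."""
    rows = sorted(
        (r.locus, r.symbol or "", r.probe or "") for r in table.records
    )
    df = pd.DataFrame(rows, columns=["locus", "symbol", "probe"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class ConversionEntry:
    """Per-input-ID conversion outcome."""

    source: str
    targets: list[str]
    unmapped: bool
    one_to_many: bool


@dataclass
class ConversionReport:
    entries: list[ConversionEntry]
    #: flat deduplicated targets, first-seen order
    output: list[str]

    @property
    def unmapped_ids(self) -> list[str]:
        return [e.source for e in self.entries if e.unmapped]

    @property
    def one_to_many_count(self) -> int:
        return sum(e.one_to_many for e in self.entries)


def convert(
    ids: Sequence[str], from_kind: str, to_kind: str, table: IdMappingTable
) -> ConversionReport:
    """Translate IDs between kinds; unmapped inputs are data, not errors."""
    from_kind, to_kind = IdKind(from_kind), IdKind(to_kind)
    if from_kind == to_kind:
        raise ValueError("source and target ID kinds must differ")
    entries: list[ConversionEntry] = []
    output: list[str] = []
    seen: set[str] = set()
    for id_ in ids:
        targets = table.targets(id_, from_kind, to_kind)
        entries.append(ConversionEntry(
            source=id_, targets=targets,
            unmapped=not targets, one_to_many=len(targets) > 1,
        ))
        for t in targets:
            if t not in seen:
                seen.add(t)
                output.append(t)
    return ConversionReport(entries=entries, output=output)


def detect_id_kind(ids: Sequence[str]) -> str:
    """Advisory heuristic: Affymetrix probe-set IDs end in '_at'.

    Raises when the list mixes apparent kinds — the caller should then
    require an explicit declaration.
    """
    kinds = {"probe" if i.endswith("_at") else "locus" for i in ids}
    if len(kinds) > 1:
        raise ValueError(
            "query mixes apparent probe-set and locus IDs; declare the ID "
            "type explicitly (e.g. --id-type probe)"
        )
    return kinds.pop() if kinds else "locus"


def query_to_locus(
    query: Sequence[str],
    table: IdMappingTable,
    id_kind: Optional[str] = None,
) -> tuple[list[str], ConversionReport]:
    """Bring a query into locus space before enrichment.

    Locus input passes through unchanged (identity report).  Probe and
    symbol inputs expand to all mapped loci; an all-unmapped expansion
    raises with an actionable message.  ``id_kind=None`` auto-detects.
    """
    kind = IdKind(id_kind) if id_kind is not None else detect_id_kind(query)
    if kind == "locus":
        entries = [ConversionEntry(source=i, targets=[i], unmapped=False,
                                   one_to_many=False) for i in query]
        output = list(dict.fromkeys(query))
        return output, ConversionReport(entries=entries, output=output)
    report = convert(query, kind, "locus", table)
    if not report.output:
        raise ValueError(
            f"none of the {len(query)} {kind} IDs mapped to a gene locus; "
            "check the mapping table and the declared ID type"
        )
    return report.output, report
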