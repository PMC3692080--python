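"""Gene-set collections: reading/writing GMT, metadata sidecars, naming.

Gene sets are organized in four categories mirroring the usual provenance
of plant gene-set resources: GO-derived sets, gene families, curated
(literature/pathway) sets, and motif-target sets.  GMT is the interchange
format (tab-separated: name, description, members...); richer metadata
(PubMed ID, author, source database) travels in a sidecar TSV keyed by set
name so the GMT files stay interoperable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Category",
    "Provenance",
    "GeneSet",
    "GeneSetCollection",
    "Background",
    "read_gmt",
    "write_gmt",
    "attach_metadata",
    "make_curated_name",
    "read_id_list",
]


class Category(str, Enum):
    """The four gene-set categories."""

    GO = "GO"
    GeneFamily = "GeneFamily"
    Curated = "Curated"
    Motif = "Motif"


@dataclass(frozen=True)
class Provenance:
    """Optional origin record for a (typically curated) gene set."""

    author: str = ""
    pubmed_id: str = ""
    source_db: str = ""
    url: str = ""


@dataclass
class GeneSet:
    """A named, non-empty set of gene identifiers in one category."""

    name: str
    description: str
    members: frozenset[str]
    category: Category = Category.Curated
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        self.category = Category(self.category)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """An ordered list of uniquely named gene sets for one organism."""

    sets: list[GeneSet] = field(default_factory=list)
    organism: str = "synthetic"

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene set names: {sorted(dupes)}")

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member sets."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def filter_categories(self, categories: Iterable[Category | str]) -> "GeneSetCollection":
        wanted = {Category(c) for c in categories}
        return GeneSetCollection(
            sets=[s for s in self.sets if s.category in wanted],
            organism=self.organism,
        )


class BackgroundSource(str, Enum):
    precomputed_genome = "precomputed_genome"
    user_supplied = "user_supplied"


@dataclass
class Background:
    """The reference gene universe against which enrichment is judged."""

    genes: frozenset[str]
    source: BackgroundSource = BackgroundSource.user_supplied

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("background is empty")
        self.source = BackgroundSource(self.source)

    def __len__(self) -> int:
        return len(self.genes)


def _clean_id(token: str, case_insensitive: bool = False, strip_suffix: bool = False) -> str:
    token = token.strip()
    if strip_suffix:
        token = re.sub(r"\.\d+$", "", token)
    if case_insensitive:
        token = token.upper()
    return token


def read_gmt(path: str | Path, category: Category | str = Category.Curated) -> GeneSetCollection:
    """Read a Broad-style GMT file into a collection.

    Each line: set name, description, then one or more member IDs, all
    tab-separated.  Duplicate member IDs within a line are collapsed.
    All sets get `category` (default Curated) until a sidecar overrides it.

    Raises ``ValueError`` naming the line number on a malformed (<3 field)
    line, and on duplicate set names.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line must have >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *members = fields
            members = [_clean_id(m) for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(
                GeneSet(name=name.strip(), description=description,
                        members=frozenset(members), category=Category(category))
            )
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write one tab-separated line per set; members in sorted order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


_SIDECAR_COLUMNS = ("category", "pubmed_id", "author", "source_db", "url")


def attach_metadata(collection: GeneSetCollection, sidecar: str | Path) -> GeneSetCollection:
    """Attach category/provenance metadata from a sidecar TSV.

    The sidecar is keyed by set name (first column ``name``) with any of the
    columns category, pubmed_id, author, source_db, url; blank cells are
    ignored.  Rows naming sets absent from the collection are reported with
    a ``UserWarning`` each.  A category value outside the four-value enum
    raises ``ValueError``.
    """
    df = pd.read_csv(sidecar, sep="\t", dtype=str).fillna("")
    if "name" not in df.columns:
        raise ValueError("sidecar must have a 'name' column")
    by_name = {s.name: s for s in collection}
    new_sets = {s.name: s for s in collection}
    for _, row in df.iterrows():
        name = row["name"]
        if name not in by_name:
            warnings.warn(f"sidecar row for unknown gene set {name!r} ignored",
                          UserWarning, stacklevel=2)
            continue
        s = new_sets[name]
        category = s.category
        if row.get("category", ""):
            category = Category(row["category"])  # raises on bad value
        prov = Provenance(
            author=row.get("author", ""),
            pubmed_id=row.get("pubmed_id", ""),
            source_db=row.get("source_db", ""),
            url=row.get("url", ""),
        )
        new_sets[name] = replace(s, category=category, provenance=prov)
    return GeneSetCollection(
        sets=[new_sets[s.name] for s in collection], organism=collection.organism
    )


def make_curated_name(author: str, description: str,
                      direction: Optional[str] = None) -> str:
    """Build a curated-set name: AUTHOR_DESCRIPTION[_UP|_DN].

    Uppercase, underscore-joined tokens; runs of non-alphanumeric
    characters collapse to a single underscore.
    """
    if not author or not author.strip():
        raise ValueError("author must be non-empty")
    if not description or not description.strip():
        raise ValueError("description must be non-empty")
    parts = [author, description]
    if direction is not None:
        direction = direction.upper()
        if direction not in ("UP", "DN"):
            raise ValueError(f"direction must be UP or DN, got {direction!r}")
        parts.append(direction)
    name = "_".join(re.sub(r"[^0-9A-Za-z]+", "_", p.strip()).strip("_") for p in parts)
    return name.upper()


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text ID list, one per line; '#' comments and blanks skipped.

    Order and duplicates are preserved (deduplication is the query audit's
    job, not the reader's).
    """
    ids: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids
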