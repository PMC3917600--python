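"""Local integrated knowledge store.

The store is the package's analogue of a compiled prior-knowledge library: a
single embedded SQLite file holding *sources* (external knowledge providers),
*groups* (pathways, ontology terms, protein families, interaction pairs),
*group members* (identifier bundles that must later be resolved to genes),
*genes* with their genomic regions, *aliases* (gene names of type ``symbol``,
``numeric`` or ``protein``), *SNP loci*, and *rs-merge* records connecting
retired SNP identifiers to current ones.

Knowledge is ingested from a plain-text, tab-separated definition format (see
:func:`KnowledgeStore.add_definitions`) so that a complete store can be built
offline and checked into version control.  Once built, a store can be
*finalized*: the file is compacted and every future mutation attempt raises,
which makes archived stores safe provenance records for published analyses.

All genomic coordinates are 1-based, fully closed intervals.
"""

from __future__ import annotations

import os
import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import FinalizedError, IngestError, KnowledgeError, QueryError

ID_TYPES = ("symbol", "numeric", "protein")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (
    key   TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS source (
    name TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS grp (
    group_id TEXT PRIMARY KEY,
    source   TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS group_name (
    group_id TEXT NOT NULL,
    name     TEXT NOT NULL,
    PRIMARY KEY (group_id, name)
);
CREATE TABLE IF NOT EXISTS member (
    group_id  TEXT NOT NULL,
    ident_key TEXT NOT NULL,
    PRIMARY KEY (group_id, ident_key)
);
CREATE TABLE IF NOT EXISTS gene (
    gene_id TEXT PRIMARY KEY,
    symbol  TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS gene_region (
    gene_id TEXT NOT NULL,
    chrom   TEXT NOT NULL,
    start   INTEGER NOT NULL,
    end     INTEGER NOT NULL,
    PRIMARY KEY (gene_id, chrom, start, end)
);
CREATE TABLE IF NOT EXISTS alias (
    name    TEXT NOT NULL,
    id_type TEXT NOT NULL,
    gene_id TEXT NOT NULL,
    PRIMARY KEY (name, id_type, gene_id)
);
CREATE TABLE IF NOT EXISTS snp_locus (
    rs    INTEGER NOT NULL,
    chrom TEXT NOT NULL,
    pos   INTEGER NOT NULL,
    PRIMARY KEY (rs, chrom, pos)
);
CREATE TABLE IF NOT EXISTS rs_merge (
    old_rs INTEGER PRIMARY KEY,
    new_rs INTEGER NOT NULL
);
"""


def chromosome_key(chrom: str):
    """Sort key placing numeric chromosomes first, in numeric order."""
    c = str(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class GroupMember:
    """One entry of a group: a bundle of 1..n identifiers naming one thing.

    Each identifier is a ``(name, id_type)`` pair with ``id_type`` one of
    ``symbol``, ``numeric`` or ``protein``.  The bundle must be resolved to a
    concrete gene set before use; see :mod:`knowfilter.ambiguity`.
    """

    group_id: str
    identifiers: frozenset[tuple[str, str]]

    def __post_init__(self):
        if not self.identifiers:
            raise KnowledgeError("a group member needs at least one identifier")
        for name, id_type in self.identifiers:
            if id_type not in ID_TYPES:
                raise KnowledgeError(f"unknown identifier type {id_type!r}")

    @property
    def ident_key(self) -> str:
        return ",".join(f"{n}:{t}" for n, t in sorted(self.identifiers))

    @classmethod
    def from_ident_key(cls, group_id: str, key: str) -> "GroupMember":
        pairs = []
        for token in key.split(","):
            name, _, id_type = token.rpartition(":")
            pairs.append((name, id_type))
        return cls(group_id, frozenset(pairs))


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    regions: tuple[tuple[str, int, int], ...]


class KnowledgeStore:
    """Query interface over a single-file embedded knowledge database."""

    def __init__(self, conn: sqlite3.Connection, path: str | None = None):
        self._conn = conn
        self.path = path
        self._conn.executescript(_SCHEMA)
        self._caches: dict = {}

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def create(cls, db_path: str | os.PathLike | None = None) -> "KnowledgeStore":
        """Create a fresh, empty store (in memory when ``db_path`` is None)."""
        if db_path is None:
            return cls(sqlite3.connect(":memory:"), None)
        path = Path(db_path)
        if path.exists():
            raise KnowledgeError(f"refusing to overwrite existing store {path}")
        return cls(sqlite3.connect(str(path)), str(path))

    @classmethod
    def open(cls, db_path: str | os.PathLike) -> "KnowledgeStore":
        """Open an existing store file."""
        path = Path(db_path)
        if not path.is_file():
            raise KnowledgeError(f"knowledge store not found: {path}")
        with open(path, "rb") as fh:
            if fh.read(16) != b"SQLite format 3\x00":
                raise KnowledgeError(f"not a knowledge store file: {path}")
        return cls(sqlite3.connect(str(path)), str(path))

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- metadata ----------------------------------------------------------

    def _meta(self, key: str) -> str | None:
        row = self._conn.execute(
            "SELECT value FROM meta WHERE key = ?", (key,)
        ).fetchone()
        return row[0] if row else None

    def _set_meta(self, key: str, value: str) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES (?, ?)", (key, value)
        )

    @property
    def finalized(self) -> bool:
        return self._meta("finalized") == "1"

    @property
    def genome_build(self) -> str:
        """The reference-genome build label recorded at ingestion."""
        return self._meta("build") or ""

    def finalize(self) -> "KnowledgeStore":
        """Mark the store read-only and compact it for archiving."""
        if self.finalized:
            raise FinalizedError("store is already finalized")
        self._set_meta("finalized", "1")
        self._conn.commit()
        self._conn.execute("VACUUM")
        return self

    def _check_mutable(self) -> None:
        if self.finalized:
            raise FinalizedError("store is finalized; updates are not permitted")

    # -- ingestion ---------------------------------------------------------

    def add_definitions(
        self,
        definition_paths: Sequence[str | os.PathLike],
        build_label: str | None = None,
    ) -> "KnowledgeStore":
        """Ingest one or more knowledge-definition files.

        The format is UTF-8, tab-separated and line-oriented; the first field
        of each line is a record tag::

            build   <label>
            source  <name>
            group   <source> <group_id> <name>[|<name>...]
            member  <group_id> <name>:<id_type>[,<name>:<id_type>...]
            gene    <gene_id> <symbol> <chrom> <start> <end>[;<chrom> <start> <end>...]
            alias   <name> <id_type> <gene_id>[,<gene_id>...]
            snp     <rs> <chrom> <pos>
            merge   <old_rs> <new_rs>

        Lines starting with ``#`` and blank lines are skipped.  Referential
        integrity (members -> groups -> sources, alias targets -> genes) and
        merge-chain acyclicity are validated after all files are read, so the
        resulting store does not depend on record or file order.  An explicit
        ``build_label`` argument overrides any ``build`` records in the files.
        """
        self._check_mutable()
        cur = self._conn.cursor()
        pending_members: list[tuple[str, str, str, int]] = []
        pending_aliases: list[tuple[str, str, str, str, int]] = []
        pending_groups: list[tuple[str, str, int]] = []
        file_build: str | None = None

        for path in definition_paths:
            path = Path(path)
            try:
                text = path.read_text(encoding="utf-8")
            except OSError as exc:
                raise IngestError(f"cannot read definition file: {exc}", path)
            for line_no, raw in enumerate(text.splitlines(), start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                tag = fields[0]
                try:
                    if tag == "build":
                        _expect(fields, 2, path, line_no)
                        file_build = fields[1]
                    elif tag == "source":
                        _expect(fields, 2, path, line_no)
                        cur.execute(
                            "INSERT OR IGNORE INTO source (name) VALUES (?)",
                            (fields[1],),
                        )
                    elif tag == "group":
                        _expect(fields, 4, path, line_no)
                        source, group_id, names = fields[1], fields[2], fields[3]
                        name_list = [n for n in names.split("|") if n]
                        if not name_list:
                            raise IngestError("group needs at least one name", path, line_no)
                        pending_groups.append((group_id, source, line_no))
                        cur.execute(
                            "INSERT OR IGNORE INTO grp (group_id, source) VALUES (?, ?)",
                            (group_id, source),
                        )
                        cur.executemany(
                            "INSERT OR IGNORE INTO group_name (group_id, name) VALUES (?, ?)",
                            [(group_id, n) for n in name_list],
                        )
                    elif tag == "member":
                        _expect(fields, 3, path, line_no)
                        member = _parse_member(fields[1], fields[2], path, line_no)
                        pending_members.append(
                            (member.group_id, member.ident_key, str(path), line_no)
                        )
                    elif tag == "gene":
                        _expect(fields, 4, path, line_no)
                        gene_id, symbol, region_spec = fields[1], fields[2], fields[3]
                        regions = _parse_regions(region_spec, path, line_no)
                        cur.execute(
                            "INSERT OR IGNORE INTO gene (gene_id, symbol) VALUES (?, ?)",
                            (gene_id, symbol),
                        )
                        cur.executemany(
                            "INSERT OR IGNORE INTO gene_region (gene_id, chrom, start, end)"
                            " VALUES (?, ?, ?, ?)",
                            [(gene_id, c, s, e) for c, s, e in regions],
                        )
                        # every gene is reachable by its own symbol and id
                        cur.executemany(
                            "INSERT OR IGNORE INTO alias (name, id_type, gene_id)"
                            " VALUES (?, 'symbol', ?)",
                            [(symbol, gene_id), (gene_id, gene_id)],
                        )
                    elif tag == "alias":
                        _expect(fields, 4, path, line_no)
                        name, id_type, targets = fields[1], fields[2], fields[3]
                        if id_type not in ID_TYPES:
                            raise IngestError(
                                f"unknown identifier type {id_type!r}", path, line_no
                            )
                        for gid in targets.split(","):
                            if not gid:
                                raise IngestError("empty alias target", path, line_no)
                            pending_aliases.append((name, id_type, gid, str(path), line_no))
                    elif tag == "snp":
                        _expect(fields, 4, path, line_no)
                        rs = _parse_int(fields[1], "rs number", path, line_no)
                        pos = _parse_int(fields[3], "position", path, line_no)
                        if rs <= 0 or pos <= 0:
                            raise IngestError("rs and position must be positive", path, line_no)
                        cur.execute(
                            "INSERT OR IGNORE INTO snp_locus (rs, chrom, pos) VALUES (?, ?, ?)",
                            (rs, fields[2], pos),
                        )
                    elif tag == "merge":
                        _expect(fields, 3, path, line_no)
                        old = _parse_int(fields[1], "rs number", path, line_no)
                        new = _parse_int(fields[2], "rs number", path, line_no)
                        if old == new:
                            raise IngestError("merge maps an rs to itself", path, line_no)
                        cur.execute(
                            "INSERT OR REPLACE INTO rs_merge (old_rs, new_rs) VALUES (?, ?)",
                            (old, new),
                        )
                    else:
                        raise IngestError(f"unknown record tag {tag!r}", path, line_no)
                except IngestError:
                    raise
                except KnowledgeError as exc:
                    raise IngestError(str(exc), path, line_no)

        # deferred referential checks, so record order never matters
        for group_id, source, line_no in pending_groups:
            if cur.execute(
                "SELECT 1 FROM source WHERE name = ?", (source,)
            ).fetchone() is None:
                raise IngestError(f"group {group_id!r} references unknown source {source!r}")
        for group_id, ident_key, path_s, line_no in pending_members:
            if cur.execute(
                "SELECT 1 FROM grp WHERE group_id = ?", (group_id,)
            ).fetchone() is None:
                raise IngestError(
                    f"member references unknown group {group_id!r}", path_s, line_no
                )
            cur.execute(
                "INSERT OR IGNORE INTO member (group_id, ident_key) VALUES (?, ?)",
                (group_id, ident_key),
            )
        for name, id_type, gid, path_s, line_no in pending_aliases:
            if cur.execute("SELECT 1 FROM gene WHERE gene_id = ?", (gid,)).fetchone() is None:
                raise IngestError(
                    f"alias {name!r} targets unknown gene {gid!r}", path_s, line_no
                )
            cur.execute(
                "INSERT OR IGNORE INTO alias (name, id_type, gene_id) VALUES (?, ?, ?)",
                (name, id_type, gid),
            )

        self._validate_merges()

        if build_label:
            self._set_meta("build", build_label)
        elif file_build is not None and not self._meta("build"):
            self._set_meta("build", file_build)
        self._conn.commit()
        self._caches.clear()
        return self

    def _validate_merges(self) -> None:
        merges = dict(self._conn.execute("SELECT old_rs, new_rs FROM rs_merge"))
        for start in merges:
            seen = {start}
            node = start
            while node in merges:
                node = merges[node]
                if node in seen:
                    raise IngestError(f"rs-merge cycle involving rs{start}")
                seen.add(node)

    # -- queries -----------------------------------------------------------

    def _cache(self, key, builder):
        if key not in self._caches:
            self._caches[key] = builder()
        return self._caches[key]

    def current_rs(self, rs: int) -> int:
        """Follow the rs-merge chain from ``rs`` to its current terminus.

        An rs number with no merge record (including one entirely unknown to
        the store) maps to itself, so unmatched input can still be reported
        downstream rather than aborting a run.
        """
        merges = self._cache(
            "merges", lambda: dict(self._conn.execute("SELECT old_rs, new_rs FROM rs_merge"))
        )
        while rs in merges:
            rs = merges[rs]
        return rs

    def genes_by_name(self, name: str, id_type: str | None = None) -> frozenset[str]:
        """Exact-match alias lookup; empty set when the name is unknown."""
        if id_type is None:
            rows = self._conn.execute(
                "SELECT gene_id FROM alias WHERE name = ?", (name,)
            )
        else:
            rows = self._conn.execute(
                "SELECT gene_id FROM alias WHERE name = ? AND id_type = ?",
                (name, id_type),
            )
        return frozenset(r[0] for r in rows)

    def snp_loci(self, rs: int) -> list[tuple[str, int]]:
        """Loci of a SNP, after merge normalization, in (chrom, pos) order."""
        rs = self.current_rs(rs)
        rows = self._conn.execute(
            "SELECT chrom, pos FROM snp_locus WHERE rs = ?", (rs,)
        ).fetchall()
        return sorted(((c, p) for c, p in rows), key=lambda cp: (chromosome_key(cp[0]), cp[1]))

    def groups_by_name(self, name: str) -> frozenset[str]:
        rows = self._conn.execute(
            "SELECT group_id FROM group_name WHERE name = ?", (name,)
        )
        return frozenset(r[0] for r in rows)

    def sources(self) -> frozenset[str]:
        return frozenset(r[0] for r in self._conn.execute("SELECT name FROM source"))

    def group_ids(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT group_id FROM grp ORDER BY group_id")]

    def group_source(self, group_id: str) -> str:
        row = self._conn.execute(
            "SELECT source FROM grp WHERE group_id = ?", (group_id,)
        ).fetchone()
        if row is None:
            raise QueryError(f"unknown group {group_id!r}")
        return row[0]

    def group_names(self, group_id: str) -> frozenset[str]:
        return frozenset(
            r[0]
            for r in self._conn.execute(
                "SELECT name FROM group_name WHERE group_id = ?", (group_id,)
            )
        )

    def group_members(self, group_id: str) -> list[GroupMember]:
        rows = self._conn.execute(
            "SELECT ident_key FROM member WHERE group_id = ? ORDER BY ident_key",
            (group_id,),
        )
        return [GroupMember.from_ident_key(group_id, r[0]) for r in rows]

    def gene_ids(self) -> frozenset[str]:
        return frozenset(r[0] for r in self._conn.execute("SELECT gene_id FROM gene"))

    def gene(self, gene_id: str) -> Gene:
        row = self._conn.execute(
            "SELECT symbol FROM gene WHERE gene_id = ?", (gene_id,)
        ).fetchone()
        if row is None:
            raise QueryError(f"unknown gene {gene_id!r}")
        return Gene(gene_id, row[0], tuple(self.gene_regions(gene_id)))

    def gene_regions(self, gene_id: str) -> list[tuple[str, int, int]]:
        rows = self._conn.execute(
            "SELECT chrom, start, end FROM gene_region WHERE gene_id = ?", (gene_id,)
        ).fetchall()
        return sorted(rows, key=lambda r: (chromosome_key(r[0]), r[1], r[2]))

    def all_regions(self) -> list[tuple[str, int, int, str]]:
        rows = self._conn.execute(
            "SELECT chrom, start, end, gene_id FROM gene_region"
        ).fetchall()
        return sorted(rows, key=lambda r: (chromosome_key(r[0]), r[1], r[2], r[3]))

    def snp_ids(self) -> frozenset[int]:
        """Distinct current rs numbers that have at least one recorded locus."""
        return frozenset(r[0] for r in self._conn.execute("SELECT DISTINCT rs FROM snp_locus"))

    def all_loci(self) -> list[tuple[int, str, int]]:
        rows = self._conn.execute("SELECT rs, chrom, pos FROM snp_locus").fetchall()
        return sorted(rows, key=lambda r: (r[0], chromosome_key(r[1]), r[2]))

    def chromosomes(self) -> frozenset[str]:
        chroms = {r[0] for r in self._conn.execute("SELECT DISTINCT chrom FROM gene_region")}
        chroms |= {r[0] for r in self._conn.execute("SELECT DISTINCT chrom FROM snp_locus")}
        return frozenset(chroms)

    def counts(self) -> dict[str, int]:
        """Entity tallies: sources, groups, genes, snps, chromosomes."""
        one = lambda q: self._conn.execute(q).fetchone()[0]
        return {
            "sources": one("SELECT COUNT(*) FROM source"),
            "groups": one("SELECT COUNT(*) FROM grp"),
            "genes": one("SELECT COUNT(*) FROM gene"),
            "snps": one("SELECT COUNT(DISTINCT rs) FROM snp_locus"),
            "chromosomes": len(self.chromosomes()),
        }

    def region_index(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees over gene regions (closed intervals).

        Tree intervals use half-open ``[start, end + 1)`` coordinates with the
        gene id as payload; the index is cached and rebuilt after mutation.
        """

        def build():
            trees: dict[str, IntervalTree] = {}
            for chrom, start, end, gene_id in self.all_regions():
                trees.setdefault(chrom, IntervalTree())[start : end + 1] = gene_id
            return trees

        return self._cache("region_index", build)


# -- module-level conveniences (the operation surface) -----------------------


def ingest_knowledge(
    definition_paths: Sequence[str | os.PathLike],
    build_label: str | None = None,
    db_path: str | os.PathLike | None = None,
) -> KnowledgeStore:
    """Build a new store from knowledge-definition files.

    With ``db_path`` None the store lives in memory; otherwise it is persisted
    to a new single file at that path.
    """
    store = KnowledgeStore.create(db_path)
    store.add_definitions(definition_paths, build_label)
    return store


def finalize_store(store: KnowledgeStore) -> KnowledgeStore:
    return store.finalize()


def report_genome_build(store: KnowledgeStore) -> str:
    return store.genome_build


# -- parsing helpers ---------------------------------------------------------

_REGION_RE = re.compile(r"^\s*(\S+)\s+(\d+)\s+(\d+)\s*$")


def _expect(fields: list[str], n: int, path, line_no: int) -> None:
    if len(fields) != n:
        raise IngestError(
            f"expected {n} tab-separated fields for {fields[0]!r}, got {len(fields)}",
            path,
            line_no,
        )


def _parse_int(token: str, what: str, path, line_no: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise IngestError(f"invalid {what} {token!r}", path, line_no)


def _parse_member(group_id: str, spec: str, path, line_no: int) -> GroupMember:
    pairs = set()
    for token in spec.split(","):
        name, sep, id_type = token.rpartition(":")
        if not sep or not name or id_type not in ID_TYPES:
            raise IngestError(f"invalid member identifier {token!r}", path, line_no)
        pairs.add((name, id_type))
    return GroupMember(group_id, frozenset(pairs))


def _parse_regions(spec: str, path, line_no: int) -> list[tuple[str, int, int]]:
    regions = []
    for part in spec.split(";"):
        m = _REGION_RE.match(part)
        if not m:
            raise IngestError(f"invalid region spec {part!r}", path, line_no)
        chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        if start > end or start < 1:
            raise IngestError(f"invalid region bounds {part!r}", path, line_no)
        regions.append((chrom, start, end))
    return regions
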