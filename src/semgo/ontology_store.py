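"""Parse OBO 1.2 ontologies and decompose them into normalized subontology tables.

The Gene Ontology ships as a flat text file of ``[Term]`` stanzas, each
carrying an accession id, a canonical name, a namespace (one of the three GO
subontologies), synonyms with a scope qualifier, and typed relations to other
terms.  This module extracts exactly the attributes the retrieval pipeline
needs and stores them in a small relational layout:

* one table per subontology — ``component`` (CID, CName), ``function``
  (FID, FName), ``process`` (PID, PName);
* a shared ``synonym`` table (SID, GID, SName, SType) and a shared
  ``relation`` table (RID, GID, ParentID, ParentName, RType), both keyed to
  the owning term by its accession (GID).

The store is backed by sqlite3 and works identically in memory
(``":memory:"``) or as a single artifact file on disk.
"""

from __future__ import annotations

import io
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The three GO namespaces (subontologies).
NAMESPACES = ("cellular_component", "molecular_function", "biological_process")

#: Short codes used in the annotated index and in frequency vectors.
NS_SHORT = {
    "cellular_component": "cc",
    "molecular_function": "mf",
    "biological_process": "bp",
}
SHORT_NS = {v: k for k, v in NS_SHORT.items()}

#: Human-readable subontology labels, as printed in term metadata blocks.
NS_LABEL = {
    "cellular_component": "Component",
    "molecular_function": "Function",
    "biological_process": "Process",
}

#: Closed vocabulary of synonym scopes.  "RELATD" (a typo seen in the wild)
#: is normalized to RELATED on ingest.
SYNONYM_SCOPES = ("EXACT", "NARROW", "BROAD", "RELATED")

#: Closed vocabulary of relation types.  positively_/negatively_regulates
#: are folded into regulates on ingest.
RELATION_TYPES = ("is_a", "part_of", "has_part", "regulates")

_SCOPE_ALIASES = {"RELATD": "RELATED"}
_REL_ALIASES = {
    "positively_regulates": "regulates",
    "negatively_regulates": "regulates",
}

_NS_TABLE = {
    "cellular_component": ("component", "CID", "CName"),
    "molecular_function": ("function", "FID", "FName"),
    "biological_process": ("process", "PID", "PName"),
}


class OboFormatError(ValueError):
    """Input does not look like an OBO 1.2 flat file."""


class OboStanzaError(ValueError):
    """One or more [Term] stanzas are malformed (missing id or namespace)."""

    def __init__(self, stanzas: Sequence[str]):
        self.stanzas = list(stanzas)
        preview = "\n---\n".join(s.strip() for s in self.stanzas)
        super().__init__(
            f"{len(self.stanzas)} malformed [Term] stanza(s):\n{preview}"
        )


class DuplicateTermError(ValueError):
    """The same term accession appears more than once."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"duplicate term id: {term_id}")


@dataclass(frozen=True)
class Synonym:
    surface: str
    scope: str  # EXACT | NARROW | BROAD | RELATED


@dataclass(frozen=True)
class Relation:
    target_id: str
    target_name: str
    rel_type: str  # is_a | part_of | has_part | regulates


@dataclass
class OntTerm:
    """One parsed [Term] stanza, reduced to the attributes the pipeline uses."""

    term_id: str
    name: str
    namespace: str
    synonyms: list[Synonym] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    obsolete: bool = False


@dataclass
class TermRecord:
    """Full metadata block for one stored term, as returned by lookups."""

    term_id: str
    name: str
    namespace: str
    synonyms: list[Synonym]
    relations: list[Relation]

    @property
    def type_label(self) -> str:
        return NS_LABEL[self.namespace]


_SYN_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"\s+(?P<scope>[A-Za-z_]+)')
_REL_RE = re.compile(
    r"^(?P<type>\S+)\s+(?P<target>\S+)\s*(?:!\s*(?P<name>.*\S))?\s*$"
)
_ISA_RE = re.compile(r"^(?P<target>\S+)\s*(?:!\s*(?P<name>.*\S))?\s*$")


def _parse_stanza(lines: list[str]) -> OntTerm | None:
    """Parse the tag/value lines of one [Term] stanza.

    Returns None when the stanza lacks an id or a valid namespace (the
    caller collects those for a record-level error).
    """
    term_id = name = namespace = None
    obsolete = False
    synonyms: list[Synonym] = []
    relations: list[Relation] = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            term_id = value
        elif tag == "name":
            name = value
        elif tag == "namespace":
            namespace = value
        elif tag == "is_obsolete":
            obsolete = value.lower() == "true"
        elif tag == "synonym":
            m = _SYN_RE.match(value)
            if not m:
                logger.warning("unparseable synonym line dropped: %r", line)
                continue
            scope = m.group("scope").upper()
            scope = _SCOPE_ALIASES.get(scope, scope)
            if scope not in SYNONYM_SCOPES:
                logger.warning("synonym scope %r not in closed set; dropped", scope)
                continue
            synonyms.append(Synonym(m.group("text").replace('\\"', '"'), scope))
        elif tag == "is_a":
            m = _ISA_RE.match(value)
            if m:
                relations.append(
                    Relation(m.group("target"), m.group("name") or "", "is_a")
                )
        elif tag == "relationship":
            m = _REL_RE.match(value)
            if not m:
                logger.warning("unparseable relationship line dropped: %r", line)
                continue
            rtype = _REL_ALIASES.get(m.group("type"), m.group("type"))
            if rtype != m.group("type"):
                logger.info("relation type %r folded into %r", m.group("type"), rtype)
            if rtype not in RELATION_TYPES:
                logger.warning("relation type %r not in closed set; dropped", rtype)
                continue
            relations.append(
                Relation(m.group("target"), m.group("name") or "", rtype)
            )
        # every other tag (def, xref, subset, comment, ...) is discarded
    if term_id is None or namespace not in NAMESPACES:
        return None
    return OntTerm(
        term_id=term_id,
        name=name or "",
        namespace=namespace,
        synonyms=synonyms,
        relations=relations,
        obsolete=obsolete,
    )


def parse_obo(stream: str | io.TextIOBase | Path) -> list[OntTerm]:
    """Parse OBO 1.2 text into a list of :class:`OntTerm`.

    ``stream`` may be the OBO text itself, an open text stream, or a path.
    Only the attributes the pipeline needs are kept; everything else in a
    stanza is discarded.  Obsolete stanzas are returned with
    ``obsolete=True`` so callers can decide what to do with them.

    Raises :class:`OboFormatError` for input with no OBO structure at all and
    :class:`OboStanzaError` listing every stanza missing an id or namespace.
    Relation targets defined elsewhere in the same file have their names
    resolved even when the ``! name`` comment is absent.
    """
    if isinstance(stream, Path):
        text = stream.read_text(encoding="utf-8")
    elif isinstance(stream, str):
        text = stream
    else:
        text = stream.read()

    lines = text.splitlines()
    if not any(ln.strip() for ln in lines):
        return []
    has_header = any(
        ln.split(":")[0].strip() in ("format-version", "ontology", "data-version")
        for ln in lines[:50]
        if ":" in ln
    )
    has_term = any(ln.strip() == "[Term]" for ln in lines)
    if not has_header and not has_term:
        raise OboFormatError("input has no OBO header and no [Term] stanza")

    terms: list[OntTerm] = []
    bad: list[str] = []
    stanza: list[str] | None = None
    in_term = False

    def _flush() -> None:
        nonlocal stanza
        if stanza is not None and in_term:
            parsed = _parse_stanza(stanza)
            if parsed is None:
                bad.append("\n".join(stanza))
            else:
                terms.append(parsed)
        stanza = None

    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            _flush()
            in_term = stripped == "[Term]"
            stanza = [] if in_term else None
        elif stanza is not None:
            stanza.append(ln)
    _flush()

    if bad:
        raise OboStanzaError(bad)

    # second pass: fill in relation-target names from sibling stanzas
    names = {t.term_id: t.name for t in terms}
    for t in terms:
        t.relations = [
            Relation(r.target_id, r.target_name or names.get(r.target_id, ""), r.rel_type)
            for r in t.relations
        ]
    return terms


_SCHEMA = """
CREATE TABLE IF NOT EXISTS component (CID TEXT PRIMARY KEY, CName TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS function  (FID TEXT PRIMARY KEY, FName TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS process   (PID TEXT PRIMARY KEY, PName TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS relation (
    RID INTEGER PRIMARY KEY AUTOINCREMENT,
    GID TEXT NOT NULL, ParentID TEXT NOT NULL,
    ParentName TEXT NOT NULL, RType TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS synonym (
    SID INTEGER PRIMARY KEY AUTOINCREMENT,
    GID TEXT NOT NULL, SName TEXT NOT NULL, SType TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS paper (
    PaperID TEXT PRIMARY KEY, PaperTitle TEXT DEFAULT '', PaperAuthor TEXT DEFAULT '');
CREATE TABLE IF NOT EXISTS term (
    PaperID TEXT NOT NULL, TermName TEXT NOT NULL,
    TermType TEXT NOT NULL, TermFreq INTEGER NOT NULL,
    PRIMARY KEY (PaperID, TermName));
CREATE INDEX IF NOT EXISTS idx_syn_gid ON synonym (GID);
CREATE INDEX IF NOT EXISTS idx_rel_gid ON relation (GID);
CREATE INDEX IF NOT EXISTS idx_term_name ON term (TermName);
"""

SUBONTOLOGY_TABLES = ("component", "function", "process")
TABLE_COLUMNS = {
    "component": ("CID", "CName"),
    "function": ("FID", "FName"),
    "process": ("PID", "PName"),
    "relation": ("RID", "GID", "ParentID", "ParentName", "RType"),
    "synonym": ("SID", "GID", "SName", "SType"),
    "paper": ("PaperID", "PaperTitle", "PaperAuthor"),
    "term": ("PaperID", "TermName", "TermType", "TermFreq"),
}


class NormalizedStore:
    """Relational store holding the three subontology tables plus the shared
    synonym/relation tables, and (after indexing) the annotated-index tables.

    One sqlite file, or ``":memory:"``; both paths run the same code and
    produce identical query results.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- building -----------------------------------------------------------

    def add_terms(self, terms: Iterable[OntTerm]) -> None:
        """Route non-obsolete terms into their subontology table; store their
        synonyms and relations in the shared tables.  Obsolete terms are
        skipped entirely (indexing obsolete names would pollute annotation).
        """
        cur = self.conn.cursor()
        seen: set[str] = {
            row[0]
            for tbl, (idc, _) in _nsid_cols()
            for row in cur.execute(f"SELECT {idc} FROM {tbl}")
        }
        for t in terms:
            if t.term_id in seen:
                raise DuplicateTermError(t.term_id)
            seen.add(t.term_id)
            if t.obsolete:
                logger.debug("skipping obsolete term %s (%s)", t.term_id, t.name)
                continue
            table, id_col, name_col = _NS_TABLE[t.namespace]
            cur.execute(
                f"INSERT INTO {table} ({id_col}, {name_col}) VALUES (?, ?)",
                (t.term_id, t.name),
            )
            for s in t.synonyms:
                cur.execute(
                    "INSERT INTO synonym (GID, SName, SType) VALUES (?, ?, ?)",
                    (t.term_id, s.surface, s.scope),
                )
            for r in t.relations:
                cur.execute(
                    "INSERT INTO relation (GID, ParentID, ParentName, RType)"
                    " VALUES (?, ?, ?, ?)",
                    (t.term_id, r.target_id, r.target_name, r.rel_type),
                )
        self.conn.commit()

    # -- queries ------------------------------------------------------------

    def counts(self) -> dict[str, int]:
        cur = self.conn.cursor()
        return {
            tbl: cur.execute(f"SELECT COUNT(*) FROM {tbl}").fetchone()[0]
            for tbl in TABLE_COLUMNS
        }

    def synonyms_of(self, gid: str) -> list[Synonym]:
        rows = self.conn.execute(
            "SELECT SName, SType FROM synonym WHERE GID = ? ORDER BY SID", (gid,)
        ).fetchall()
        return [Synonym(n, s) for n, s in rows]

    def relations_of(self, gid: str) -> list[Relation]:
        rows = self.conn.execute(
            "SELECT ParentID, ParentName, RType FROM relation WHERE GID = ?"
            " ORDER BY RID",
            (gid,),
        ).fetchall()
        return [Relation(pid, pname, rtype) for pid, pname, rtype in rows]

    def _record(self, term_id: str, name: str, namespace: str) -> TermRecord:
        return TermRecord(
            term_id=term_id,
            name=name,
            namespace=namespace,
            synonyms=self.synonyms_of(term_id),
            relations=self.relations_of(term_id),
        )

    def resolve(self, name_or_id: str, namespace: str | None = None) -> list[TermRecord]:
        """Match a term by case-insensitive name or exact accession id.

        Restricted to one subontology when ``namespace`` is given; ambiguous
        names return every match.
        """
        spaces = [namespace] if namespace else list(NAMESPACES)
        out: list[TermRecord] = []
        for ns in spaces:
            table, id_col, name_col = _NS_TABLE[ns]
            rows = self.conn.execute(
                f"SELECT {id_col}, {name_col} FROM {table}"
                f" WHERE {id_col} = ? OR lower({name_col}) = lower(?)"
                f" ORDER BY {id_col}",
                (name_or_id, name_or_id),
            ).fetchall()
            out.extend(self._record(tid, nm, ns) for tid, nm in rows)
        return out

    def lookup_term(self, name_or_id: str) -> list[TermRecord]:
        """Full metadata for a term by name or id, across all subontologies.

        Returns an empty list (not an error) when nothing matches; a name
        that is ambiguous across namespaces returns all matches.
        """
        return self.resolve(name_or_id)

    def vocabulary(self) -> dict[str, tuple[str, str]]:
        """All matchable surface strings, lowercased.

        Returns ``{surface: (owner_term_id, namespace)}`` over canonical
        names and synonym surfaces.  A string serving several concepts keeps
        a single entry (one count in the index): the canonical-name owner
        wins over a synonym owner, then the smallest accession, so the
        mapping is deterministic.
        """
        vocab: dict[str, tuple[str, str, bool]] = {}

        def _offer(surface: str, gid: str, ns: str, is_name: bool) -> None:
            key = surface.lower().strip()
            if not key:
                return
            cur = vocab.get(key)
            if (
                cur is None
                or (is_name and not cur[2])
                or (is_name == cur[2] and gid < cur[0])
            ):
                vocab[key] = (gid, ns, is_name)

        gid_ns: dict[str, str] = {}
        for ns in NAMESPACES:
            table, id_col, name_col = _NS_TABLE[ns]
            for tid, nm in self.conn.execute(
                f"SELECT {id_col}, {name_col} FROM {table}"
            ):
                gid_ns[tid] = ns
                _offer(nm, tid, ns, True)
        for gid, sname in self.conn.execute("SELECT GID, SName FROM synonym"):
            _offer(sname, gid, gid_ns[gid], False)
        return {k: (gid, ns) for k, (gid, ns, _) in sorted(vocab.items())}

    def all_term_ids(self) -> dict[str, str]:
        """Mapping term_id -> namespace over the three subontology tables."""
        out: dict[str, str] = {}
        for ns in NAMESPACES:
            table, id_col, _ = _NS_TABLE[ns]
            for (tid,) in self.conn.execute(f"SELECT {id_col} FROM {table}"):
                out[tid] = ns
        return out

    # -- dumps --------------------------------------------------------------

    def dump_tsv(self, outdir: str | Path, tables: Sequence[str] | None = None) -> list[Path]:
        """Write one TSV per table (columns exactly as stored) for inspection."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for tbl in tables or TABLE_COLUMNS:
            cols = TABLE_COLUMNS[tbl]
            rows = self.conn.execute(
                f"SELECT {', '.join(cols)} FROM {tbl} ORDER BY {cols[0]}, {cols[1]}"
            ).fetchall()
            path = outdir / f"{tbl}.tsv"
            with path.open("w", encoding="utf-8", newline="") as fh:
                fh.write("\t".join(cols) + "\n")
                for row in rows:
                    fh.write("\t".join(str(v) for v in row) + "\n")
            written.append(path)
        return written


def _nsid_cols():
    for ns in NAMESPACES:
        table, id_col, name_col = _NS_TABLE[ns]
        yield table, (id_col, name_col)


def decompose(terms: Sequence[OntTerm], path: str | Path = ":memory:") -> NormalizedStore:
    """Decompose parsed terms into a :class:`NormalizedStore`.

    Non-obsolete terms are routed by namespace into the component/function/
    process tables; every synonym and relation goes to the shared tables
    keyed by the owning term's accession.  Duplicate accessions raise
    :class:`DuplicateTermError`.
    """
    ids = [t.term_id for t in terms]
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise DuplicateTermError(i)
            seen.add(i)
    store = NormalizedStore(path)
    store.add_terms(terms)
    return store


def lookup_term(store: NormalizedStore, name_or_id: str) -> list[TermRecord]:
    """Module-level convenience wrapper over :meth:`NormalizedStore.lookup_term`."""
    return store.lookup_term(name_or_id)
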