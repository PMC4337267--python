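"""Expand asserted subontology terms with their synonyms and relation targets.

A query asserts up to three terms, one per GO subontology (cellular
component, molecular function, biological process).  Expansion is depth-1:
for each asserted term it collects the canonical name, every stored synonym
with its scope, and every direct relation target name with its type.  Each
inferred string later becomes its own search probe against the annotated
index — e.g. asserting the process "brain development" also probes "organ
development" (its is_a parent) and "central nervous system development"
(which it is part_of).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ontology_store import (
    NAMESPACES,
    NS_SHORT,
    SHORT_NS,
    NormalizedStore,
    Relation,
    Synonym,
    TermRecord,
)


class TermNotFoundError(KeyError):
    """Asserted name does not resolve in its stated subontology."""

    def __init__(self, name: str, namespace: str, found_in: str | None = None):
        self.name = name
        self.namespace = namespace
        self.found_in = found_in
        msg = f"term {name!r} not found in subontology {namespace!r}"
        if found_in:
            msg += f"; it exists in {found_in!r} — assert it there instead"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


@dataclass(frozen=True)
class AssertedQuery:
    """Up to three asserted term names (or ids), one per subontology."""

    cc: str | None = None
    mf: str | None = None
    bp: str | None = None

    def __post_init__(self):
        if self.cc is None and self.mf is None and self.bp is None:
            raise ValueError("at least one of cc/mf/bp must be asserted")

    def items(self) -> list[tuple[str, str]]:
        """(short-code, asserted name) pairs for the present slots."""
        return [
            (code, name)
            for code, name in (("cc", self.cc), ("mf", self.mf), ("bp", self.bp))
            if name is not None
        ]


@dataclass
class TermExpansion:
    """One asserted term with its depth-1 inferred strings."""

    term_id: str
    name: str
    namespace: str
    synonyms: list[Synonym] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)


@dataclass
class ExpandedQuery:
    cc: TermExpansion | None = None
    mf: TermExpansion | None = None
    bp: TermExpansion | None = None

    def items(self) -> list[tuple[str, TermExpansion]]:
        return [
            (code, exp)
            for code, exp in (("cc", self.cc), ("mf", self.mf), ("bp", self.bp))
            if exp is not None
        ]


def _dedupe_synonyms(syns: list[Synonym]) -> list[Synonym]:
    seen: set[tuple[str, str]] = set()
    out = []
    for s in syns:
        key = (s.surface.lower(), s.scope)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def _dedupe_relations(rels: list[Relation]) -> list[Relation]:
    seen: set[tuple[str, str]] = set()
    out = []
    for r in rels:
        key = (r.target_name.lower(), r.rel_type)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def resolve_asserted(
    store: NormalizedStore, name: str, subontology: str
) -> TermRecord:
    """Resolve an asserted name (or id) inside one subontology.

    Raises :class:`TermNotFoundError`; when the name lives in a different
    subontology the error says which one, so the caller can re-assert it
    under the right slot.
    """
    namespace = SHORT_NS.get(subontology, subontology)
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown subontology {subontology!r}")
    matches = store.resolve(name, namespace)
    if matches:
        return matches[0]
    elsewhere = store.resolve(name)
    found_in = NS_SHORT[elsewhere[0].namespace] if elsewhere else None
    raise TermNotFoundError(name, NS_SHORT[namespace], found_in)


def expand(store: NormalizedStore, query: AssertedQuery) -> ExpandedQuery:
    """Build the :class:`ExpandedQuery` for up to three asserted terms.

    For each asserted term the expansion holds the canonical name, all
    stored synonyms with scope, and all direct relation targets with type
    (all four stored relation types; duplicates within a list removed).
    A string reachable both as a synonym and as a relation target stays in
    both lists — the two roles carry different ranking weights.
    Expansion is idempotent: it reads the store only.
    """
    out = ExpandedQuery()
    for code, name in query.items():
        rec = resolve_asserted(store, name, code)
        exp = TermExpansion(
            term_id=rec.term_id,
            name=rec.name,
            namespace=rec.namespace,
            synonyms=_dedupe_synonyms(rec.synonyms),
            relations=_dedupe_relations(rec.relations),
        )
        setattr(out, code, exp)
    return out


def format_metadata_block(exp: TermExpansion) -> str:
    """Render one asserted term's metadata the way the search tool prints it.

    Example::

        Term Name: binding
        ID: GO:0005488
        Type: Function
        Relations: molecular_function (is_a)
        Synonyms: ligand (NARROW)
    """
    from .ontology_store import NS_LABEL

    rels = "; ".join(f"{r.target_name} ({r.rel_type})" for r in exp.relations)
    syns = "; ".join(f"{s.surface} ({s.scope})" for s in exp.synonyms)
    return "\n".join(
        [
            f"Term Name: {exp.name}",
            f"ID: {exp.term_id}",
            f"Type: {NS_LABEL[exp.namespace]}",
            f"Relations: {rels or '-'}",
            f"Synonyms: {syns or '-'}",
        ]
    )
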