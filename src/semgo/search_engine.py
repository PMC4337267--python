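"""Probe the annotated index, union the hits, and build frequency vectors.

Every asserted term contributes one *term* probe, one *synonym* probe per
synonym surface, and one *relation* probe per relation target — each probe
tagged with the subontology of the asserted term that induced it (a relation
target may name a term, or a root, of another namespace; the grouping stays
with the asserted side).  Hits are unioned into a set of unique documents,
and each document is rearranged into the metadata structure

    [T_cc, T_mf, T_bp, R_cc, R_mf, R_bp, S_cc, S_mf, S_bp]

where the T slots are plain frequencies and the R/S slots are lists of
(relation-type, frequency) and (synonym-scope, frequency) pairs, one entry
per distinct inferred surface string found in the document.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotator import AnnotatedIndex
from .query_expansion import ExpandedQuery

SUBONTOLOGY_CODES = ("cc", "mf", "bp")
PROBE_ROLES = ("term", "synonym", "relation")


@dataclass(frozen=True)
class Probe:
    """One index lookup: a surface string with its query role."""

    surface: str  # lowercase surface string searched in the index
    role: str  # term | synonym | relation
    subontology: str  # cc | mf | bp — of the ASSERTED term that induced it
    kind: str | None = None  # synonym scope or relation type; None for terms


#: HitTable: probe -> {paper_id: frequency}
HitTable = dict[Probe, dict[str, int]]


def build_probes(query: ExpandedQuery) -> list[Probe]:
    """Flatten an expanded query into its ordered list of probes."""
    probes: list[Probe] = []
    for code, exp in query.items():
        probes.append(Probe(exp.name.lower(), "term", code))
        for s in exp.synonyms:
            probes.append(Probe(s.surface.lower(), "synonym", code, s.scope))
        for r in exp.relations:
            probes.append(Probe(r.target_name.lower(), "relation", code, r.rel_type))
    return probes


def search_index(index: AnnotatedIndex, query: ExpandedQuery) -> HitTable:
    """Look every probe up in the annotated index.

    Probes with no hits map to an empty dict (kept, so the hit summary can
    report zero classes the way the result tables do).
    """
    return {p: index.lookup(p.surface) for p in build_probes(query)}


def union_documents(hits: HitTable) -> set[str]:
    """Unique documents over all probes — the redundancy-eliminating union."""
    docs: set[str] = set()
    for hit in hits.values():
        docs.update(hit)
    return docs


@dataclass
class FrequencyVector:
    """Per-document frequencies arranged by slot: terms, relations, synonyms."""

    t_cc: int = 0
    t_mf: int = 0
    t_bp: int = 0
    r_cc: list[tuple[str, int]] = field(default_factory=list)
    r_mf: list[tuple[str, int]] = field(default_factory=list)
    r_bp: list[tuple[str, int]] = field(default_factory=list)
    s_cc: list[tuple[str, int]] = field(default_factory=list)
    s_mf: list[tuple[str, int]] = field(default_factory=list)
    s_bp: list[tuple[str, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "t_cc": self.t_cc,
            "t_mf": self.t_mf,
            "t_bp": self.t_bp,
            "r_cc": list(self.r_cc),
            "r_mf": list(self.r_mf),
            "r_bp": list(self.r_bp),
            "s_cc": list(self.s_cc),
            "s_mf": list(self.s_mf),
            "s_bp": list(self.s_bp),
        }


@dataclass
class ResultRecord:
    paper_id: str
    vector: FrequencyVector


def rearrange(hits: HitTable, docs: set[str]) -> list[ResultRecord]:
    """One :class:`ResultRecord` per document, frequencies placed by slot.

    Probe order (hence list-entry order inside R/S slots) follows the
    expansion; records are returned in paper_id order.  A document carrying
    no hits at all (possible only if ``docs`` was widened manually) gets an
    all-zero vector.
    """
    records = {pid: ResultRecord(pid, FrequencyVector()) for pid in sorted(docs)}
    for probe, hit in hits.items():
        for pid, freq in hit.items():
            if pid not in records:
                continue
            vec = records[pid].vector
            if probe.role == "term":
                setattr(vec, f"t_{probe.subontology}", freq)
            elif probe.role == "synonym":
                getattr(vec, f"s_{probe.subontology}").append((probe.kind, freq))
            else:
                getattr(vec, f"r_{probe.subontology}").append((probe.kind, freq))
    return list(records.values())


def summarize_hits(hits: HitTable) -> dict:
    """Hit summary in the shape of the per-class result tables.

    For each subontology and probe class reports both the number of distinct
    documents and the summed occurrence count (the printed tables are
    ambiguous about which is meant, so both views are kept), plus the union
    size.
    """
    summary = {
        code: {
            role: {"documents": 0, "occurrences": 0}
            for role in ("terms", "relations", "synonyms")
        }
        for code in SUBONTOLOGY_CODES
    }
    per_class_docs: dict[tuple[str, str], set[str]] = {}
    for probe, hit in hits.items():
        role = {"term": "terms", "synonym": "synonyms", "relation": "relations"}[
            probe.role
        ]
        key = (probe.subontology, role)
        per_class_docs.setdefault(key, set()).update(hit)
        summary[probe.subontology][role]["occurrences"] += sum(hit.values())
    for (code, role), docset in per_class_docs.items():
        summary[code][role]["documents"] = len(docset)
    summary["union"] = len(union_documents(hits))
    return summary
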