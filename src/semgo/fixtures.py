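"""Synthetic ontology and corpus generators with known ground truth.

The fixture ontology is a valid OBO 1.2 file containing a hand-coded set of
real GO concept records — binding, chromosome, nucleus, alkaline phosphatase
activity, host, growth, and the brain development / organ development /
central nervous system development triple, each with its published synonyms
and relations — plus any number of synthetic filler terms spread across the
three namespaces.  Filler names are built from an invented word list so they
can never collide with the hand-coded vocabulary.

The fixture corpus is generated from a :class:`PlantingPlan`: each document
contains each planted vocabulary string exactly its planned number of times,
boundary-delimited, embedded in filler text drawn from a fixed
non-biological word list that shares no word with any vocabulary string.
Planted tokens are always separated by at least one filler word, so no
vocabulary phrase can form across token boundaries, and the annotator's
output over the corpus equals the plan exactly.

Two sources of ambiguity are rejected up front rather than accounted for:
a planted string that (boundary-delimited) contains another planted string
of the same document, and — when the full vocabulary is supplied — a
planted string that contains *any* other vocabulary string (e.g. ``cell
nucleus`` contains ``nucleus``; the nested occurrence would be counted
independently and the plan would no longer be the truth).  Fixtures exist
for correctness, not realism: no attempt is made to imitate real
biomedical prose.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .annotator import Document, match_occurrences

# -- hand-coded concept records ---------------------------------------------
# (term_id, name, namespace, [(synonym, scope)...], [(target_id, target_name,
# rel_type)...])  These reproduce the published GO records used throughout
# the test suite, string for string.
CORE_TERMS: list[tuple] = [
    ("GO:0005575", "cellular_component", "cellular_component", [], []),
    ("GO:0003674", "molecular_function", "molecular_function", [], []),
    ("GO:0008150", "biological_process", "biological_process", [], []),
    (
        "GO:0005488",
        "binding",
        "molecular_function",
        [("ligand", "NARROW")],
        [("GO:0003674", "molecular_function", "is_a")],
    ),
    (
        "GO:0043232",
        "intracellular non-membrane-bounded organelle",
        "cellular_component",
        [],
        [],
    ),
    (
        "GO:0005694",
        "chromosome",
        "cellular_component",
        [
            ("chromatid", "RELATED"),
            ("interphase chromosome", "NARROW"),
            ("prophase chromosome", "NARROW"),
        ],
        [("GO:0043232", "intracellular non-membrane-bounded organelle", "is_a")],
    ),
    (
        "GO:0005634",
        "nucleus",
        "cellular_component",
        [("cell nucleus", "EXACT")],
        [("GO:0043232", "intracellular non-membrane-bounded organelle", "is_a")],
    ),
    ("GO:0016791", "phosphatase activity", "molecular_function", [], []),
    (
        "GO:0004035",
        "alkaline phosphatase activity",
        "molecular_function",
        [
            ("alkaline phenyl phosphatase activity", "EXACT"),
            ("alkaline phosphohydrolase activity", "EXACT"),
            ("alkaline phosphomonoesterase activity", "EXACT"),
            ("glycerophosphatase activity", "BROAD"),
            (
                "orthophosphoric-monoester phosphohydrolase (alkaline optimum)",
                "EXACT",
            ),
            (
                "phosphate-monoester phosphohydrolase (alkaline optimum)",
                "EXACT",
            ),
            ("phosphomonoesterase activity", "BROAD"),
        ],
        [("GO:0016791", "phosphatase activity", "is_a")],
    ),
    ("GO:0044217", "other organisms", "cellular_component", [], []),
    (
        "GO:0018995",
        "host",
        "cellular_component",
        [("host organism", "EXACT")],
        [("GO:0044217", "other organisms", "is_a")],
    ),
    (
        "GO:0040007",
        "growth",
        "biological_process",
        [
            ("growth pattern", "RELATED"),
            ("nondevelopmental growth", "RELATED"),
        ],
        [("GO:0008150", "biological_process", "is_a")],
    ),
    ("GO:0048513", "organ development", "biological_process", [], []),
    (
        "GO:0007417",
        "central nervous system development",
        "biological_process",
        [],
        [],
    ),
    (
        "GO:0007420",
        "brain development",
        "biological_process",
        [],
        [
            ("GO:0048513", "organ development", "is_a"),
            ("GO:0007417", "central nervous system development", "part_of"),
        ],
    ),
]

N_CORE_TERMS = len(CORE_TERMS)

_NAMESPACE_CYCLE = (
    "cellular_component",
    "molecular_function",
    "biological_process",
)

# invented words for filler TERM names/synonyms — never overlap CORE vocab
_TERM_WORDS = (
    "veltro", "quandic", "morvel", "zintra", "plome", "drassic", "fenwick",
    "ostrene", "bilvar", "crunet", "halvic", "tremba", "quolish", "varnex",
    "sploden", "mirkel", "jundra", "povit", "laxern", "wibbel",
)

# invented words for CORPUS filler text — disjoint from _TERM_WORDS and from
# every word of every hand-coded name/synonym, so filler can never produce a
# vocabulary hit, alone or by adjacency
CORPUS_FILLER_WORDS = (
    "lorem", "ipsum", "dolor", "amet", "consectetur", "adipiscing", "elitra",
    "tempor", "incididunt", "labore", "dolore", "magna", "aliqua", "nostrud",
    "ullamco", "laboris", "aliquip", "commodo", "consequat", "voluptate",
    "cupidatat", "proident", "mollit", "excepteur", "deserunt", "officia",
)


class PlanError(ValueError):
    """The planting plan would make planted counts ambiguous or is invalid."""


def _relation_tag(target_id: str, target_name: str, rel_type: str) -> str:
    if rel_type == "is_a":
        return f"is_a: {target_id} ! {target_name}"
    return f"relationship: {rel_type} {target_id} ! {target_name}"


def make_fixture_ontology(
    n_filler: int = 0, seed: int = 0, n_obsolete: int = 0
) -> str:
    """Emit a valid OBO 1.2 file: the hand-coded concepts plus filler terms.

    ``n_filler`` synthetic terms are appended, cycling through the three
    namespaces; the last ``n_obsolete`` of them are flagged obsolete.  With
    ``n_filler=0`` the file holds exactly the hand-coded concept set.
    Deterministic under ``seed``.
    """
    if n_obsolete > n_filler:
        raise ValueError("n_obsolete cannot exceed n_filler")
    rng = random.Random(seed)
    lines = ["format-version: 1.2", "ontology: go-fixture", ""]
    for term_id, name, ns, syns, rels in CORE_TERMS:
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {ns}")
        for surface, scope in syns:
            lines.append(f'synonym: "{surface}" {scope} []')
        for tid, tname, rtype in rels:
            lines.append(_relation_tag(tid, tname, rtype))
        lines.append("")

    filler_ids: list[tuple[str, str]] = []  # (id, namespace)
    scopes = ("EXACT", "NARROW", "BROAD", "RELATED")
    rel_types = ("is_a", "part_of", "has_part", "regulates")
    roots = {
        "cellular_component": ("GO:0005575", "cellular_component"),
        "molecular_function": ("GO:0003674", "molecular_function"),
        "biological_process": ("GO:0008150", "biological_process"),
    }
    names: dict[str, str] = {}
    for i in range(n_filler):
        term_id = f"GO:9{i:06d}"
        ns = _NAMESPACE_CYCLE[i % 3]
        w1, w2 = rng.choice(_TERM_WORDS), rng.choice(_TERM_WORDS)
        name = f"{w1} {w2} {i:03d}"
        names[term_id] = name
        obsolete = i >= n_filler - n_obsolete
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {ns}")
        for k in range(rng.randint(0, 2)):
            w3, w4 = rng.choice(_TERM_WORDS), rng.choice(_TERM_WORDS)
            scope = rng.choice(scopes)
            lines.append(f'synonym: "{w3} {w4} {i:03d}s{k}" {scope} []')
        # link to the namespace root or an earlier filler term of any namespace
        if rng.random() < 0.8:
            if filler_ids and rng.random() < 0.5:
                tid, tns = rng.choice(filler_ids)
                tname = names[tid]
            else:
                tid, tname = roots[ns]
            lines.append(_relation_tag(tid, tname, rng.choice(rel_types)))
        if obsolete:
            lines.append("is_obsolete: true")
        else:
            filler_ids.append((term_id, ns))
        lines.append("")
    return "\n".join(lines)


# -- corpus planting ---------------------------------------------------------


@dataclass
class PlantingPlan:
    """Intended occurrence counts per (document, vocabulary string).

    ``docs`` maps paper_id -> {surface: count}; ``filler_words`` is the
    number of filler tokens per document (raised automatically when a
    document plants more occurrences than that); same seed, same corpus.
    """

    docs: dict[str, dict[str, int]] = field(default_factory=dict)
    filler_words: int = 60
    seed: int = 0

    def truth_entries(self) -> list[tuple[str, str, int]]:
        """(paper_id, surface_lowercase, count) rows with count > 0, sorted."""
        rows = [
            (pid, surface.lower(), count)
            for pid, plants in self.docs.items()
            for surface, count in plants.items()
            if count > 0
        ]
        return sorted(rows)


def _contains(container: str, inner: str) -> bool:
    """True when ``inner`` occurs boundary-delimited inside ``container``."""
    return inner.lower() != container.lower() and match_occurrences(
        container, inner
    ) > 0


def _validate_plan(plan: PlantingPlan, vocabulary: Iterable[str] | None) -> None:
    vocab = None if vocabulary is None else sorted({v.lower() for v in vocabulary})
    for pid, plants in plan.docs.items():
        surfaces = []
        for surface, count in plants.items():
            if not isinstance(count, int) or count < 0:
                raise PlanError(
                    f"{pid}: count for {surface!r} must be a non-negative int"
                )
            if not surface.strip():
                raise PlanError(f"{pid}: empty planted string")
            if count > 0:
                surfaces.append(surface)
        for a in surfaces:
            for b in surfaces:
                if _contains(b, a):
                    raise PlanError(
                        f"{pid}: planted string {a!r} occurs inside planted "
                        f"string {b!r}; counts would be ambiguous"
                    )
            if vocab is not None:
                if a.lower() not in vocab:
                    raise PlanError(
                        f"{pid}: planted string {a!r} is not in the vocabulary"
                    )
                for v in vocab:
                    if _contains(a, v):
                        raise PlanError(
                            f"{pid}: planted string {a!r} contains the "
                            f"vocabulary string {v!r}; counts would be ambiguous"
                        )


def make_fixture_corpus(
    plan: PlantingPlan, vocabulary: Iterable[str] | None = None
) -> list[Document]:
    """Generate the corpus a plan describes.

    Every planted string appears exactly its planned number of times in its
    document, flanked by filler words (never adjacent to another planted
    token).  Passing the store's full ``vocabulary`` enables the stricter
    ambiguity check against unplanted vocabulary strings.  Deterministic
    under the plan's seed.
    """
    _validate_plan(plan, vocabulary)
    docs: list[Document] = []
    for pid in sorted(plan.docs):
        plants = plan.docs[pid]
        occurrences: list[str] = []
        for surface in sorted(plants):
            occurrences.extend([surface] * plants[surface])
        rng = random.Random(f"{plan.seed}:{pid}")
        rng.shuffle(occurrences)
        n_filler = max(plan.filler_words, len(occurrences) + 3)
        fillers = [rng.choice(CORPUS_FILLER_WORDS) for _ in range(n_filler)]
        # one distinct filler gap per planted occurrence: no two planted
        # tokens are ever adjacent, and the text starts with a filler word
        gaps = rng.sample(range(n_filler), len(occurrences))
        planted_at = dict(zip(gaps, occurrences))
        tokens: list[str] = []
        for i, filler in enumerate(fillers):
            tokens.append(filler)
            if i in planted_at:
                tokens.append(planted_at[i])
        # sentence-ish punctuation between tokens only, never inside one
        pieces: list[str] = []
        for k, tok in enumerate(tokens):
            pieces.append(tok)
            pieces.append(". " if (k + 1) % 8 == 0 else " ")
        docs.append(Document(pid, "".join(pieces).strip() + "."))
    return docs


def plantable_vocabulary(vocabulary: Iterable[str]) -> list[str]:
    """Vocabulary strings that contain no other vocabulary string.

    Only these can be planted with unambiguous counts — a container like
    ``cell nucleus`` (which holds ``nucleus``) is excluded.
    """
    vocab = sorted({v.lower() for v in vocabulary})
    return [s for s in vocab if not any(_contains(s, v) for v in vocab)]


def random_plan(
    vocabulary: Sequence[str],
    n_docs: int = 100,
    seed: int = 0,
    terms_per_doc: tuple[int, int] = (1, 5),
    max_count: int = 5,
    prefix: str = "doc",
) -> PlantingPlan:
    """Draw a random plan over the plantable subset of a vocabulary."""
    pool = plantable_vocabulary(vocabulary)
    if not pool:
        raise PlanError("no plantable vocabulary strings")
    rng = random.Random(seed)
    width = len(str(max(n_docs - 1, 0)))
    docs: dict[str, dict[str, int]] = {}
    for d in range(n_docs):
        k = rng.randint(*terms_per_doc)
        chosen = rng.sample(pool, min(k, len(pool)))
        docs[f"{prefix}{d:0{width}d}.txt"] = {
            s: rng.randint(1, max_count) for s in chosen
        }
    return PlantingPlan(docs=docs, seed=seed)


def write_plan_tsv(plan: PlantingPlan, path: str | Path) -> Path:
    """Dump the ground-truth table (PaperID, Surface, Count) as TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("PaperID\tSurface\tCount\n")
        for pid, surface, count in plan.truth_entries():
            fh.write(f"{pid}\t{surface}\t{count}\n")
    return path
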