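"""Dictionary annotation of a plain-text corpus against the normalized store.

Each document is scanned for occurrences of every vocabulary string — the
canonical subontology term names plus all synonym surface forms — and the
per-document frequencies are written to the annotated index (``paper`` and
``term`` tables).  Matching is case-insensitive and boundary-delimited: an
occurrence counts only when it is flanked by start/end of text, whitespace,
or punctuation, so ``binding`` never matches inside ``unbinding``.  No
stemming, tokenization model, or lemmatization is applied; the text is
scanned as-is.

Synonym occurrences are indexed under the synonym's own surface string, not
folded into the canonical name; the link back to the owning concept is made
at query time through the synonym table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .ontology_store import NS_SHORT, NormalizedStore

logger = logging.getLogger(__name__)


@dataclass
class Document:
    """One corpus document; ``paper_id`` is the file name in directory corpora."""

    paper_id: str
    text: str
    title: str = ""
    author: str = ""


@dataclass(frozen=True)
class IndexEntry:
    """One (document, vocabulary string) row of the annotated index."""

    paper_id: str
    term_name: str  # matched surface string, lowercase
    term_type: str  # subontology short code of the owning concept: cc|mf|bp
    term_freq: int  # occurrence count, >= 1


def _is_boundary(ch: str) -> bool:
    # boundary = anything that is not a letter or digit (whitespace, punctuation)
    return not ch.isalnum()


def match_occurrences(text: str, surface: str) -> int:
    """Count boundary-delimited, case-insensitive occurrences of ``surface``.

    Scans every position (a sliding ``find``), so occurrences that overlap
    other vocabulary strings — or, degenerately, themselves — are all seen.
    Empty text yields 0; an empty surface is a programming error.
    """
    if not surface or not surface.strip():
        raise ValueError("surface string must be non-empty")
    hay = text.lower()
    needle = surface.lower()
    count = 0
    pos = 0
    while True:
        i = hay.find(needle, pos)
        if i < 0:
            break
        j = i + len(needle)
        if (i == 0 or _is_boundary(hay[i - 1])) and (
            j == len(hay) or _is_boundary(hay[j])
        ):
            count += 1
        pos = i + 1
    return count


def annotate_document(
    doc: Document,
    store: NormalizedStore,
    vocabulary: dict[str, tuple[str, str]] | None = None,
) -> list[IndexEntry]:
    """Scan one document against the store's full vocabulary.

    Returns one :class:`IndexEntry` per vocabulary string (canonical names
    and synonym surfaces) occurring at least once, sorted by surface string
    for determinism.  Nested vocabulary strings are counted independently:
    ``alkaline phosphatase activity`` in the text also yields a hit for
    ``phosphatase activity``.  ``vocabulary`` lets corpus-scale callers fetch
    :meth:`NormalizedStore.vocabulary` once instead of per document.
    """
    if vocabulary is None:
        vocabulary = store.vocabulary()
    entries: list[IndexEntry] = []
    for surface, (gid, ns) in vocabulary.items():
        freq = match_occurrences(doc.text, surface)
        if freq > 0:
            entries.append(IndexEntry(doc.paper_id, surface, NS_SHORT[ns], freq))
    return entries


@dataclass
class AnnotatedIndex:
    """Annotated index held in (and queried from) the store's database.

    ``paper`` rows record document identity/metadata; ``term`` rows hold the
    per-document concept frequencies.
    """

    store: NormalizedStore

    def lookup(self, surface: str) -> dict[str, int]:
        """Documents containing ``surface`` with their frequencies."""
        rows = self.store.conn.execute(
            "SELECT PaperID, TermFreq FROM term WHERE TermName = ?",
            (surface.lower().strip(),),
        ).fetchall()
        return dict(rows)

    def paper_ids(self) -> list[str]:
        return [
            r[0]
            for r in self.store.conn.execute(
                "SELECT PaperID FROM paper ORDER BY PaperID"
            )
        ]

    def entries(self) -> list[IndexEntry]:
        rows = self.store.conn.execute(
            "SELECT PaperID, TermName, TermType, TermFreq FROM term"
            " ORDER BY PaperID, TermName"
        ).fetchall()
        return [IndexEntry(*r) for r in rows]

    def n_rows(self) -> int:
        return self.store.conn.execute("SELECT COUNT(*) FROM term").fetchone()[0]

    def dump_tsv(self, outdir: str | Path) -> list[Path]:
        return self.store.dump_tsv(outdir, tables=("paper", "term"))


def build_index(
    corpus: Iterable[Document], store: NormalizedStore
) -> AnnotatedIndex:
    """Annotate every document and (re)build the index tables in the store.

    Deterministic given identical inputs: documents are processed in
    paper_id order and any previous index content is replaced.
    """
    docs = sorted(corpus, key=lambda d: d.paper_id)
    ids = [d.paper_id for d in docs]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate paper_id(s) in corpus: {dupes}")
    cur = store.conn.cursor()
    cur.execute("DELETE FROM paper")
    cur.execute("DELETE FROM term")
    vocabulary = store.vocabulary()
    for doc in docs:
        cur.execute(
            "INSERT INTO paper (PaperID, PaperTitle, PaperAuthor) VALUES (?, ?, ?)",
            (doc.paper_id, doc.title, doc.author),
        )
        for e in annotate_document(doc, store, vocabulary):
            cur.execute(
                "INSERT INTO term (PaperID, TermName, TermType, TermFreq)"
                " VALUES (?, ?, ?, ?)",
                (e.paper_id, e.term_name, e.term_type, e.term_freq),
            )
        logger.info("annotated %s", doc.paper_id)
    store.conn.commit()
    return AnnotatedIndex(store)


def load_corpus(
    directory: str | Path, metadata: str | Path | None = None
) -> list[Document]:
    """Read a directory of UTF-8 plain-text files, one document per file.

    The file name is the PaperID.  Title/author stay empty unless a sidecar
    TSV (columns PaperID, PaperTitle, PaperAuthor) is supplied — no heuristic
    extraction from the text is attempted.  Unreadable files are reported
    and skipped so a corpus run continues.
    """
    directory = Path(directory)
    meta: dict[str, tuple[str, str]] = {}
    if metadata is not None:
        with Path(metadata).open(encoding="utf-8") as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts and parts[0]:
                    title = parts[1] if len(parts) > 1 else ""
                    author = parts[2] if len(parts) > 2 else ""
                    meta[parts[0]] = (title, author)
    docs: list[Document] = []
    skip = Path(metadata).resolve() if metadata is not None else None
    for path in sorted(p for p in directory.iterdir() if p.is_file()):
        if skip is not None and path.resolve() == skip:
            continue
        try:
            text = path.read_text(encoding="utf-8")
        except (OSError, UnicodeDecodeError) as exc:
            logger.error("skipping unreadable document %s: %s", path.name, exc)
            continue
        title, author = meta.get(path.name, ("", ""))
        docs.append(Document(path.name, text, title, author))
    return docs
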