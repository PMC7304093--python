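"""Text preparation: raw statements to token sequences and basic-form term bags.

Every downstream stage consumes one of two views of a patient statement:

* an ordered :class:`TokenSequence` (the recurrent classifier needs word
  order), or
* an unordered :class:`TermBag` of basic-form terms with multiplicities
  (all dictionary stages are order-blind).

The preparation pipeline is: punctuation removal + case folding ->
stop-list filtering -> reduction to basic grammatical form.  The stop list
is applied only on the dictionary pathway; the recurrent pathway receives
all cleaned tokens.
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "RawDocument",
    "TokenSequence",
    "TermBag",
    "StopList",
    "BasicFormMap",
    "clean_and_tokenize",
    "apply_stoplist",
    "lemmatize",
    "prepare_term_bag",
    "read_corpus_dir",
    "read_corpus_tsv",
    "read_stoplist",
    "read_basic_form_map",
]

GROUPS = ("pathological", "control", "unknown")


@dataclass(frozen=True)
class RawDocument:
    """A free-text patient statement.

    ``group`` distinguishes the clinical (pathological) group from healthy
    controls; ``unknown`` is used for unlabeled input.  ``text`` may be
    empty — a legal, degenerate statement.
    """

    doc_id: str
    text: str
    group: str = "unknown"
    language: str = "pl"

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass(frozen=True)
class TokenSequence:
    """Ordered, cleaned tokens of one document (word order preserved)."""

    doc_id: str
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


@dataclass(frozen=True)
class TermBag:
    """Bag of basic-form terms with occurrence counts (order discarded)."""

    doc_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for term, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count for {term!r} must be >= 1, got {n}")

    def total(self) -> int:
        """Total number of tokens represented by the bag."""
        return sum(self.counts.values())


@dataclass(frozen=True)
class StopList:
    """Set of lowercase words negligible for dictionary analysis."""

    terms: frozenset[str] = frozenset()

    def __contains__(self, term: str) -> bool:
        return term in self.terms


@dataclass(frozen=True)
class BasicFormMap:
    """Surface-form -> basic-form lookup used as a pluggable lemmatizer.

    Basic forms must be fixed points of the map (idempotence): if a basic
    form itself appears as a key it must map to itself.  A morphological
    analyzer can be slotted in behind the same mapping contract; the
    packaged default is plain dictionary lookup with identity fallback.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for surface, basic in self.entries.items():
            mapped = self.entries.get(basic, basic)
            if mapped != basic:
                raise ValueError(
                    f"basic form {basic!r} (of {surface!r}) is not a fixed "
                    f"point: it maps on to {mapped!r}"
                )

    def __call__(self, token: str) -> str:
        return self.entries.get(token, token)


def _strip_punctuation(token: str) -> str:
    # Unicode categories P* (punctuation) and S* (symbols) are removed from
    # edges and interiors; digits and letters are retained.
    return "".join(
        ch for ch in token if unicodedata.category(ch)[0] not in ("P", "S")
    )


def clean_and_tokenize(doc: RawDocument) -> TokenSequence:
    """Whitespace-split, punctuation-strip and case-fold a statement.

    Total function: empty text yields an empty sequence.  Tokens that
    consist entirely of punctuation vanish.
    """
    tokens = []
    for raw in doc.text.split():
        tok = _strip_punctuation(raw).lower()
        if tok:
            tokens.append(tok)
    return TokenSequence(doc.doc_id, tuple(tokens))


def apply_stoplist(seq: TokenSequence, stop: StopList) -> TokenSequence:
    """Remove stop-listed tokens, preserving the order of the remainder."""
    return TokenSequence(seq.doc_id, tuple(t for t in seq.tokens if t not in stop))


def lemmatize(seq: TokenSequence, bmap: BasicFormMap) -> TermBag:
    """Map each token to its basic form and aggregate duplicates.

    Tokens absent from the map fall back to themselves, so the total count
    of the bag always equals the length of the input sequence.
    """
    return TermBag(seq.doc_id, dict(Counter(bmap(t) for t in seq.tokens)))


def prepare_term_bag(
    doc: RawDocument,
    stop: StopList | None = None,
    bmap: BasicFormMap | None = None,
) -> TermBag:
    """Full dictionary-pathway preparation: clean, stop-filter, lemmatize."""
    seq = clean_and_tokenize(doc)
    seq = apply_stoplist(seq, stop if stop is not None else StopList())
    return lemmatize(seq, bmap if bmap is not None else BasicFormMap())


# ---------------------------------------------------------------------------
# corpus and resource IO


def read_corpus_dir(path: str | Path, group: str = "unknown") -> list[RawDocument]:
    """Read a directory of ``.txt`` files; doc_id is the filename stem."""
    root = Path(path)
    docs = [
        RawDocument(p.stem, p.read_text(encoding="utf-8-sig"), group=group)
        for p in sorted(root.glob("*.txt"))
    ]
    return docs


def read_corpus_tsv(path: str | Path) -> list[RawDocument]:
    """Read a TSV corpus with columns ``doc_id, group, text``."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"doc_id", "group", "text"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"corpus TSV missing columns: {sorted(missing)}")
    docs = [
        RawDocument(row.doc_id, row.text, group=row.group)
        for row in frame.itertuples(index=False)
    ]
    if len({d.doc_id for d in docs}) != len(docs):
        raise ValueError("duplicate doc_id in corpus")
    return docs


def read_stoplist(path: str | Path) -> StopList:
    """One term per line, lowercase; blank lines and ``#`` comments ignored."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8-sig").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.lower())
    return StopList(frozenset(terms))


def read_basic_form_map(path: str | Path) -> BasicFormMap:
    """Two-column TSV ``surface<TAB>basic``."""
    entries: dict[str, str] = {}
    for i, line in enumerate(
        Path(path).read_text(encoding="utf-8-sig").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected 'surface<TAB>basic'")
        entries[parts[0].strip().lower()] = parts[1].strip().lower()
    return BasicFormMap(entries)
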