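"""Drug-label corpus I/O.

Reads drug-label text from a simplified SPL-like XML dialect and from
TAC-2017-style annotated XML, producing tokenized documents whose
character offsets are globally consistent with the reconstructed label
text.  Offsets are 0-based, half-open throughout.
"""
from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field

from lxml import etree

log = logging.getLogger("phenomine.corpus_io")

#: Closed set of entity mention types used across the package.
ENTITY_TYPES = (
    "AdverseReaction",
    "Severity",
    "Factor",
    "DrugClass",
    "Negation",
    "Animal",
)


class CorpusError(ValueError):
    """Malformed corpus input (XML schema, offset integrity, ...)."""


@dataclass(frozen=True)
class TextSpan:
    """A character interval within one document's text."""

    doc_id: str
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class EntityMention:
    span: TextSpan
    type: str

    def __post_init__(self) -> None:
        if self.type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.type!r}")


@dataclass(frozen=True)
class Token:
    text: str
    span: TextSpan
    sentence_index: int


@dataclass
class AnnotatedDocument:
    """A drug-label text with tokens and (optionally) gold entity mentions."""

    doc_id: str
    text: str
    sections: list[tuple[str, TextSpan]]
    tokens: list[Token]
    mentions: list[EntityMention] = field(default_factory=list)

    @property
    def drug(self) -> str:
        return self.doc_id

    def sentences(self) -> list[list[Token]]:
        """Tokens grouped by sentence index, in order."""
        out: list[list[Token]] = []
        for tok in self.tokens:
            if tok.sentence_index == len(out):
                out.append([])
            out[tok.sentence_index].append(tok)
        return out


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str, doc_id: str = "") -> list[Token]:
    """Split ``text`` into offset-faithful word/punctuation tokens.

    Maximal runs of word characters form tokens; every other
    non-whitespace character is a single-character token.  Sentence
    boundaries are placed after ``.``, ``?`` or ``!`` when followed by
    whitespace and an uppercase letter, or at end of text.  The
    round-trip property ``text[t.start:t.end] == t.text`` holds for
    every token.
    """
    tokens: list[Token] = []
    sent = 0
    for m in _WORD_RE.finditer(text):
        start, end = m.start(), m.end()
        tokens.append(Token(m.group(), TextSpan(doc_id, start, end, m.group()), sent))
        if m.group() in ".?!":
            tail = text[end:]
            stripped = tail.lstrip()
            at_eot = stripped == ""
            new_sentence = (
                at_eot
                or (len(stripped) < len(tail) and stripped[0].isupper())
            )
            if new_sentence:
                sent += 1
    return tokens


# ---------------------------------------------------------------------------
# Simplified label XML (unannotated drug labels)
# ---------------------------------------------------------------------------

def _parse_xml(path) -> etree._Element:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # byte offset via libxml2 position
        raise CorpusError(f"{path}: malformed XML: {exc}") from exc
    return tree.getroot()


def _require(elem, name: str, path) -> None:
    if elem is None:
        raise CorpusError(f"{path}: missing required element <{name}>")


def _assemble_sections(doc_id: str, section_elems) -> tuple[str, list[tuple[str, TextSpan]]]:
    """Join section texts with single newlines; spans are global offsets."""
    pieces: list[str] = []
    sections: list[tuple[str, TextSpan]] = []
    offset = 0
    for sec in section_elems:
        name = sec.get("name", "")
        body = sec.text or ""
        if pieces:
            offset += 1  # the joining newline
        if body:  # empty sections contribute position but no span
            sections.append((name, TextSpan(doc_id, offset, offset + len(body), body)))
        pieces.append(body)
        offset += len(body)
    return "\n".join(pieces), sections


def parse_drug_label_xml(path) -> AnnotatedDocument:
    """Parse a simplified drug-label XML file into a document (no mentions).

    Expected shape: ``<Label drug="NAME"><Section name="...">text</Section>
    ...</Label>``.  Section texts are concatenated joined by single
    newlines; offsets are global to the joined text.
    """
    root = _parse_xml(path)
    if root.tag != "Label":
        raise CorpusError(f"{path}: expected root <Label>, got <{root.tag}>")
    doc_id = root.get("drug") or ""
    if not doc_id:
        raise CorpusError(f"{path}: <Label> missing required attribute 'drug'")
    section_elems = root.findall("Section")
    if not section_elems:
        raise CorpusError(f"{path}: missing required element <Section>")
    text, sections = _assemble_sections(doc_id, section_elems)
    return AnnotatedDocument(doc_id, text, sections, tokenize(text, doc_id))


# ---------------------------------------------------------------------------
# TAC-style annotated XML
# ---------------------------------------------------------------------------

def _snap_to_tokens(tokens: list[Token], start: int, end: int) -> tuple[int, int] | None:
    """Smallest [start, end) covering run of whole tokens, or None."""
    covering = [t for t in tokens if t.span.end > start and t.span.start < end]
    if not covering:
        return None
    return covering[0].span.start, covering[-1].span.end


def parse_annotated_xml(path) -> AnnotatedDocument:
    """Parse TAC-style annotated label XML, populating gold mentions.

    Shape: ``<Label drug><Text><Section>...</Section></Text>
    <Mentions><Mention id str type start len/></Mentions></Label>``.
    ``start``/``len`` may be comma-separated lists; each contiguous
    fragment becomes its own mention.  The recorded surface string must
    match the text slice, else an integrity error names the mention id.
    Mention boundaries falling inside a token are snapped outward to the
    smallest covering token run (logged).
    """
    root = _parse_xml(path)
    if root.tag != "Label":
        raise CorpusError(f"{path}: expected root <Label>, got <{root.tag}>")
    doc_id = root.get("drug") or ""
    text_elem = root.find("Text")
    _require(text_elem, "Text", path)
    section_elems = text_elem.findall("Section")
    if not section_elems:
        raise CorpusError(f"{path}: missing required element <Section>")
    text, sections = _assemble_sections(doc_id, section_elems)
    tokens = tokenize(text, doc_id)

    mentions: list[EntityMention] = []
    mention_parent = root.find("Mentions")
    mention_elems = mention_parent.findall("Mention") if mention_parent is not None else []
    for m in mention_elems:
        mid = m.get("id", "?")
        mtype = m.get("type", "")
        if mtype not in ENTITY_TYPES:
            raise CorpusError(f"{path}: mention {mid}: unknown type {mtype!r}")
        starts = [int(s) for s in (m.get("start") or "").split(",")]
        lens = [int(s) for s in (m.get("len") or "").split(",")]
        if len(starts) != len(lens):
            raise CorpusError(f"{path}: mention {mid}: start/len list length mismatch")
        surface = m.get("str") or ""
        fragments = [text[s: s + l] for s, l in zip(starts, lens)]
        recorded = surface if len(fragments) == 1 else None
        if recorded is not None and fragments[0] != recorded:
            raise CorpusError(
                f"{path}: mention {mid}: surface string {recorded!r} does not "
                f"match text slice {fragments[0]!r}"
            )
        if recorded is None and surface and " ".join(fragments) != surface \
                and "".join(fragments) != surface:
            raise CorpusError(
                f"{path}: mention {mid}: discontinuous surface {surface!r} "
                f"does not match fragments {fragments!r}"
            )
        for s, l in zip(starts, lens):
            snapped = _snap_to_tokens(tokens, s, s + l)
            if snapped is None:
                log.warning("mention %s in %s covers no tokens; dropped", mid, doc_id)
                continue
            ns, ne = snapped
            if (ns, ne) != (s, s + l):
                log.info("snapped mention %s in %s: [%d,%d) -> [%d,%d)",
                         mid, doc_id, s, s + l, ns, ne)
            mentions.append(
                EntityMention(TextSpan(doc_id, ns, ne, text[ns:ne]), mtype)
            )
    return AnnotatedDocument(doc_id, text, sections, tokens, mentions)


# ---------------------------------------------------------------------------
# Lexicon + corpus split
# ---------------------------------------------------------------------------

def load_lexicon(path) -> set[str]:
    """One disorder term per line, UTF-8; returns normalized token strings."""
    terms: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.strip()
            if term:
                terms.add(" ".join(t.text.lower() for t in tokenize(term)))
    return terms


def split_corpus(docs, ratio: float, seed: int):
    """Deterministic document-level train/dev split.

    ``|train| = round(ratio * N)`` with half-up rounding; the shuffle is
    a pure function of ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    order = list(docs)
    random.Random(seed).shuffle(order)
    n_train = int(ratio * len(order) + 0.5)
    return order[:n_train], order[n_train:]
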