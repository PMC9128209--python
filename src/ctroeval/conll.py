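"""CoNLL-style one-token-per-line I/O for single-entity annotations.

Plain BIO tagging cannot represent the overlapping and embedded entity
annotations that occur in fine-grained clinical-trial corpora (e.g. three
overlapping *TimePoint* spans, or two *Drug* mentions embedded in a wider
*Drug* annotation of a fixed combination).  The dialect used here therefore
carries annotation ids in the tag field:

* one token per line, three TAB-separated columns:
  ``token_index``, ``token_text``, ``tag``;
* the tag is ``O`` or a ``|``-joined list of ``Category[ann_id]`` items;
* an entity covers the maximal run of consecutive lines carrying its id;
* documents are introduced by a ``#doc <doc_id>`` line and separated by a
  blank line.

Output is deterministic: documents ordered by doc_id, tags by ann_id.
"""

from __future__ import annotations

import re
import string
from pathlib import Path
from typing import Iterable, Union

from .model import AnnotationSet, Document, EntityAnnotation, Token

_PUNCT = set(string.punctuation)
_TAG_ITEM = re.compile(r"^(?P<cat>[^\[\]|]+)\[(?P<aid>[^\[\]|]+)\]$")


class ConllParseError(ValueError):
    """Malformed CoNLL input; the message names the offending line."""


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenization with leading/trailing punctuation split off.

    ``"0.03% once daily."`` yields tokens ``0.03``, ``%``, ``once``,
    ``daily``, ``.`` — internal punctuation (the decimal point) stays inside
    its token.  Deterministic, and idempotent on the produced token texts.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(), m.start()
        pieces: list[tuple[int, str]] = []  # (char offset, piece)
        lead = 0
        while lead < len(chunk) - 1 and chunk[lead] in _PUNCT:
            pieces.append((start + lead, chunk[lead]))
            lead += 1
        trail: list[tuple[int, str]] = []
        end = len(chunk)
        while end - 1 > lead and chunk[end - 1] in _PUNCT:
            trail.append((start + end - 1, chunk[end - 1]))
            end -= 1
        pieces.append((start + lead, chunk[lead:end]))
        pieces.extend(reversed(trail))
        for off, piece in pieces:
            tokens.append(
                Token(
                    index=len(tokens),
                    text=piece,
                    char_start=off,
                    char_end=off + len(piece),
                )
            )
    return tokens


def make_document(doc_id: str, text: str) -> Document:
    return Document(doc_id=doc_id, tokens=tuple(tokenize(text)), text=text)


def document_from_token_texts(doc_id: str, token_texts: Iterable[str]) -> Document:
    """Rebuild a Document from bare token texts (single-space separators)."""
    tokens: list[Token] = []
    pos = 0
    for i, t in enumerate(token_texts):
        tokens.append(Token(index=i, text=t, char_start=pos, char_end=pos + len(t)))
        pos += len(t) + 1
    text = " ".join(t.text for t in tokens)
    return Document(doc_id=doc_id, tokens=tuple(tokens), text=text)


def _format_tag(entities: list[EntityAnnotation], index: int) -> str:
    items = [
        f"{e.category}[{e.ann_id}]"
        for e in sorted(entities, key=lambda e: e.ann_id)
        if e.start <= index < e.end
    ]
    return "|".join(items) if items else "O"


def write_conll(sets: Iterable[AnnotationSet], path: Union[str, Path]) -> None:
    Path(path).write_text(dumps_conll(sets), encoding="utf-8")


def dumps_conll(sets: Iterable[AnnotationSet]) -> str:
    lines: list[str] = []
    for aset in sorted(sets, key=lambda s: s.document.doc_id):
        lines.append(f"#doc {aset.document.doc_id}")
        for tok in aset.document.tokens:
            lines.append(
                f"{tok.index}\t{tok.text}\t{_format_tag(aset.entities, tok.index)}"
            )
        lines.append("")
    return "\n".join(lines) + ("\n" if lines else "")


def read_conll(
    source: Union[str, Path], annotator_id: str = ""
) -> list[AnnotationSet]:
    path = Path(source)
    return loads_conll(
        path.read_text(encoding="utf-8"), annotator_id=annotator_id or path.stem
    )


def loads_conll(text: str, annotator_id: str = "annotator") -> list[AnnotationSet]:
    sets: list[AnnotationSet] = []
    doc_id: str | None = None
    token_texts: list[str] = []
    # ann_id -> [category, start, end, open?]
    spans: dict[str, list] = {}

    def flush(line_no: int) -> None:
        nonlocal doc_id, token_texts, spans
        if doc_id is None:
            return
        doc = document_from_token_texts(doc_id, token_texts)
        entities = [
            EntityAnnotation(
                ann_id=aid,
                category=cat,
                start=start,
                end=end,
                surface=" ".join(token_texts[start:end]),
            )
            for aid, (cat, start, end, _open) in sorted(spans.items())
        ]
        sets.append(
            AnnotationSet(
                document=doc,
                annotator_id=annotator_id,
                entities=entities,
                templates=[],
            )
        )
        doc_id, token_texts, spans = None, [], {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(line_no)
            continue
        if line.startswith("#doc"):
            flush(line_no)
            doc_id = line[len("#doc") :].strip()
            if not doc_id:
                raise ConllParseError(f"line {line_no}: #doc without an id")
            continue
        if doc_id is None:
            raise ConllParseError(
                f"line {line_no}: token line before any '#doc' header"
            )
        cols = line.split("\t")
        if len(cols) != 3:
            raise ConllParseError(
                f"line {line_no}: expected 3 TAB-separated columns, got {len(cols)}"
            )
        idx_str, tok_text, tag = cols
        try:
            idx = int(idx_str)
        except ValueError:
            raise ConllParseError(
                f"line {line_no}: token index {idx_str!r} is not an integer"
            ) from None
        if idx != len(token_texts):
            raise ConllParseError(
                f"line {line_no}: token index {idx} out of order "
                f"(expected {len(token_texts)})"
            )
        token_texts.append(tok_text)
        active: set[str] = set()
        if tag != "O":
            for item in tag.split("|"):
                m = _TAG_ITEM.match(item)
                if m is None:
                    raise ConllParseError(
                        f"line {line_no}: malformed tag item {item!r}"
                    )
                cat, aid = m.group("cat"), m.group("aid")
                active.add(aid)
                if aid in spans:
                    rec = spans[aid]
                    if not rec[3]:
                        raise ConllParseError(
                            f"line {line_no}: annotation id {aid!r} re-opened "
                            f"after its span closed"
                        )
                    if rec[0] != cat:
                        raise ConllParseError(
                            f"line {line_no}: annotation id {aid!r} changes "
                            f"category {rec[0]!r} -> {cat!r}"
                        )
                    rec[2] = idx + 1
                else:
                    spans[aid] = [cat, idx, idx + 1, True]
        for aid, rec in spans.items():
            if aid not in active:
                rec[3] = False
    flush(-1)
    return sets
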