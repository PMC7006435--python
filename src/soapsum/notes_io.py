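"""Reading clinical SOAP notes and turning them into model inputs.

A SOAP note has a Header (patient metadata and the reason for visit /
chief complaint), Subjective and Objective narrative sections, the
Assessment (the diagnosis-bearing summary the model must generate) and a
Plan.  This module parses raw note text into sections, tokenizes,
builds the fixed vocabulary, and encodes examples with the per-example
extended vocabulary that the copy mechanism needs.

Vocabulary policy: any token containing a digit is out-of-vocabulary
unless it is a single digit; the ten digits "0"–"9" are always in the
vocabulary.  Dates, ages and identifiers therefore surface either as
single digits or as OOV tokens the model must copy from the source.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Note",
    "Vocabulary",
    "EncodedExample",
    "UnparseableNoteError",
    "UntrainableExampleError",
    "parse_soap_note",
    "tokenize",
    "build_vocabulary",
    "encode_example",
    "render_ids",
    "read_jsonl_notes",
    "write_jsonl_notes",
]

PAD, UNK, BEGIN, END = "<pad>", "<unk>", "</begin>", "</end>"
SPECIALS = (PAD, UNK, BEGIN, END)

MAX_SOURCE_LEN = 500
MAX_HEADER_LEN = 100
MAX_TARGET_LEN = 60


class UnparseableNoteError(ValueError):
    """Raised when a raw note lacks a required section marker."""


class UntrainableExampleError(ValueError):
    """Raised when a note cannot yield a usable training example."""


@dataclass
class Note:
    """One SOAP document, section texts without their label lines."""

    header_text: str
    subjective_text: str
    objective_text: str
    assessment_text: str
    plan_text: str = ""

    @property
    def source_text(self) -> str:
        """The narrative the assessment is generated from."""
        return (self.subjective_text + " " + self.objective_text).strip()

    def is_trainable(self) -> bool:
        return bool(self.header_text.strip()) and bool(self.assessment_text.strip())

    def to_dict(self) -> dict:
        return {
            "header": self.header_text,
            "subjective": self.subjective_text,
            "objective": self.objective_text,
            "assessment": self.assessment_text,
            "plan": self.plan_text,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Note":
        return cls(
            header_text=d.get("header", ""),
            subjective_text=d.get("subjective", ""),
            objective_text=d.get("objective", ""),
            assessment_text=d.get("assessment", ""),
            plan_text=d.get("plan", ""),
        )


# ---------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------

# markers accepted at the start of a line (or inline after another
# section's text); dialects vary across clinics
_MARKERS = {
    "header": r"header\s*:",
    "reason": r"reason\s+for\s+visit\s*:?",
    "subjective": r"subjective\s*:",
    "hpi": r"history\s+of\s+present\s+illness\s*:?",
    "objective": r"objective\s*:",
    "assessment": r"assessment\s*:",
    "plan": r"plan\s*:",
}

_MARKER_RE = re.compile(
    "|".join(f"(?P<{name}>{pat})" for name, pat in _MARKERS.items()),
    re.IGNORECASE,
)


def parse_soap_note(raw_text: str) -> Note:
    """Split raw note text into SOAP sections.

    Section labels are matched case-insensitively.  When explicit
    ``subjective:``/``objective:`` markers are absent, everything between
    a ``history of present illness`` marker and the ``assessment`` marker
    becomes the subjective text (the objective text is left empty) —
    the aggregation fallback used for notes that describe the narrative
    under other headings.

    Raises
    ------
    UnparseableNoteError
        If no assessment marker is found.
    """
    if not raw_text or not raw_text.strip():
        raise UnparseableNoteError("empty note text")

    hits = [(m.start(), m.end(), m.lastgroup) for m in _MARKER_RE.finditer(raw_text)]
    if not any(name == "assessment" for _, _, name in hits):
        raise UnparseableNoteError("missing section marker: assessment")

    # segment: text after each marker up to the next marker
    segments: dict[str, str] = {}
    order: list[str] = []
    prev_end = 0
    prev_name: str | None = None
    for start, end, name in hits:
        if prev_name is None:
            if raw_text[:start].strip():
                segments.setdefault("header", raw_text[:start].strip())
                order.append("header")
        else:
            segments[prev_name] = raw_text[prev_end:start].strip()
        prev_end, prev_name = end, name
        order.append(name)
    segments[prev_name] = raw_text[prev_end:].strip()

    header = segments.get("header", "")
    if "reason" in segments:
        reason = "reason for visit: " + segments["reason"]
        header = (header + " " + reason).strip() if header else reason

    subjective = segments.get("subjective", "")
    objective = segments.get("objective", "")
    if not subjective and not objective and "hpi" in segments:
        # aggregation fallback: all text between the HPI marker and the
        # assessment marker counts as subjective narrative
        subjective = segments["hpi"]

    return Note(
        header_text=header,
        subjective_text=subjective,
        objective_text=objective,
        assessment_text=segments.get("assessment", ""),
        plan_text=segments.get("plan", ""),
    )


# ---------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+|[^a-z0-9\s]")


def tokenize(text: str) -> list[str]:
    """Lowercase and split into word/punctuation tokens.

    Runs of letters and digits form one token; every other non-space
    character is a standalone token, so ``03/04/2016`` becomes
    ``["03", "/", "04", "/", "2016"]``.  Deterministic; empty text gives
    an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


def detokenize(tokens: Sequence[str]) -> str:
    return " ".join(tokens)


# ---------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------

_DIGITS = tuple(str(d) for d in range(10))


def _vocab_eligible(token: str) -> bool:
    if any(ch.isdigit() for ch in token):
        return token in _DIGITS
    return True


@dataclass
class Vocabulary:
    """Fixed token↔id map with reserved special ids.

    Ids 0–3 are ``<pad>``, ``<unk>``, ``</begin>``, ``</end>``; regular
    tokens follow in frequency rank order.  The ten single digits are
    always present; no multi-character token containing a digit ever is.
    """

    token_to_id: dict[str, int] = field(default_factory=dict)
    id_to_token: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.id_to_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def begin_id(self) -> int:
        return self.token_to_id[BEGIN]

    @property
    def end_id(self) -> int:
        return self.token_to_id[END]

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def save(self, path) -> None:
        """One token per line, rank order (specials first)."""
        with open(path, "w") as fh:
            for tok in self.id_to_token:
                fh.write(tok + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        return cls._from_ranked(tokens)

    @classmethod
    def _from_ranked(cls, tokens: list[str]) -> "Vocabulary":
        vocab = cls()
        vocab.id_to_token = list(tokens)
        vocab.token_to_id = {tok: i for i, tok in enumerate(tokens)}
        if len(vocab.token_to_id) != len(vocab.id_to_token):
            raise ValueError("duplicate tokens in vocabulary file")
        return vocab


def build_vocabulary(corpus: Iterable[Note], max_size: int = 100_000) -> Vocabulary:
    """Count tokens over header+source+assessment text and keep the most
    frequent eligible ones, up to ``max_size`` regular slots.

    Frequency ties break lexicographically.  The digits 0–9 are always
    included (counting toward ``max_size``); digit-bearing multi-character
    tokens are excluded and will surface as OOV at encoding time.
    """
    if max_size < len(SPECIALS) + 10:
        raise ValueError(f"max_size must be at least {len(SPECIALS) + 10}")
    counts: Counter[str] = Counter()
    n_notes = 0
    for note in corpus:
        n_notes += 1
        for text in (note.header_text, note.source_text, note.assessment_text):
            counts.update(tokenize(text))
    if n_notes == 0:
        raise ValueError("empty corpus")

    for d in _DIGITS:  # digits are always in-vocabulary
        counts.setdefault(d, 0)
    non_digits = sorted(
        (t for t in counts if _vocab_eligible(t) and t not in _DIGITS),
        key=lambda t: (-counts[t], t),
    )
    keep = set(_DIGITS) | set(non_digits[: max_size - len(_DIGITS)])
    ranked = sorted(keep, key=lambda t: (-counts[t], t))
    return Vocabulary._from_ranked(list(SPECIALS) + ranked)


# ---------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------

@dataclass
class EncodedExample:
    """Id sequences for one note, plus its extended OOV vocabulary.

    ``source_ids`` uses UNK for OOV tokens; ``source_ext_ids`` gives each
    distinct OOV source token a dense id ≥ vocabulary size, in first-
    occurrence order, so the copy mechanism can address it.  Target ids
    use extended ids for OOV tokens that appear in the source and UNK
    for OOV tokens that do not.
    """

    source_ids: list[int]
    source_ext_ids: list[int]
    header_ids: list[int]
    target_ids: list[int]
    oov_tokens: list[str]
    source_tokens: list[str]
    header_tokens: list[str]
    target_tokens: list[str]

    @property
    def n_oov(self) -> int:
        return len(self.oov_tokens)


def encode_example(
    note: Note,
    vocab: Vocabulary,
    max_source_len: int = MAX_SOURCE_LEN,
    max_header_len: int = MAX_HEADER_LEN,
    max_target_len: int = MAX_TARGET_LEN,
) -> EncodedExample:
    """Tokenize, truncate and id-encode one note.

    The source (subjective+objective) is truncated to ``max_source_len``
    tokens *before* OOV indexing, so extended ids never reference
    truncated positions; the header to ``max_header_len``; the target
    assessment to ``max_target_len`` tokens followed by the end symbol.
    """
    source_tokens = tokenize(note.source_text)[:max_source_len]
    if not source_tokens:
        raise UntrainableExampleError("empty source after tokenization")
    header_tokens = tokenize(note.header_text)[:max_header_len]
    target_tokens = tokenize(note.assessment_text)[:max_target_len]

    source_ids: list[int] = []
    source_ext_ids: list[int] = []
    oov_tokens: list[str] = []
    oov_index: dict[str, int] = {}
    for tok in source_tokens:
        tid = vocab.id_of(tok)
        source_ids.append(tid)
        if tid != vocab.unk_id:
            source_ext_ids.append(tid)
        else:
            if tok not in oov_index:
                oov_index[tok] = vocab.size + len(oov_tokens)
                oov_tokens.append(tok)
            source_ext_ids.append(oov_index[tok])

    header_ids = [vocab.id_of(tok) for tok in header_tokens]

    target_ids: list[int] = []
    for tok in target_tokens:
        tid = vocab.id_of(tok)
        if tid == vocab.unk_id and tok in oov_index:
            tid = oov_index[tok]
        target_ids.append(tid)
    target_ids.append(vocab.end_id)

    return EncodedExample(
        source_ids=source_ids,
        source_ext_ids=source_ext_ids,
        header_ids=header_ids,
        target_ids=target_ids,
        oov_tokens=oov_tokens,
        source_tokens=source_tokens,
        header_tokens=header_tokens,
        target_tokens=target_tokens,
    )


def render_ids(ids: Sequence[int], vocab: Vocabulary, oov_tokens: Sequence[str]) -> list[str]:
    """Map (possibly extended) ids back to token strings."""
    out = []
    for i in ids:
        if i < vocab.size:
            out.append(vocab.id_to_token[i])
        else:
            out.append(oov_tokens[i - vocab.size])
    return out


# ---------------------------------------------------------------------
# JSON-lines IO
# ---------------------------------------------------------------------

def read_jsonl_notes(path) -> list[Note]:
    notes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                notes.append(Note.from_dict(json.loads(line)))
    return notes


def write_jsonl_notes(notes: Iterable[Note], path) -> None:
    with open(path, "w") as fh:
        for note in notes:
            fh.write(json.dumps(note.to_dict()) + "\n")
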