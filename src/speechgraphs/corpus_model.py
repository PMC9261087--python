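"""Domain types for annotated speech transcripts.

A corpus is a set of *responses* (one per elicitation prompt) from a set of
participants.  Each response is an ordered list of manually segmented
*utterances*; each utterance carries tokens (surface form, lemma, universal
POS tag) and semantic-role-labeling (SRL) frames in the PropBank style, of
which only the core arguments A0 (proto-agent), A1 and A2 (proto-patients)
are retained.

The module also owns the normalization rules that feed graph construction:
which POS classes count as content words, how filled pauses are removed,
and how argument spans are rendered into node labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Token",
    "SRLFrame",
    "Utterance",
    "Response",
    "Corpus",
    "CorpusParseError",
    "CorpusValidationError",
    "CONTENT_POS",
    "FUNCTION_POS",
    "CORE_ARG_LABELS",
    "DEFAULT_FILLED_PAUSES",
    "TASKS",
    "token_is_content",
    "content_lemmas",
    "argument_label",
    "annotate_plaintext",
    "read_corpus",
    "write_corpus",
    "read_conll_utterances",
]

#: Universal POS tags admitted into structural graphs: nouns, pronouns,
#: non-auxiliary verbs, adjectives and adverbs.  AUX covers auxiliary verbs.
CONTENT_POS = frozenset({"NOUN", "PROPN", "PRON", "VERB", "ADJ", "ADV"})

#: Tags always excluded (function words, punctuation, residual classes).
FUNCTION_POS = frozenset(
    {"AUX", "DET", "ADP", "CCONJ", "SCONJ", "CONJ", "INTJ", "PART", "PUNCT", "NUM", "SYM", "X"}
)

#: Core PropBank argument labels used for semantic graphs.
CORE_ARG_LABELS = frozenset({"A0", "A1", "A2"})

#: Lexical stoplist for filled pauses that transcribers may tag as content
#: words.  Transcription conventions vary, so this extends the INTJ filter
#: and is configurable at every call site.
DEFAULT_FILLED_PAUSES = frozenset({"um", "uh", "uhm", "erm", "er", "mm", "hmm", "mhm", "mm-hmm", "uh-huh"})

TASKS = ("picture", "narrative")


class CorpusParseError(ValueError):
    """Raised when an on-disk transcript record cannot be interpreted."""


class CorpusValidationError(ValueError):
    """Raised when parsed data violates a corpus invariant."""


@dataclass(frozen=True)
class Token:
    """A single token: surface form, lowercased lemma, universal POS tag,
    and its 0-based position within the owning utterance."""

    surface: str
    lemma: str
    pos: str
    index: int

    def __post_init__(self) -> None:
        if self.surface and not self.lemma:
            raise CorpusValidationError(
                f"token {self.index!r} ({self.surface!r}): non-empty surface requires a lemma"
            )
        if self.index < 0:
            raise CorpusValidationError(f"token index must be >= 0, got {self.index}")
        object.__setattr__(self, "lemma", self.lemma.lower())


@dataclass(frozen=True)
class SRLFrame:
    """One predicate-argument frame.  Spans are (start, end) token-index
    pairs, 0-based and end-exclusive, within the owning utterance."""

    predicate: tuple[int, int]
    predicate_lemma: str
    arguments: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicate", tuple(self.predicate))
        object.__setattr__(self, "predicate_lemma", self.predicate_lemma.lower())
        args = {}
        for label, span in dict(self.arguments).items():
            if label not in CORE_ARG_LABELS:
                raise CorpusValidationError(
                    f"argument label {label!r} not in {sorted(CORE_ARG_LABELS)}"
                )
            args[label] = tuple(span)
        object.__setattr__(self, "arguments", args)
        for name, (start, end) in [("predicate", self.predicate), *self.arguments.items()]:
            if not (0 <= start < end):
                raise CorpusValidationError(
                    f"span for {name!r} must satisfy 0 <= start < end, got ({start}, {end})"
                )


@dataclass(frozen=True)
class Utterance:
    """A manually segmented utterance: ordered tokens plus SRL frames."""

    utterance_id: int
    tokens: tuple[Token, ...]
    frames: tuple[SRLFrame, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "frames", tuple(self.frames))
        for expected, token in enumerate(self.tokens):
            if token.index != expected:
                raise CorpusValidationError(
                    f"utterance {self.utterance_id}: token indices must be consecutive from 0, "
                    f"found {token.index} at position {expected}"
                )
        n = len(self.tokens)
        for frame in self.frames:
            for name, (start, end) in [("predicate", frame.predicate), *frame.arguments.items()]:
                if end > n:
                    raise CorpusValidationError(
                        f"utterance {self.utterance_id}: span ({start}, {end}) for {name!r} "
                        f"exceeds utterance length {n}"
                    )

    def span_tokens(self, span: tuple[int, int]) -> tuple[Token, ...]:
        start, end = span
        return self.tokens[start:end]


@dataclass(frozen=True)
class Response:
    """All utterances a participant produced for one prompt."""

    participant_id: str
    task: str
    prompt_id: str
    utterances: tuple[Utterance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "utterances", tuple(self.utterances))
        if self.task not in TASKS:
            raise CorpusValidationError(f"task must be one of {TASKS}, got {self.task!r}")
        if not self.utterances:
            raise CorpusValidationError(
                f"response {self.participant_id}/{self.prompt_id}: at least one utterance required"
            )
        for expected, utt in enumerate(self.utterances):
            if utt.utterance_id != expected:
                raise CorpusValidationError(
                    f"response {self.participant_id}/{self.prompt_id}: utterance_ids must be "
                    f"consecutive from 0, found {utt.utterance_id} at position {expected}"
                )


@dataclass
class Corpus:
    """Responses plus the participant table.

    ``participants`` is a DataFrame with columns ``participant_id``,
    ``group`` (e.g. ``PS+`` / ``PS-``) and one numeric column per clinical
    score (e.g. BPRS, SANS, TLC totals or factors).
    """

    responses: list[Response]
    participants: pd.DataFrame

    def __post_init__(self) -> None:
        if "participant_id" not in self.participants.columns:
            raise CorpusValidationError("participant table needs a 'participant_id' column")
        known = set(self.participants["participant_id"])
        for resp in self.responses:
            if resp.participant_id not in known:
                raise CorpusValidationError(
                    f"response references unknown participant {resp.participant_id!r}"
                )

    @property
    def clinical_measures(self) -> list[str]:
        skip = {"participant_id", "group"}
        return [c for c in self.participants.columns if c not in skip]

    def responses_for(self, participant_id: str, task: str | None = None) -> list[Response]:
        return [
            r
            for r in self.responses
            if r.participant_id == participant_id and (task is None or r.task == task)
        ]


# ---------------------------------------------------------------------------
# Content-word filtering and node labels
# ---------------------------------------------------------------------------

KNOWN_POS = CONTENT_POS | FUNCTION_POS


def token_is_content(
    token: Token,
    *,
    stoplist: frozenset[str] = DEFAULT_FILLED_PAUSES,
    on_unknown_pos: str = "warn",
) -> bool:
    """Whether a token survives the content-word filter.

    Content words are nouns, proper nouns, pronouns, non-auxiliary verbs,
    adjectives and adverbs; filled pauses on ``stoplist`` are excluded
    regardless of tag.  Unknown POS tags are excluded with a warning by
    default (``on_unknown_pos="raise"`` to fail instead).
    """
    if token.pos in CONTENT_POS:
        return token.lemma not in stoplist
    if token.pos not in KNOWN_POS:
        if on_unknown_pos == "raise":
            raise CorpusValidationError(f"unknown POS tag {token.pos!r} on {token.surface!r}")
        warnings.warn(
            f"unknown POS tag {token.pos!r} on token {token.surface!r}; excluding",
            stacklevel=3,
        )
    return False


def content_lemmas(
    response: Response,
    *,
    stoplist: frozenset[str] = DEFAULT_FILLED_PAUSES,
    on_unknown_pos: str = "warn",
) -> list[str]:
    """Lowercased lemmas of all content tokens in the response, concatenated
    across utterances in spoken order.

    Structural graphs are built on this single cross-utterance sequence;
    utterance boundaries do not break the chain.
    """
    out: list[str] = []
    for utt in response.utterances:
        for token in utt.tokens:
            if token_is_content(token, stoplist=stoplist, on_unknown_pos=on_unknown_pos):
                out.append(token.lemma)
    return out


def argument_label(
    span: tuple[int, int],
    utterance: Utterance,
    *,
    stoplist: frozenset[str] = DEFAULT_FILLED_PAUSES,
) -> str:
    """Node label for an argument span: content-filtered lemmas joined by
    single spaces ("the cookie jar" -> "cookie jar").

    If the filter removes every token of the span, the lemmatized full span
    is used instead so that every tagged argument yields a node.
    """
    start, end = span
    tokens = utterance.span_tokens((start, end))
    if not tokens:
        raise CorpusValidationError(
            f"empty argument span ({start}, {end}) in utterance {utterance.utterance_id}"
        )
    kept = [t.lemma for t in tokens if token_is_content(t, stoplist=stoplist, on_unknown_pos="warn")]
    if not kept:
        kept = [t.lemma for t in tokens]
    return " ".join(kept)


# ---------------------------------------------------------------------------
# Annotation adapter
# ---------------------------------------------------------------------------

#: An annotator maps raw text to a list of utterance dictionaries in the
#: on-disk schema (see `read_corpus`).  Any SRL backend (e.g. a BERT-based
#: PropBank labeler) can be plugged in through this contract; the core
#: pipeline itself only ever consumes pre-annotated input.
Annotator = Callable[[str], list[dict]]


def annotate_plaintext(text: str, annotator: Annotator) -> list[Utterance]:
    """Run an external annotator on raw text and validate its output.

    Frames emitted with argument labels outside {A0, A1, A2} have those
    labels dropped with a warning; everything else must satisfy the
    `Utterance` invariants.
    """
    raw = annotator(text)
    return [_parse_utterance(rec, i, where=f"annotated utterance {i}") for i, rec in enumerate(raw)]


# ---------------------------------------------------------------------------
# On-disk schema
# ---------------------------------------------------------------------------


def _parse_span(value, where: str) -> tuple[int, int]:
    try:
        start, end = value
        return int(start), int(end)
    except (TypeError, ValueError) as exc:
        raise CorpusParseError(f"{where}: expected [start, end] span, got {value!r}") from exc


def _parse_utterance(rec: dict, expected_id: int, where: str) -> Utterance:
    try:
        raw_tokens = rec["tokens"]
    except (TypeError, KeyError) as exc:
        raise CorpusParseError(f"{where}: missing 'tokens'") from exc
    tokens = []
    for i, t in enumerate(raw_tokens):
        try:
            tokens.append(
                Token(
                    surface=str(t["surface"]),
                    lemma=str(t["lemma"]),
                    pos=str(t["pos"]),
                    index=int(t.get("index", i)),
                )
            )
        except KeyError as exc:
            raise CorpusParseError(f"{where}, token {i}: missing field {exc}") from exc
    frames = []
    for j, f in enumerate(rec.get("frames", [])):
        fwhere = f"{where}, frame {j}"
        try:
            predicate = _parse_span(f["predicate"], fwhere)
            predicate_lemma = str(f["predicate_lemma"])
        except KeyError as exc:
            raise CorpusParseError(f"{fwhere}: missing field {exc}") from exc
        args = {}
        for label, span in f.get("args", {}).items():
            if label not in CORE_ARG_LABELS:
                warnings.warn(
                    f"{fwhere}: dropping non-core argument label {label!r}", stacklevel=2
                )
                continue
            args[label] = _parse_span(span, fwhere)
        frames.append(SRLFrame(predicate=predicate, predicate_lemma=predicate_lemma, arguments=args))
    utterance_id = int(rec.get("utterance_id", expected_id))
    return Utterance(utterance_id=utterance_id, tokens=tuple(tokens), frames=tuple(frames))


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus from the JSON transcript schema.

    Top level: ``{"participants": [...], "responses": [...]}``.  Each
    participant record carries ``id``, ``group`` and a ``scores`` mapping;
    each response carries ``participant_id``, ``task``, ``prompt_id`` and
    ``utterances`` in the format consumed by `Utterance`.  Spans are
    0-based, end-exclusive.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise CorpusParseError(f"{path}: invalid JSON: {exc}") from exc
    return corpus_from_dict(doc, where=str(path))


def corpus_from_dict(doc: dict, where: str = "<dict>") -> Corpus:
    part_rows = []
    for rec in doc.get("participants", []):
        try:
            row = {"participant_id": str(rec["id"]), "group": str(rec.get("group", ""))}
        except KeyError as exc:
            raise CorpusParseError(f"{where}: participant record missing {exc}") from exc
        for score, value in rec.get("scores", {}).items():
            row[score] = float(value)
        part_rows.append(row)
    participants = pd.DataFrame(part_rows, columns=None if part_rows else ["participant_id", "group"])

    responses = []
    for k, rec in enumerate(doc.get("responses", [])):
        rwhere = f"{where}: response {k}"
        try:
            utterances = tuple(
                _parse_utterance(u, i, where=f"{rwhere}, utterance {i}")
                for i, u in enumerate(rec["utterances"])
            )
            responses.append(
                Response(
                    participant_id=str(rec["participant_id"]),
                    task=str(rec["task"]),
                    prompt_id=str(rec.get("prompt_id", k)),
                    utterances=utterances,
                )
            )
        except KeyError as exc:
            raise CorpusParseError(f"{rwhere}: missing field {exc}") from exc
    return Corpus(responses=responses, participants=participants)


def corpus_to_dict(corpus: Corpus) -> dict:
    participants = []
    for _, row in corpus.participants.iterrows():
        scores = {
            m: float(row[m]) for m in corpus.clinical_measures if pd.notna(row.get(m))
        }
        participants.append(
            {"id": row["participant_id"], "group": row.get("group", ""), "scores": scores}
        )
    responses = []
    for resp in corpus.responses:
        responses.append(
            {
                "participant_id": resp.participant_id,
                "task": resp.task,
                "prompt_id": resp.prompt_id,
                "utterances": [
                    {
                        "utterance_id": utt.utterance_id,
                        "tokens": [
                            {"surface": t.surface, "lemma": t.lemma, "pos": t.pos, "index": t.index}
                            for t in utt.tokens
                        ],
                        "frames": [
                            {
                                "predicate": list(f.predicate),
                                "predicate_lemma": f.predicate_lemma,
                                "args": {lab: list(span) for lab, span in f.arguments.items()},
                            }
                            for f in utt.frames
                        ],
                    }
                    for utt in resp.utterances
                ],
            }
        )
    return {"participants": participants, "responses": responses}


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus to the JSON transcript schema (round-trip safe)."""
    Path(path).write_text(json.dumps(corpus_to_dict(corpus), indent=1, sort_keys=True))


def read_conll_utterances(path: str | Path) -> list[Utterance]:
    """Read utterances from a CoNLL-style column file.

    One token per line with tab- or whitespace-separated columns
    ``index surface lemma pos``; blank lines separate utterances.  Frames
    are not represented in this format, so the result carries none.
    """
    utterances: list[Utterance] = []
    tokens: list[Token] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            if tokens:
                utterances.append(Utterance(utterance_id=len(utterances), tokens=tuple(tokens)))
                tokens = []
            continue
        cols = line.split()
        if len(cols) < 4:
            raise CorpusParseError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
        tokens.append(Token(surface=cols[1], lemma=cols[2], pos=cols[3], index=int(cols[0])))
    if tokens:
        utterances.append(Utterance(utterance_id=len(utterances), tokens=tuple(tokens)))
    return utterances
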