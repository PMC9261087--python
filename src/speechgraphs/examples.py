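"""Hand-annotated miniature fixtures for documentation and smoke tests.

The annotations below are written out token by token (universal POS tags,
0-based end-exclusive spans) for two classic picture-description
utterances, so the expected graphs can be stated exactly:

``cookie_jar_response`` — "The kid is grabbing the cookie jar."
  structural: kid -> grab -> cookie -> jar
  semantic:   grab -> kid, grab -> cookie jar, kid -> cookie jar

``two_frame_response`` — "I see a chair." + the sentence above
  semantic: see -> i, see -> chair, i -> chair,
            grab -> kid, grab -> cookie jar, kid -> cookie jar
"""

from __future__ import annotations

import pandas as pd

from .corpus_model import Corpus, Response, SRLFrame, Token, Utterance

__all__ = [
    "cookie_jar_utterance",
    "cookie_jar_response",
    "see_chair_utterance",
    "two_frame_response",
    "example_corpus",
]


def cookie_jar_utterance(utterance_id: int = 0) -> Utterance:
    """"The kid is grabbing the cookie jar." with one grab-frame."""
    tokens = (
        Token("The", "the", "DET", 0),
        Token("kid", "kid", "NOUN", 1),
        Token("is", "be", "AUX", 2),
        Token("grabbing", "grab", "VERB", 3),
        Token("the", "the", "DET", 4),
        Token("cookie", "cookie", "NOUN", 5),
        Token("jar", "jar", "NOUN", 6),
    )
    frame = SRLFrame(predicate=(3, 4), predicate_lemma="grab", arguments={"A0": (0, 2), "A1": (4, 7)})
    return Utterance(utterance_id=utterance_id, tokens=tokens, frames=(frame,))


def see_chair_utterance(utterance_id: int = 0) -> Utterance:
    """"I see a chair." with one see-frame."""
    tokens = (
        Token("I", "i", "PRON", 0),
        Token("see", "see", "VERB", 1),
        Token("a", "a", "DET", 2),
        Token("chair", "chair", "NOUN", 3),
    )
    frame = SRLFrame(predicate=(1, 2), predicate_lemma="see", arguments={"A0": (0, 1), "A1": (2, 4)})
    return Utterance(utterance_id=utterance_id, tokens=tokens, frames=(frame,))


def cookie_jar_response(participant_id: str = "P000", task: str = "picture") -> Response:
    return Response(
        participant_id=participant_id, task=task, prompt_id="cookie",
        utterances=(cookie_jar_utterance(),),
    )


def two_frame_response(participant_id: str = "P000", task: str = "picture") -> Response:
    return Response(
        participant_id=participant_id, task=task, prompt_id="scene",
        utterances=(see_chair_utterance(0), cookie_jar_utterance(1)),
    )


def example_corpus() -> Corpus:
    """A one-participant corpus wrapping both fixture responses."""
    participants = pd.DataFrame(
        [{"participant_id": "P000", "group": "PS-", "bprs_total": 22.0}]
    )
    return Corpus(
        responses=[cookie_jar_response(), two_frame_response()], participants=participants
    )
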