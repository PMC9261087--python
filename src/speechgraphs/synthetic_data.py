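"""Seeded generators of annotated transcripts and test designs.

Real clinical transcripts are not redistributable, so every pipeline stage
is exercised on synthetic corpora that emulate the shape of elicited
speech: multi-utterance responses to picture-description and open-ended
narrative prompts (picture responses average ~110 words, narratives ~162,
with ~10-word utterances), a Zipf-distributed content vocabulary,
per-utterance predicate-argument frames with variable A0/A1/A2 presence,
and a configurable tendency to repeat recent words (perseveration).

Group effects are injected through two knobs tied to a per-participant
latent severity: cases sample from a shrunken vocabulary (smaller, denser
graphs) and repeat more.  Clinical scores (BPRS/SANS/TLC-like) are linear
in the same latent plus Gaussian noise, so features causally downstream of
the knobs correlate with the scores.  Generated text is lemma-only
(surface = lemma): graph construction consumes lemmas and POS tags, so
morphological variation would be untested dead weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_model import Corpus, Response, SRLFrame, Token, Utterance

__all__ = [
    "ResponseParams",
    "GeneratorConfig",
    "generate_response",
    "generate_cohort",
    "collinear_matrix",
    "population_vifs",
]

_FUNCTION_WORDS = (
    ("the", "DET"),
    ("a", "DET"),
    ("of", "ADP"),
    ("in", "ADP"),
    ("and", "CCONJ"),
    ("be", "AUX"),
    ("um", "INTJ"),
)

_CONTENT_POS = ("NOUN", "VERB", "ADJ", "ADV")
_CONTENT_POS_P = (0.45, 0.3, 0.15, 0.1)


@dataclass(frozen=True)
class ResponseParams:
    """Shape of a single generated response."""

    utterances_mean: float = 11.0  # ~110 words / ~10-word utterances
    tokens_mean: float = 10.0
    content_fraction: float = 0.65
    vocab_size: int = 120
    zipf_exponent: float = 1.0
    frames_mean: float = 1.5
    p_a0: float = 0.9
    p_a1: float = 0.7
    p_a2: float = 0.2
    repetition_rate: float = 0.1  # chance the next content lemma repeats a recent one
    repetition_horizon: int = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level settings.

    Defaults mirror a mid-sized clinical speech study: two groups (cases
    labeled PS+, controls PS-), three picture-description and two narrative
    responses per participant, narrative responses ~1.5x longer.  The case
    group's vocabulary is multiplied by ``vocab_shrink ** severity`` and
    its repetition rate by ``repetition_inflation ** severity``, where
    severity is a per-participant latent (cases ~ N(1, 0.25), controls
    ~ N(0, 0.25), truncated at 0).  All randomness flows from ``seed``.
    """

    n_cases: int = 81
    n_controls: int = 124
    picture_responses: int = 3
    narrative_responses: int = 2
    narrative_length_factor: float = 1.5
    base: ResponseParams = field(default_factory=ResponseParams)
    vocab_shrink: float = 0.6
    repetition_inflation: float = 1.0
    severity_sd: float = 0.5
    clinical_noise_sd: float = 4.0
    seed: int = 0

    def null_config(self) -> "GeneratorConfig":
        """Same cohort with every group effect switched off."""
        return replace(self, vocab_shrink=1.0, repetition_inflation=1.0)


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks**-exponent
    return p / p.sum()


def _draw_content_lemma(
    params: ResponseParams, rng: np.random.Generator, recent: list[str], probs: np.ndarray
) -> str:
    if recent and rng.random() < params.repetition_rate:
        return recent[rng.integers(len(recent))]
    rank = rng.choice(params.vocab_size, p=probs)
    return f"w{rank + 1}"


def generate_response(
    params: ResponseParams,
    rng: np.random.Generator,
    *,
    participant_id: str = "P000",
    task: str = "picture",
    prompt_id: str = "p0",
) -> Response:
    """Generate one annotated response.

    Each utterance draws ~``tokens_mean`` tokens, a content/function mix;
    content lemmas come from a Zipf-distributed vocabulary with optional
    repetition of recently used lemmas.  Frames pick a generated verb as
    predicate and single-noun spans as arguments according to the A0/A1/A2
    presence probabilities.
    """
    probs = _zipf_probs(params.vocab_size, params.zipf_exponent)
    n_utts = max(1, int(rng.poisson(params.utterances_mean)))
    recent: list[str] = []
    utterances = []
    for uid in range(n_utts):
        n_tokens = max(2, int(rng.poisson(params.tokens_mean)))
        tokens: list[Token] = []
        verb_positions: list[int] = []
        noun_positions: list[int] = []
        for i in range(n_tokens):
            if rng.random() < params.content_fraction:
                lemma = _draw_content_lemma(params, rng, recent, probs)
                recent.append(lemma)
                if len(recent) > params.repetition_horizon:
                    recent.pop(0)
                pos = _CONTENT_POS[rng.choice(len(_CONTENT_POS), p=_CONTENT_POS_P)]
                if pos == "VERB":
                    verb_positions.append(i)
                elif pos == "NOUN":
                    noun_positions.append(i)
                tokens.append(Token(surface=lemma, lemma=lemma, pos=pos, index=i))
            else:
                word, pos = _FUNCTION_WORDS[rng.integers(len(_FUNCTION_WORDS))]
                tokens.append(Token(surface=word, lemma=word, pos=pos, index=i))
        frames: list[SRLFrame] = []
        n_frames = min(int(rng.poisson(params.frames_mean)), len(verb_positions))
        preds = rng.choice(len(verb_positions), size=n_frames, replace=False) if n_frames else []
        for k in sorted(preds):
            v = verb_positions[k]
            args: dict[str, tuple[int, int]] = {}
            candidates = [i for i in noun_positions]
            rng.shuffle(candidates)
            for label, p_label in (("A0", params.p_a0), ("A1", params.p_a1), ("A2", params.p_a2)):
                if candidates and rng.random() < p_label:
                    i = candidates.pop()
                    args[label] = (i, i + 1)
            frames.append(
                SRLFrame(predicate=(v, v + 1), predicate_lemma=tokens[v].lemma, arguments=args)
            )
        utterances.append(Utterance(utterance_id=uid, tokens=tuple(tokens), frames=tuple(frames)))
    return Response(
        participant_id=participant_id, task=task, prompt_id=prompt_id, utterances=tuple(utterances)
    )


def _participant_params(
    config: GeneratorConfig, severity: float, task: str
) -> ResponseParams:
    base = config.base
    vocab = max(2, int(round(base.vocab_size * config.vocab_shrink**severity)))
    rep = min(1.0, base.repetition_rate * config.repetition_inflation**severity)
    utts = base.utterances_mean * (config.narrative_length_factor if task == "narrative" else 1.0)
    return replace(base, vocab_size=vocab, repetition_rate=rep, utterances_mean=utts)


def generate_cohort(config: GeneratorConfig | None = None) -> Corpus:
    """Generate a two-group corpus with participant metadata and clinical
    scores.  Deterministic given ``config.seed``."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0]))
    part_rows = []
    responses: list[Response] = []
    groups = ["PS+"] * config.n_cases + ["PS-"] * config.n_controls
    for k, group in enumerate(groups):
        pid = f"P{k:03d}"
        center = 1.0 if group == "PS+" else 0.0
        severity = max(0.0, float(rng.normal(center, config.severity_sd)))
        noise = config.clinical_noise_sd
        part_rows.append(
            {
                "participant_id": pid,
                "group": group,
                "bprs_total": 22.0 + 20.0 * severity + rng.normal(0, noise),
                "sans_total": 4.0 + 26.0 * severity + rng.normal(0, noise),
                "tlc_total": 4.0 + 12.0 * severity + rng.normal(0, noise),
            }
        )
        for task, count in (("picture", config.picture_responses), ("narrative", config.narrative_responses)):
            params = _participant_params(config, severity, task)
            for j in range(count):
                responses.append(
                    generate_response(
                        params, rng, participant_id=pid, task=task, prompt_id=f"{task}{j}"
                    )
                )
    return Corpus(responses=responses, participants=pd.DataFrame(part_rows))


# ---------------------------------------------------------------------------
# Collinear design matrices for the VIF harness
# ---------------------------------------------------------------------------


def collinear_matrix(
    n_rows: int, spec: dict[str, dict | None], seed: int = 0
) -> pd.DataFrame:
    """Design matrix with a known redundancy structure.

    ``spec`` maps column names to either ``None`` (independent standard
    normal) or ``{"parents": [...], "coeffs": [...], "noise_sd": s}``
    (linear combination of earlier columns plus Gaussian noise).  The
    population VIF of a derived column is available in closed form via
    `population_vifs`.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name, rule in spec.items():
        if rule is None:
            data[name] = rng.standard_normal(n_rows)
        else:
            coeffs = rule.get("coeffs", [1.0] * len(rule["parents"]))
            col = np.zeros(n_rows)
            for parent, c in zip(rule["parents"], coeffs):
                col += c * data[parent]
            col += rng.standard_normal(n_rows) * rule["noise_sd"]
            data[name] = col
    return pd.DataFrame(data)


def population_vifs(spec: dict[str, dict | None]) -> dict[str, float]:
    """Closed-form population VIFs for a `collinear_matrix` spec in which
    derived columns depend only on independent parents: for such a column,
    R^2 = var(signal) / (var(signal) + noise_sd^2) and VIF = 1/(1 - R^2).
    Parents of a derived column share its VIF scaled by their contribution;
    this helper reports the derived-column value and 1.0 for columns no
    derived column touches."""
    touched: dict[str, float] = {name: 1.0 for name in spec}
    for name, rule in spec.items():
        if rule is None:
            continue
        coeffs = np.asarray(rule.get("coeffs", [1.0] * len(rule["parents"])), dtype=float)
        signal_var = float((coeffs**2).sum())
        r2 = signal_var / (signal_var + rule["noise_sd"] ** 2)
        touched[name] = np.inf if rule["noise_sd"] == 0 else 1.0 / (1.0 - r2)
    return touched
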