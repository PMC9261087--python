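"""Static and dynamic (moving-window) feature extraction.

Static features come from one graph over the whole response.  Dynamic
features slide a fixed-length window over the response — 30 content tokens
with a 1-token step for structural graphs, 3 utterances with a 1-utterance
step for semantic graphs — build one graph per window, and average each of
the nine metrics across windows.  Responses shorter than one window
contribute a single whole-sample window and are flagged.

`extract_all` assembles the participant x task feature table: per response
four blocks (static/dynamic x structural/semantic), then an unweighted
mean across each participant's responses of the same task.  The table
always carries exactly 36 feature columns named
``{S,D}_{SEQ,AP}_{metric}`` (SEQ = sequential/structural, AP =
action-predication/semantic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus_model import (
    DEFAULT_FILLED_PAUSES,
    Corpus,
    Response,
    Utterance,
    content_lemmas,
)
from .graph_builder import SpeechGraph, build_semantic, build_structural
from .graph_metrics import METRIC_NAMES, GraphFeatures, MetricConfig, compute_features

__all__ = [
    "WindowSpec",
    "Window",
    "PipelineConfig",
    "FEATURE_COLUMNS",
    "DEFAULT_STRUCTURAL_WINDOW",
    "DEFAULT_SEMANTIC_WINDOW",
    "windows",
    "static_features",
    "dynamic_features",
    "response_features",
    "extract_all",
]

logger = logging.getLogger(__name__)

MODE_CODES = {"static": "S", "dynamic": "D"}
TYPE_CODES = {"structural": "SEQ", "semantic": "AP"}

#: The fixed 36-column inventory: 9 metrics x {static, dynamic} x
#: {structural, semantic}.
FEATURE_COLUMNS = [
    f"{MODE_CODES[mode]}_{TYPE_CODES[gtype]}_{metric}"
    for gtype in ("structural", "semantic")
    for mode in ("static", "dynamic")
    for metric in METRIC_NAMES
]


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry: ``unit`` is ``tokens`` (content lemmas,
    cross-utterance) or ``utterances``; ``length`` and ``step`` in that
    unit."""

    unit: str
    length: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.unit not in ("tokens", "utterances"):
            raise ValueError(f"unit must be 'tokens' or 'utterances', got {self.unit!r}")
        if self.length < 1 or self.step < 1:
            raise ValueError("window length and step must be >= 1")


DEFAULT_STRUCTURAL_WINDOW = WindowSpec(unit="tokens", length=30, step=1)
DEFAULT_SEMANTIC_WINDOW = WindowSpec(unit="utterances", length=3, step=1)


@dataclass(frozen=True)
class Window:
    """One window's input: a lemma slice (tokens unit) or utterance slice."""

    items: tuple
    offset: int
    short_sample: bool = False


@dataclass
class PipelineConfig:
    """Extraction settings: window geometry, metric/baseline settings, and
    the content-word stoplist."""

    structural_window: WindowSpec = DEFAULT_STRUCTURAL_WINDOW
    semantic_window: WindowSpec = DEFAULT_SEMANTIC_WINDOW
    metrics: MetricConfig = field(default_factory=MetricConfig)
    stoplist: frozenset[str] = DEFAULT_FILLED_PAUSES
    on_unknown_pos: str = "warn"


def windows(response: Response, spec: WindowSpec, *, config: PipelineConfig | None = None) -> list[Window]:
    """Slice a response into moving windows.

    Full-length windows start at offsets 0, step, 2*step, ...; a sample
    shorter than one window yields exactly one whole-sample window with
    ``short_sample=True``.
    """
    config = config or PipelineConfig()
    if spec.unit == "tokens":
        items: Sequence = content_lemmas(
            response, stoplist=config.stoplist, on_unknown_pos=config.on_unknown_pos
        )
    else:
        items = response.utterances
    n = len(items)
    if n < spec.length:
        return [Window(items=tuple(items), offset=0, short_sample=True)]
    return [
        Window(items=tuple(items[off : off + spec.length]), offset=off)
        for off in range(0, n - spec.length + 1, spec.step)
    ]


def _build(graph_type: str, items, provenance: dict, config: PipelineConfig) -> SpeechGraph:
    if graph_type == "structural":
        return build_structural(items, provenance)
    return build_semantic(items, provenance, stoplist=config.stoplist)


def static_features(
    response: Response, graph_type: str, config: PipelineConfig | None = None
) -> GraphFeatures:
    """Nine metrics of the single whole-response graph."""
    config = config or PipelineConfig()
    provenance = {
        "participant": response.participant_id,
        "task": response.task,
        "prompt": response.prompt_id,
        "mode": "static",
    }
    if graph_type == "structural":
        items: Sequence = content_lemmas(
            response, stoplist=config.stoplist, on_unknown_pos=config.on_unknown_pos
        )
    else:
        items = response.utterances
    return compute_features(_build(graph_type, items, provenance, config), config.metrics)


def dynamic_features(
    response: Response,
    graph_type: str,
    spec: WindowSpec | None = None,
    config: PipelineConfig | None = None,
) -> GraphFeatures:
    """Mean of the nine metrics over moving windows.

    Each window's z-scores are computed against a baseline matched to that
    window's own (NN, NE).  Degenerate flags are unioned across windows.
    """
    config = config or PipelineConfig()
    if spec is None:
        spec = config.structural_window if graph_type == "structural" else config.semantic_window
    per_window: list[GraphFeatures] = []
    flags: set[str] = set()
    for win in windows(response, spec, config=config):
        provenance = {
            "participant": response.participant_id,
            "task": response.task,
            "prompt": response.prompt_id,
            "mode": "dynamic",
            "window_offset": win.offset,
        }
        feats = compute_features(_build(graph_type, win.items, provenance, config), config.metrics)
        per_window.append(feats)
        flags |= set(feats.degenerate_flags)
        if win.short_sample:
            flags.add("short_sample")
    means = {
        name: float(np.mean([f.as_dict()[name] for f in per_window])) for name in METRIC_NAMES
    }
    return GraphFeatures(
        nn=means["NN"],
        ne=means["NE"],
        diameter=means["DIAMETER"],
        aspl=means["ASPL"],
        awd=means["AWD"],
        density=means["DENSITY"],
        lscc=means["LSCC"],
        lsccz=means["LSCCZ"],
        asplz=means["ASPLZ"],
        degenerate_flags=frozenset(flags),
    )


def response_features(response: Response, config: PipelineConfig | None = None) -> dict[str, float]:
    """The four 9-metric blocks of one response, keyed by the 36 canonical
    column names, plus a ``_flags`` entry with the unioned flags."""
    config = config or PipelineConfig()
    row: dict = {}
    all_flags: set[str] = set()
    for gtype in ("structural", "semantic"):
        for mode in ("static", "dynamic"):
            if mode == "static":
                feats = static_features(response, gtype, config)
            else:
                feats = dynamic_features(response, gtype, config=config)
            prefix = f"{MODE_CODES[mode]}_{TYPE_CODES[gtype]}"
            for metric, value in feats.as_dict().items():
                row[f"{prefix}_{metric}"] = value
            all_flags |= set(feats.degenerate_flags)
    row["_flags"] = all_flags
    return row


def extract_all(corpus: Corpus, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Participant x task feature table with the 36 canonical columns.

    Per (participant, task) cell: the unweighted mean across that
    participant's responses of that task.  Metadata columns:
    ``n_responses`` and ``flagged`` (True when any contributing graph was
    degenerate or short-sampled).
    """
    config = config or PipelineConfig()
    records: dict[tuple[str, str], list[dict]] = {}
    for response in corpus.responses:
        logger.info(
            "extracting %s/%s (%s)", response.participant_id, response.prompt_id, response.task
        )
        row = response_features(response, config)
        records.setdefault((response.participant_id, response.task), []).append(row)
    out_rows = []
    for (pid, task), rows in sorted(records.items()):
        rec: dict = {"participant_id": pid, "task": task, "n_responses": len(rows)}
        flags: set[str] = set().union(*(r["_flags"] for r in rows))
        for col in FEATURE_COLUMNS:
            rec[col] = float(np.mean([r[col] for r in rows]))
        rec["flagged"] = bool(flags)
        out_rows.append(rec)
    columns = ["participant_id", "task", "n_responses", *FEATURE_COLUMNS, "flagged"]
    return pd.DataFrame(out_rows, columns=columns)
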