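"""Shared helper for the synthetic-cohort parameter-recovery experiment.

One experiment iteration: generate a two-group cohort, compute dynamic
structural NN per participant (mean over that participant's picture
responses), and run the controls-vs-cases Mann-Whitney comparison.  A
cohort counts as a detection when p < 0.05 with the constructed sign
(controls stochastically larger, RBC > 0).

Baseline z-scores are skipped here because only NN is inspected; that
leaves the measured feature bit-identical while avoiding thousands of
irrelevant random-graph simulations per cohort.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from speechgraphs import (
    GeneratorConfig,
    MetricConfig,
    PipelineConfig,
    Response,
    Token,
    Utterance,
    dynamic_features,
    generate_cohort,
    mann_whitney_rbc,
)


def lemma_only_response(lemmas, participant_id="P0", task="picture", prompt_id="x") -> Response:
    tokens = tuple(Token(w, w, "NOUN", i) for i, w in enumerate(lemmas))
    return Response(
        participant_id=participant_id, task=task, prompt_id=prompt_id,
        utterances=(Utterance(0, tokens, ()),),
    )


def cohort_dynamic_nn_comparison(config: GeneratorConfig):
    """Controls-vs-cases comparison of mean dynamic structural NN."""
    corpus = generate_cohort(config)
    pipeline = PipelineConfig(metrics=MetricConfig(replicates=1, seed=config.seed, zscores=False))
    per_participant: dict[str, list[float]] = {}
    for resp in corpus.responses:
        if resp.task != "picture":
            continue
        feats = dynamic_features(resp, "structural", config=pipeline)
        per_participant.setdefault(resp.participant_id, []).append(feats.nn)
    groups = dict(zip(corpus.participants["participant_id"], corpus.participants["group"]))
    controls = [np.mean(v) for p, v in per_participant.items() if groups[p] == "PS-"]
    cases = [np.mean(v) for p, v in per_participant.items() if groups[p] == "PS+"]
    return mann_whitney_rbc(controls, cases)


def power_experiment(config: GeneratorConfig, n_cohorts: int, base_seed: int) -> list[dict]:
    """Run the comparison over ``n_cohorts`` independently seeded cohorts."""
    out = []
    for k in range(n_cohorts):
        seed = int(
            np.random.SeedSequence([base_seed, k]).generate_state(1, dtype=np.uint32)[0]
            % (2**31)
        )
        res = cohort_dynamic_nn_comparison(replace(config, seed=seed))
        out.append({"p": res.p_value, "rbc": res.rbc,
                    "detected": res.p_value < 0.05 and res.rbc > 0})
    return out
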