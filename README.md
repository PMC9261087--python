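# speechgraphs

Graph-theoretic features of spoken language for computational psychiatry.

Disorganized and impoverished speech are core clinical features of
psychosis. A productive way to quantify them is to turn a transcript into a
graph and measure its shape. `speechgraphs` implements two complementary
graph representations of SRL-annotated transcripts:

- **Structural (sequential) graphs** connect each lemmatized content word to
  the next in spoken order, across utterance boundaries. "The kid is
  grabbing the cookie jar." becomes the chain
  `kid → grab → cookie → jar`.
- **Semantic (action–predication) graphs** are built from PropBank-style
  semantic role labels within each utterance: predication edges link the
  verb predicate to each core argument (`grab → kid`, `grab → cookie jar`),
  and action edges link the actor A0 to the undergoers A1/A2
  (`kid → cookie jar`). Multiword arguments stay single nodes.

Both graphs are directed, simple, and integer-weighted — the first
occurrence of a relation weighs 1 and every repetition adds 1.

Nine features are computed per graph, in three domains:

| Domain | Features |
|---|---|
| Size | NN (nodes), NE (edges), diameter, ASPL (mean directed shortest path over reachable pairs) |
| Connectedness | AWD (in+out strength per node, `2·Σw/NN`), density (`NE/(NN·(NN−1))`), LSCC (largest strongly connected component) |
| Organization | LSCCZ, ASPLZ — z-scores of LSCC and ASPL against 1000 directed Erdős–Rényi G(n, m) graphs matched on NN and NE |

Each feature comes in a **static** variant (whole-response graph) and a
**dynamic** variant (mean over moving windows: 30 content tokens / step 1
for structural, 3 utterances / step 1 for semantic), for 9 × 2 × 2 = 36
features per participant and task. The statistics layer covers
Mann–Whitney U group comparisons with rank-biserial effect sizes
(RBC = 2·U₁/(n₁n₂) − 1), Spearman correlations with dimensional clinical
scores, Bonferroni correction, and a layered stepwise variance-inflation-
factor (VIF < 5) protocol that prunes redundant features domain-by-domain,
then per graph type, then per task.

Because clinical transcripts are not redistributable, the package ships a
seeded synthetic-cohort generator (`speechgraphs.synthetic_data`) that
emulates elicited speech — Zipf vocabulary, ~10-word utterances,
per-utterance SRL frames — with tunable group effects and clinical scores,
so the full pipeline is testable end to end.

## Worked example

```python
from speechgraphs import build_structural, build_semantic, content_lemmas, \
    compute_features, MetricConfig
from speechgraphs.examples import cookie_jar_response, two_frame_response

resp = cookie_jar_response()          # "The kid is grabbing the cookie jar."
print(content_lemmas(resp))           # ['kid', 'grab', 'cookie', 'jar']
print(build_structural(content_lemmas(resp)).edges)
# {('kid', 'grab'): 1, ('grab', 'cookie'): 1, ('cookie', 'jar'): 1}
print(build_semantic(resp.utterances).edges)
# {('grab', 'kid'): 1, ('grab', 'cookie jar'): 1, ('kid', 'cookie jar'): 1}

scene = two_frame_response()          # adds "I see a chair."
g = build_semantic(scene.utterances)
print(compute_features(g, MetricConfig(replicates=1000, seed=1)))
# GraphFeatures(nn=6.0, ne=6.0, diameter=1.0, aspl=1.0, awd=2.0,
#               density=0.2, lscc=1.0, lsccz=-0.92..., asplz=-1.78...,
#               degenerate_flags=frozenset())
```

The semantic graph of the two-sentence scene has 6 nodes and 6 edges; with
every node reachable in one hop from its predicate but no cycles, its LSCC
is 1 and both z-scores are negative — it is organized in smaller, tighter
components than a size-matched random digraph, the typical signature of
semantic speech graphs.

At the cohort scale:

```bash
speechgraphs simulate --config sim.yaml --out corpus.json --seed 7
speechgraphs extract  --corpus corpus.json --out features.csv --replicates 1000 --seed 7
speechgraphs analyze  --features features.csv --meta corpus.json --out report/
```

`extract` writes the 36-column participant × task feature table; `analyze`
writes `comparisons.csv` (U, p, RBC per feature and task),
`correlations.csv` (Spearman grid against clinical measures),
`vif_layers.csv` (removal order and survivors at every VIF layer) and a
heatmap-ready long-format correlation table.

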