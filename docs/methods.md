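# Methods

## Input model

The pipeline consumes pre-annotated transcripts: ordered utterances
(segmented upstream, e.g. manually on syntactic completeness), tokens with
surface form, lowercased lemma and universal POS tag, and PropBank-style
SRL frames restricted to the core arguments A0, A1, A2. Spans are 0-based
and end-exclusive. The SRL backend is pluggable through the
`annotate_plaintext` adapter contract; labels outside {A0, A1, A2} are
dropped with a warning. Nothing in the core requires a live tagger — the
JSON transcript schema is the interface.

Content words are nouns, proper nouns, pronouns, non-auxiliary verbs
(`VERB` but not `AUX`), adjectives and adverbs; determiners, adpositions,
conjunctions, particles, interjections, numerals, punctuation and residual
tags are excluded. A configurable lexical stoplist (default: "um", "uh"
and variants) additionally removes filled pauses whatever their tag, since
transcription conventions vary; the default list is a convention of this
package, not a claim about any particular corpus. Unknown tags are
excluded with a warning by default (strict mode raises). Node identity is
exact string equality of the lowercased lemma. Argument spans are rendered
as space-joined content lemmas; a span left empty by the filter falls back
to its full lemmatized text so that every tagged argument yields a node.

## Graph construction

Both graph types are directed simple digraphs with integer edge weights
(first occurrence 1, +1 per repetition). Self-loops — identical
consecutive lemmas, or frames in which an argument label coincides with
the predicate or the other argument — are skipped, because the random null
model and the density formula assume simple digraphs and disfluency
repetitions would otherwise dominate; the endpoints still count as nodes.

Structural graphs chain the content-lemma sequence of a whole response (or
window) across utterance boundaries. Semantic graphs are built within
utterances: per frame, predication edges predicate→A0/A1/A2 and action
edges A0→A1 and A0→A2. A2 is treated as a second undergoer — it receives a
predication edge always and an action edge from A0 when A0 exists, but no
A1→A2 edge. Overlapping frames are processed independently; each frame
instance counts. Edge weights accumulate over the graph's whole scope
(response or window) rather than resetting per utterance; the relation
multiset is order-free, so permuting utterances never changes a semantic
graph.

## Features

Nine metrics per graph. Distances are unweighted directed hop counts —
weights enter only AWD — because weighted degree and path measures
describe different things and mixing them would conflate repetition with
distance. ASPL averages, and diameter maximizes, over ordered node pairs
with a finite path (self-pairs excluded). Graphs where no such pair exists
(no edges) report 0 with a `no_finite_path` flag; the empty graph reports
all zeros with `empty_graph`. AWD = 2·Σw/NN; density = NE/(NN·(NN−1)) for
NN ≥ 2, else 0; LSCC is the largest strongly connected component's node
count (≥ 1 for any non-empty graph). Path computations are delegated to
igraph; the test suite pins them to an independent pure-Python BFS /
mutual-reachability oracle.

### Random-graph normalization

LSCCZ and ASPLZ are z-scores against directed Erdős–Rényi G(n, m) graphs
matched on (NN, NE) — the fixed-edge-count variant, since matching "the
same NN and NE" is exactly what G(n, m) does. Default 1000 replicates.
Replicates are drawn by sampling m distinct ordered non-diagonal index
pairs uniformly, and their ASPL/LSCC use the identical finite-pairs
conventions as the observed graph, so the comparison is like-with-like.
Baseline SDs use the population (n-denominator) convention; at 1000
replicates the choice is immaterial but it must be fixed for determinism.
A zero-SD baseline (e.g. a complete digraph admits exactly one G(n, m))
yields z = 0 with a `zero_sd_*` flag rather than NaN, keeping window
averages defined.

Seeding: each (NN, NE) size class derives its own seed from the master
seed via `SeedSequence([seed, nn, ne])`, so results are independent of
processing order, and baselines are memoized by (nn, ne, replicates,
seed). Moving windows revisit the same sizes constantly; memoization is
what makes desk-scale runs fast. A TSV cache format is provided for
persisting baselines across runs.

## Static and dynamic extraction

Static features come from one graph per whole response. Dynamic features
slide a window — 30 content tokens, step 1, for structural graphs; 3
utterances, step 1, for semantic graphs (the closest equivalent given
~10-word utterances) — build a graph per window, compute all nine metrics
per window (z-scores against that window's own (NN, NE)), and average
them. A response shorter than one window yields a single whole-sample
window flagged `short_sample` rather than being dropped; analyses can
exclude flagged rows. Window geometry is configurable.

Per (participant, task), feature blocks are averaged unweighted across
that participant's responses of the task. The resulting table always has
exactly 36 feature columns, `{S,D}_{SEQ,AP}_{metric}`, regardless of data.

## Statistics

Group comparisons use the Mann–Whitney U test with rank-biserial
correlation RBC = 2·U₁/(n₁n₂) − 1 as effect size; the sign convention is
explicit in `AnalysisConfig.group_order` — positive means the first-named
group (default PS−, i.e. no psychosis-spectrum diagnosis) is
stochastically larger. p-values are exact by enumeration when n₁·n₂ ≤ 400
and no ties are present, otherwise a tie-corrected normal approximation.
Fully tied data yields p = 1, RBC = 0. Spearman correlations use mid-ranks
with a t-approximation p; zero-variance inputs are flagged degenerate with
rho reported as 0.

Bonferroni family sizes are configuration, defaulting to features × tasks
for comparisons and features × measures × tasks for correlations. The
corrected level is applied as a strict threshold.

VIF_i = 1/(1 − R²_i) from an intercepted OLS of feature i on the others
(statsmodels). Exact collinearity (1 − R² below 1e−12) reports +∞;
constant columns are dropped with a warning before fitting. Stepwise
pruning removes the arg-max VIF until all survive below the threshold
(default 5), breaking ties by column-name order for determinism. The
layered protocol runs per task: stage 1 within each (graph type, mode,
domain) block, where domains are size = {NN, NE, DIAMETER, ASPL},
connectedness = {AWD, DENSITY, LSCC}, organization = {LSCCZ, ASPLZ};
stage 2 pools stage-1 survivors per graph type; stage 3 pools per task for
the final set. Correlations are computed for the final survivors by
default (`correlate="all"` for the full grid).

## Synthetic cohorts

The generator emulates the shape of elicited clinical speech, not its
content: two groups (PS+/PS−, default 81/124), three picture-description
and two open-ended narrative responses per participant, ~11 utterances of
~10 tokens for picture responses and 1.5× longer narratives (matching the
~110 vs ~162 word averages typical of these tasks), a 65% content-word
fraction, a 120-lemma Zipf(1.0) content vocabulary, ~1.5 frames per
utterance with A0/A1/A2 presence probabilities 0.9/0.7/0.2, and a 10%
chance that the next content lemma repeats one of the last five.

Group effects run through a per-participant latent severity (cases
~N(1, 0.5), controls ~N(0, 0.5), truncated at 0): the case vocabulary is
multiplied by `vocab_shrink^severity` (default 0.6 — smaller, denser
graphs) and the repetition rate by `repetition_inflation^severity`
(default 1.0, i.e. off). Clinical scores (BPRS/SANS/TLC-like totals) are
linear in the same latent plus Gaussian noise (sd 4), the simplest model
under which rank-correlation recovery is predictable. Surface form equals
lemma — graph construction never reads morphology, so generating it would
be untested dead weight.

What passing tests on this generator do show: the pipeline recovers
constructed group differences with the right sign and stays calibrated
under the null. What they do not show: performance on real disfluent,
coreferent, topically coherent speech — the generator has no discourse
structure, no coreference, and lexical choice is i.i.d. Zipf apart from
the repetition knob.

## Problem sizes and numerical choices

Unit tests run at reduced sizes (tens of participants, 20–100 baseline
replicates); the self-consistency and parameter-recovery checks use
1000-replicate baselines, 200 null graphs, 1000 null Mann–Whitney
replicates, and 100 cohorts of 40+40 participants (picture task), sizes at
which the Monte-Carlo error of each checked quantity is several times
smaller than its acceptance margin. The power experiment skips z-score
baselines since only NN is inspected; `MetricConfig(zscores=False)` leaves
the measured feature bit-identical.

Known limitations: no coreference resolution (repeated mentions of one
referent stay distinct nodes unless lexically identical); no adjunct
arguments (AM-*); no weighted-path variants; utterance segmentation is
taken as given; the finite-pairs ASPL convention, while applied
identically to observed and random graphs, is one of several defensible
treatments of unreachable pairs and is isolated behind the metrics module
for sensitivity analysis.
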