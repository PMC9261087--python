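"""The nine speech-graph features and their random-graph normalization.

Size: number of nodes (NN), number of distinct edges (NE), diameter and
average shortest path length (ASPL) as unweighted directed hop counts.
Connectedness: average weighted degree (AWD), density, and the node count
of the largest strongly connected component (LSCC).
Organization: z-scores of LSCC and ASPL (LSCCZ, ASPLZ) against directed
Erdős–Rényi G(n, m) graphs matched on NN and NE (1000 replicates by
default).

Path-based measures average over ordered node pairs with a finite directed
path (self-pairs excluded); graphs with no such pair report 0 with a
degenerate flag.  The identical convention is applied to the random
baseline so z-scores compare like with like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import igraph as ig
import numpy as np

from .graph_builder import SpeechGraph

__all__ = [
    "GraphFeatures",
    "RandomBaseline",
    "MetricConfig",
    "BaselineCache",
    "METRIC_NAMES",
    "compute_basic",
    "random_baseline",
    "zscores",
    "compute_features",
]

#: Canonical metric order used throughout feature tables.
METRIC_NAMES = ("NN", "NE", "DIAMETER", "ASPL", "AWD", "DENSITY", "LSCC", "LSCCZ", "ASPLZ")


@dataclass(frozen=True)
class GraphFeatures:
    nn: float
    ne: float
    diameter: float
    aspl: float
    awd: float
    density: float
    lscc: float
    lsccz: float = 0.0
    asplz: float = 0.0
    degenerate_flags: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "NN": self.nn,
            "NE": self.ne,
            "DIAMETER": self.diameter,
            "ASPL": self.aspl,
            "AWD": self.awd,
            "DENSITY": self.density,
            "LSCC": self.lscc,
            "LSCCZ": self.lsccz,
            "ASPLZ": self.asplz,
        }


@dataclass(frozen=True)
class RandomBaseline:
    """Moments of ASPL and LSCC over directed G(n, m) replicates."""

    nn: int
    ne: int
    replicates: int
    seed: int
    mean_aspl: float
    sd_aspl: float
    mean_lscc: float
    sd_lscc: float


class BaselineCache:
    """Memoizes baselines by (nn, ne, replicates, seed).

    Moving windows repeat graph sizes heavily, so caching turns thousands
    of 1000-replicate simulations into a few hundred.  The cache can be
    persisted as a TSV with columns nn, ne, replicates, seed, mean_aspl,
    sd_aspl, mean_lscc, sd_lscc.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[int, int, int, int], RandomBaseline] = {}

    def __len__(self) -> int:
        return len(self._store)

    def get_or_compute(self, nn: int, ne: int, replicates: int, seed: int) -> RandomBaseline:
        key = (nn, ne, replicates, seed)
        if key not in self._store:
            self._store[key] = random_baseline(nn, ne, replicates=replicates, seed=seed)
        return self._store[key]

    def save_tsv(self, path: str | Path) -> None:
        lines = ["nn\tne\treplicates\tseed\tmean_aspl\tsd_aspl\tmean_lscc\tsd_lscc"]
        for b in self._store.values():
            lines.append(
                f"{b.nn}\t{b.ne}\t{b.replicates}\t{b.seed}\t"
                f"{b.mean_aspl!r}\t{b.sd_aspl!r}\t{b.mean_lscc!r}\t{b.sd_lscc!r}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def load_tsv(self, path: str | Path) -> None:
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            nn, ne, reps, seed, ma, sa, ml, sl = line.split("\t")
            b = RandomBaseline(int(nn), int(ne), int(reps), int(seed),
                               float(ma), float(sa), float(ml), float(sl))
            self._store[(b.nn, b.ne, b.replicates, b.seed)] = b


@dataclass
class MetricConfig:
    """Replicate count and seed policy for the random baselines.

    Each (nn, ne) size class gets its own deterministic seed derived from
    the master seed, so results do not depend on the order in which graphs
    are processed.  ``zscores=False`` skips baseline simulation entirely
    (LSCCZ/ASPLZ report 0 with a flag), which is useful when only raw
    metrics are needed.
    """

    replicates: int = 1000
    seed: int = 0
    zscores: bool = True
    cache: BaselineCache = field(default_factory=BaselineCache)

    def baseline_seed(self, nn: int, ne: int) -> int:
        ss = np.random.SeedSequence([int(self.seed), int(nn), int(ne)])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Basic metrics
# ---------------------------------------------------------------------------


def _path_metrics(g: ig.Graph) -> tuple[float, float, float, set[str]]:
    """(diameter, aspl, lscc) of an igraph digraph under the finite-pairs
    convention, plus degenerate flags."""
    flags: set[str] = set()
    if g.vcount() == 0:
        return 0.0, 0.0, 0.0, {"empty_graph"}
    if g.ecount() == 0:
        return 0.0, 0.0, 1.0, {"no_finite_path"}
    aspl = g.average_path_length(directed=True, unconn=True)
    if math.isnan(aspl):  # edges exist but no ordered pair is reachable: impossible, but guard
        aspl = 0.0
        flags.add("no_finite_path")
    diameter = float(g.diameter(directed=True, unconn=True))
    lscc = float(max(len(c) for c in g.connected_components(mode="strong")))
    return diameter, float(aspl), lscc, flags


def compute_basic(graph: SpeechGraph) -> GraphFeatures:
    """The seven size and connectedness metrics of one speech graph.

    AWD is total in+out strength per node, 2 * (sum of edge weights) / NN.
    Density is NE / (NN * (NN - 1)).  The z-score fields are left at 0 with
    a flag; use `compute_features` for the full nine-metric record.
    """
    g, _ = graph.to_igraph()
    diameter, aspl, lscc, flags = _path_metrics(g)
    nn = graph.nn
    ne = graph.ne
    awd = 2.0 * graph.total_weight / nn if nn else 0.0
    density = ne / (nn * (nn - 1)) if nn >= 2 else 0.0
    return GraphFeatures(
        nn=float(nn),
        ne=float(ne),
        diameter=diameter,
        aspl=aspl,
        awd=awd,
        density=density,
        lscc=lscc,
        degenerate_flags=frozenset(flags | {"zscores_not_computed"}),
    )


# ---------------------------------------------------------------------------
# Random baseline and z-scores
# ---------------------------------------------------------------------------


def _sample_gnm_edges(nn: int, ne: int, rng: np.random.Generator) -> np.ndarray:
    """ne distinct ordered pairs (i, j), i != j, uniform over all such sets."""
    idx = rng.choice(nn * (nn - 1), size=ne, replace=False)
    rows = idx // (nn - 1)
    cols = idx % (nn - 1)
    cols = cols + (cols >= rows)  # skip the diagonal
    return np.column_stack([rows, cols])


def random_baseline(nn: int, ne: int, replicates: int = 1000, seed: int = 0) -> RandomBaseline:
    """Simulate directed Erdős–Rényi G(n, m) graphs matched on (NN, NE) and
    return mean and population SD of ASPL and LSCC.

    Replicate graphs are uniform over simple digraphs with ``nn`` nodes and
    ``ne`` edges (no self-loops); per-replicate metrics follow exactly the
    `compute_basic` conventions.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    max_edges = nn * (nn - 1)
    if not (0 <= ne <= max_edges):
        raise ValueError(f"ne={ne} out of range [0, {max_edges}] for nn={nn}")
    rng = np.random.default_rng(seed)
    aspls = np.empty(replicates)
    lsccs = np.empty(replicates)
    for r in range(replicates):
        if nn == 0:
            aspls[r], lsccs[r] = 0.0, 0.0
            continue
        edges = _sample_gnm_edges(nn, ne, rng)
        g = ig.Graph(n=nn, edges=edges.tolist(), directed=True)
        _, aspls[r], lsccs[r], _ = _path_metrics(g)
    return RandomBaseline(
        nn=nn,
        ne=ne,
        replicates=replicates,
        seed=seed,
        mean_aspl=float(aspls.mean()),
        sd_aspl=float(aspls.std(ddof=0)),
        mean_lscc=float(lsccs.mean()),
        sd_lscc=float(lsccs.std(ddof=0)),
    )


def zscores(
    aspl: float, lscc: float, baseline: RandomBaseline, nn: int, ne: int
) -> tuple[float, float, frozenset[str]]:
    """(asplz, lsccz) of observed values against a matched baseline.

    A zero-SD baseline (e.g. a complete graph, where only one G(n, m)
    exists) yields z = 0 with a flag rather than NaN, keeping downstream
    window averaging defined.
    """
    if (baseline.nn, baseline.ne) != (nn, ne):
        raise ValueError(
            f"baseline is for (nn={baseline.nn}, ne={baseline.ne}), observed graph has "
            f"(nn={nn}, ne={ne})"
        )
    flags: set[str] = set()
    if baseline.sd_aspl > 0:
        asplz = (aspl - baseline.mean_aspl) / baseline.sd_aspl
    else:
        asplz = 0.0
        flags.add("zero_sd_aspl")
    if baseline.sd_lscc > 0:
        lsccz = (lscc - baseline.mean_lscc) / baseline.sd_lscc
    else:
        lsccz = 0.0
        flags.add("zero_sd_lscc")
    return asplz, lsccz, frozenset(flags)


def compute_features(graph: SpeechGraph, config: MetricConfig | None = None) -> GraphFeatures:
    """The full nine-metric record for one speech graph, with LSCCZ/ASPLZ
    normalized against a seeded, memoized G(NN, NE) baseline."""
    config = config or MetricConfig()
    basic = compute_basic(graph)
    flags = set(basic.degenerate_flags) - {"zscores_not_computed"}
    if not config.zscores:
        return replace(basic, degenerate_flags=frozenset(flags | {"zscores_skipped"}))
    if graph.nn == 0:
        return replace(basic, degenerate_flags=frozenset(flags))
    baseline = config.cache.get_or_compute(
        graph.nn, graph.ne, config.replicates, config.baseline_seed(graph.nn, graph.ne)
    )
    asplz, lsccz, zflags = zscores(basic.aspl, basic.lscc, baseline, graph.nn, graph.ne)
    return replace(
        basic, asplz=asplz, lsccz=lsccz, degenerate_flags=frozenset(flags | set(zflags))
    )
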