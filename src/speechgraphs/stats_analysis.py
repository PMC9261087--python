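"""Group comparisons, dimensional correlations, and redundancy pruning.

Psychosis-group differences in each graph feature are tested with the
Mann-Whitney U test; rank-biserial correlation (RBC = 2*U1/(n1*n2) - 1) is
the effect size, positive when the first group is stochastically larger.
Associations with dimensional clinical measures use Spearman's rank-order
correlation.  Significance levels are Bonferroni-adjusted within
configurable test families.

Redundant features are pruned by stepwise variance-inflation-factor (VIF)
elimination: the feature with the highest VIF is removed until all VIFs
fall below a threshold (default 5).  `layered_vif` applies this first
within each feature domain (size, connectedness, organization) per graph
type and mode, then across the pooled survivors per graph type, then
across the pooled survivors per task.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .feature_pipeline import FEATURE_COLUMNS

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "VIFReport",
    "StatReport",
    "AnalysisConfig",
    "DOMAIN_MAP",
    "mann_whitney_rbc",
    "spearman",
    "bonferroni",
    "vif",
    "vif_stepwise",
    "layered_vif",
    "run_analysis",
]

logger = logging.getLogger(__name__)

#: Feature domains used by the layered VIF protocol.
DOMAIN_MAP = {
    "size": ("NN", "NE", "DIAMETER", "ASPL"),
    "connectedness": ("AWD", "DENSITY", "LSCC"),
    "organization": ("LSCCZ", "ASPLZ"),
}


def _metric_domain(column: str) -> str:
    metric = column.split("_", 2)[2]
    for domain, metrics in DOMAIN_MAP.items():
        if metric in metrics:
            return domain
    raise KeyError(f"column {column!r} has no known metric suffix")


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    task: str
    u_statistic: float
    p_value: float
    rbc: float
    n1: int
    n2: int
    significant_bonferroni: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    clinical_measure: str
    task: str
    rho: float
    p_value: float
    n: int
    significant_uncorrected: bool = False
    significant_bonferroni: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class VIFReport:
    layer: str
    stage: int
    input_features: tuple[str, ...]
    removal_order: tuple[tuple[str, float], ...]
    survivors: dict[str, float]
    threshold: float


@dataclass
class StatReport:
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    vif_reports: list[VIFReport]

    def vif_long(self) -> pd.DataFrame:
        rows = []
        for rep in self.vif_reports:
            for feat, v in rep.removal_order:
                rows.append(
                    {"layer": rep.layer, "stage": rep.stage, "feature": feat,
                     "status": "removed", "vif": v}
                )
            for feat, v in rep.survivors.items():
                rows.append(
                    {"layer": rep.layer, "stage": rep.stage, "feature": feat,
                     "status": "survived", "vif": v}
                )
        return pd.DataFrame(rows, columns=["layer", "stage", "feature", "status", "vif"])

    def to_files(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.comparisons.to_csv(outdir / "comparisons.csv", index=False)
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        self.vif_long().to_csv(outdir / "vif_layers.csv", index=False)
        heat = self.correlations.pivot_table(
            index="feature", columns=["task", "clinical_measure"], values="rho"
        )
        heat.to_csv(outdir / "correlation_heatmap.csv")


@dataclass
class AnalysisConfig:
    """Analysis settings.

    ``group_order`` fixes the RBC sign convention: positive RBC means the
    first-named group is stochastically larger.  Bonferroni family sizes
    default to (features x tasks) for group comparisons and (features x
    measures x tasks) for correlations; pass explicit sizes to override.
    """

    alpha: float = 0.05
    group_order: tuple[str, str] = ("PS-", "PS+")
    vif_threshold: float = 5.0
    comparison_family: int | None = None
    correlation_family: int | None = None
    correlate: str = "surviving"  # or "all"


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def mann_whitney_rbc(
    values_group1: Sequence[float],
    values_group2: Sequence[float],
    *,
    feature: str = "",
    task: str = "",
    exact_max_pairs: int = 400,
) -> GroupComparison:
    """Mann-Whitney U with rank-biserial effect size.

    U1 counts cross-group pairs where a group-1 value exceeds a group-2
    value (ties count 1/2); RBC = 2*U1/(n1*n2) - 1.  The p value is exact
    (full enumeration) when n1*n2 <= ``exact_max_pairs`` and there are no
    ties, else a tie-corrected normal approximation.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and x.size * y.size <= exact_max_pairs) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    p = float(res.pvalue)
    if not math.isfinite(p):  # all values tied in both groups
        p = 1.0
    rbc = 2.0 * u1 / (x.size * y.size) - 1.0
    return GroupComparison(
        feature=feature, task=task, u_statistic=u1, p_value=min(p, 1.0), rbc=rbc,
        n1=int(x.size), n2=int(y.size),
    )


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    feature: str = "",
    clinical_measure: str = "",
    task: str = "",
) -> CorrelationResult:
    """Spearman rank-order correlation (mid-ranks for ties, two-sided p).

    A zero-variance input yields rho = 0 with ``degenerate=True`` instead
    of NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            feature=feature, clinical_measure=clinical_measure, task=task,
            rho=0.0, p_value=1.0, n=int(x.size), degenerate=True,
        )
    rho, p = st.spearmanr(x, y)
    if not math.isfinite(p):
        p = 1.0
    return CorrelationResult(
        feature=feature, clinical_measure=clinical_measure, task=task,
        rho=float(rho), p_value=float(min(p, 1.0)), n=int(x.size),
    )


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Variance inflation factors
# ---------------------------------------------------------------------------

_VIF_EPS = 1e-12


def vif(feature_matrix: pd.DataFrame) -> pd.Series:
    """VIF_i = 1 / (1 - R^2_i) from regressing feature i on all others
    (with intercept).  Exact collinearity reports +inf.  Constant columns
    are dropped with a warning before computation."""
    X = feature_matrix.astype(float)
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        warnings.warn(f"dropping zero-variance columns before VIF: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 non-constant features")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        r2 = sm.OLS(X[col].to_numpy(), others).fit().rsquared
        out[col] = math.inf if (1.0 - r2) < _VIF_EPS else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_stepwise(
    feature_matrix: pd.DataFrame, threshold: float = 5.0, *, layer: str = "", stage: int = 0
) -> VIFReport:
    """Remove the highest-VIF feature until all VIFs are below threshold.

    Ties at the maximum are broken by column-name order (lexicographically
    first removed).  Tables with a single feature survive trivially.
    """
    X = feature_matrix.astype(float)
    input_features = tuple(X.columns)
    removal_order: list[tuple[str, float]] = []
    while True:
        if X.shape[1] < 2:
            survivors = {c: 1.0 for c in X.columns}
            break
        vifs = vif(X)
        X = X[[c for c in X.columns if c in vifs.index]]  # constant columns dropped inside vif
        vmax = vifs.max()
        if vmax < threshold:
            survivors = {c: float(vifs[c]) for c in X.columns}
            break
        worst = sorted(c for c in vifs.index if vifs[c] == vmax)[0]
        removal_order.append((worst, float(vmax)))
        logger.info("VIF layer %s: removing %s (VIF=%.3g)", layer, worst, vmax)
        X = X.drop(columns=[worst])
    return VIFReport(
        layer=layer, stage=stage, input_features=input_features,
        removal_order=tuple(removal_order), survivors=survivors, threshold=threshold,
    )


def layered_vif(
    feature_table: pd.DataFrame, threshold: float = 5.0
) -> list[VIFReport]:
    """The three-stage VIF protocol, run separately per task.

    Stage 1 prunes within each (graph type, mode, domain) block; stage 2
    pools stage-1 survivors per graph type and prunes again; stage 3 pools
    stage-2 survivors across graph types per task for the final set.
    Empty blocks are skipped with a log entry.
    """
    reports: list[VIFReport] = []
    for task in sorted(feature_table["task"].unique()):
        sub = feature_table.loc[feature_table["task"] == task]
        stage2_pools: dict[str, list[str]] = {}
        for gcode in ("SEQ", "AP"):
            for mcode in ("S", "D"):
                for domain, metrics in DOMAIN_MAP.items():
                    cols = [f"{mcode}_{gcode}_{m}" for m in metrics if f"{mcode}_{gcode}_{m}" in sub.columns]
                    cols = [c for c in cols if np.ptp(sub[c].to_numpy().astype(float)) > 0]
                    layer = f"{task}/{gcode}/{mcode}/{domain}"
                    if not cols:
                        logger.info("VIF layer %s: empty block, skipped", layer)
                        continue
                    rep = vif_stepwise(sub[cols], threshold, layer=layer, stage=1)
                    reports.append(rep)
                    stage2_pools.setdefault(gcode, []).extend(rep.survivors)
        stage3_pool: list[str] = []
        for gcode, cols in sorted(stage2_pools.items()):
            layer = f"{task}/{gcode}"
            rep = vif_stepwise(sub[cols], threshold, layer=layer, stage=2)
            reports.append(rep)
            stage3_pool.extend(rep.survivors)
        if stage3_pool:
            rep = vif_stepwise(sub[stage3_pool], threshold, layer=task, stage=3)
            reports.append(rep)
    return reports


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


def run_analysis(
    feature_table: pd.DataFrame,
    participants: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> StatReport:
    """Group comparisons, layered VIF pruning, and Spearman correlations
    for a participant x task feature table.

    ``participants`` must carry ``participant_id``, ``group`` and numeric
    clinical-score columns.  Correlations cover the final VIF survivors per
    task by default (``config.correlate="all"`` for the full grid).
    """
    config = config or AnalysisConfig()
    merged = feature_table.merge(participants, on="participant_id", how="left", validate="m:1")
    feature_cols = [c for c in FEATURE_COLUMNS if c in feature_table.columns]
    tasks = sorted(merged["task"].unique())
    measures = [
        c for c in participants.columns
        if c not in ("participant_id", "group") and pd.api.types.is_numeric_dtype(participants[c])
    ]

    comp_family = config.comparison_family or (len(feature_cols) * len(tasks))
    comp_alpha = bonferroni(config.alpha, comp_family)
    g1, g2 = config.group_order
    comp_rows = []
    for task in tasks:
        sub = merged.loc[merged["task"] == task]
        v1 = sub.loc[sub["group"] == g1]
        v2 = sub.loc[sub["group"] == g2]
        if v1.empty or v2.empty:
            logger.info("task %s: a group is empty, comparisons skipped", task)
            continue
        for feat in feature_cols:
            res = mann_whitney_rbc(v1[feat], v2[feat], feature=feat, task=task)
            comp_rows.append(
                {
                    "feature": feat, "task": task, "u_statistic": res.u_statistic,
                    "p_value": res.p_value, "rbc": res.rbc, "n1": res.n1, "n2": res.n2,
                    "significant_bonferroni": res.p_value < comp_alpha,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["feature", "task", "u_statistic", "p_value", "rbc", "n1", "n2",
                 "significant_bonferroni"],
    )

    vif_reports = layered_vif(feature_table, config.vif_threshold)
    final_survivors = {
        rep.layer: list(rep.survivors) for rep in vif_reports if rep.stage == 3
    }

    corr_rows = []
    corr_targets = {
        task: (final_survivors.get(task, feature_cols) if config.correlate == "surviving" else feature_cols)
        for task in tasks
    }
    corr_family = config.correlation_family or (
        sum(len(v) for v in corr_targets.values()) * max(len(measures), 1)
    )
    corr_alpha = bonferroni(config.alpha, max(corr_family, 1))
    for task in tasks:
        sub = merged.loc[merged["task"] == task]
        for feat in corr_targets[task]:
            for measure in measures:
                mask = sub[measure].notna()
                if mask.sum() < 3:
                    logger.info("task %s: measure %s has <3 observations, skipped", task, measure)
                    continue
                res = spearman(
                    sub.loc[mask, feat], sub.loc[mask, measure],
                    feature=feat, clinical_measure=measure, task=task,
                )
                corr_rows.append(
                    {
                        "feature": feat, "clinical_measure": measure, "task": task,
                        "rho": res.rho, "p_value": res.p_value, "n": res.n,
                        "significant_uncorrected": (not res.degenerate) and res.p_value < config.alpha,
                        "significant_bonferroni": (not res.degenerate) and res.p_value < corr_alpha,
                        "degenerate": res.degenerate,
                    }
                )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["feature", "clinical_measure", "task", "rho", "p_value", "n",
                 "significant_uncorrected", "significant_bonferroni", "degenerate"],
    )
    return StatReport(comparisons=comparisons, correlations=correlations, vif_reports=vif_reports)
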