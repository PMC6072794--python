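"""Generic comparison machinery: chi-square tests of proportions, fixed
effects ANOVA (one-way and two-factor crossed), ordinary least squares, and
the covariate-vs-centrality association used for plant-biomass analyses.

The repeated-measures / split-plot error strata of field designs are out of
scope; fixed-effects factorial ANOVA stands in and is documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .otu import OtuTable

logger = logging.getLogger("conetstab")


@dataclass
class GroupComparisonResult:
    statistic_name: str
    statistic: float
    df: tuple
    p: float
    effect_direction: str = "none"


def chi2_proportions(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> GroupComparisonResult:
    """Two-sided Pearson chi-square test of two proportions (1 df).

    No Yates continuity correction by default (immaterial at the sample
    sizes this analysis meets; available behind the flag).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("need 0 <= k <= n and n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    p1, p2 = k1 / n1, k2 / n2
    direction = "A>B" if p1 > p2 else ("B>A" if p2 > p1 else "none")
    return GroupComparisonResult("chi2", float(chi2), (1,), float(p), direction)


def anova_oneway(values, groups) -> GroupComparisonResult:
    """One-way fixed-effects ANOVA.

    Degenerate all-equal data (SS_total = 0) is reported as F = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(list(groups))
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if min(len(s) for s in samples) < 2:
        raise ValueError("every group needs at least 2 values")
    if np.allclose(values, values[0]):
        a, n = len(levels), len(values)
        return GroupComparisonResult("F", 0.0, (a - 1, n - a), 1.0)
    f, p = stats.f_oneway(*samples)
    a, n = len(levels), len(values)
    means = [s.mean() for s in samples]
    direction = "A>B" if len(levels) == 2 and means[0] > means[1] else (
        "B>A" if len(levels) == 2 and means[1] > means[0] else "none"
    )
    return GroupComparisonResult("F", float(f), (a - 1, n - a), float(p), direction)


def anova_twoway(values, factor_a, factor_b) -> pd.DataFrame:
    """Two-factor crossed ANOVA with interaction, Type I sums of squares.

    Intended for balanced (sampling x drought) designs; unbalanced input is
    accepted with a warning (the Type I decomposition then depends on term
    order, which is A, B, A:B).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(values, float),
         "a": np.asarray(list(factor_a)),
         "b": np.asarray(list(factor_b))}
    )
    counts = df.groupby(["a", "b"], observed=True).size()
    if counts.nunique() > 1:
        logger.warning("anova_twoway: unbalanced design; Type I order is a, b, a:b")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    return sm.stats.anova_lm(model, typ=1)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    df: int


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares with a two-sided t test on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue ** 2),
        float(res.pvalue), len(x) - 2,
    )


def slopes_difference(x1, y1, x2, y2) -> GroupComparisonResult:
    """Difference-of-slopes t test between two independent regressions.

    t = (b1 - b2) / sqrt(se1^2 + se2^2) on df = (n1 - 2) + (n2 - 2); the
    interaction contrast standing in for an ANCOVA group x covariate term.
    """
    r1 = stats.linregress(np.asarray(x1, float), np.asarray(y1, float))
    r2 = stats.linregress(np.asarray(x2, float), np.asarray(y2, float))
    se = np.hypot(r1.stderr, r2.stderr)
    if se == 0:
        raise ValueError("zero standard error; degenerate inputs")
    t = (r1.slope - r2.slope) / se
    df = (len(np.asarray(x1)) - 2) + (len(np.asarray(x2)) - 2)
    p = 2 * stats.t.sf(abs(t), df)
    direction = "A>B" if r1.slope > r2.slope else ("B>A" if r2.slope > r1.slope else "none")
    return GroupComparisonResult("t", float(t), (df,), float(p), direction)


# -- covariate vs centrality ----------------------------------------------

def covariate_node_association(
    graph: nx.Graph,
    table: OtuTable,
    covariate,
    node_metrics: pd.DataFrame,
    groups: pd.Series | None = None,
) -> dict:
    """Per-node Spearman correlation with a covariate, then |rho| ~ centrality.

    For every network node, correlate its abundances across the community's
    samples with the covariate (e.g. D. glomerata biomass); regress |rho| on
    normalised degree and on betweenness. When ``groups`` maps nodes to two
    groups (e.g. drought vs control network membership), a difference-of-
    slopes contrast between the groups is added for each metric.
    """
    covariate = np.asarray(covariate, float)
    if np.all(covariate == covariate[0]):
        raise ValueError("constant covariate")
    if len(covariate) != table.shape[1]:
        raise ValueError("covariate must align with table samples")
    rel = table.relative_abundance()
    rows = []
    for v in graph.nodes:
        rho, p = stats.spearmanr(rel.loc[v].to_numpy(), covariate)
        rows.append({"taxon_id": v, "rho": rho, "p": p, "abs_rho": abs(rho)})
    per_node = pd.DataFrame(rows).set_index("taxon_id", drop=False)
    out: dict = {"per_node": per_node, "regressions": {}}
    merged = per_node.join(node_metrics[["normalised_degree", "betweenness"]])
    for metric in ("normalised_degree", "betweenness"):
        if merged[metric].var() == 0:
            logger.warning("covariate association: %s has zero variance", metric)
            continue
        out["regressions"][metric] = linreg(merged[metric], merged["abs_rho"])
        if groups is not None:
            lv = pd.unique(groups.loc[merged.index])
            if len(lv) == 2:
                m1 = merged[groups.loc[merged.index] == lv[0]]
                m2 = merged[groups.loc[merged.index] == lv[1]]
                if len(m1) >= 3 and len(m2) >= 3:
                    out["regressions"][f"{metric}_interaction"] = slopes_difference(
                        m1[metric], m1["abs_rho"], m2[metric], m2["abs_rho"]
                    )
    return out
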