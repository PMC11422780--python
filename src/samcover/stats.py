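"""Study-level statistics: box summaries, ANOVA + Tukey HSD grouping,
correlations.

Product comparisons follow the classic recipe: a one-way ANOVA F-test over
products (no Welch correction), followed — when the ANOVA rejects at the
chosen significance — by all-pairs Tukey HSD.  Products are then partitioned
into groups as the connected components of the "not significantly
different" relation.  This construction is deterministic and invariant to
the order of input rows and product labels; because it is a transitive
closure it can merge products that are not pairwise similar through a
chain, so the full pairwise matrix is always reported alongside the groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SampleTable",
    "BoxSummary",
    "GroupingResult",
    "box_summary",
    "compare_products",
    "correlate",
]

SAMPLE_COLUMNS = ["model", "product", "metric", "value"]


@dataclass
class SampleTable:
    """Tidy table of one value per (model, product, metric)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        dup = df.duplicated(subset=["model", "product", "metric"])
        if dup.any():
            raise ValueError("duplicate (model, product, metric) rows in sample table")
        self.frame = df.reset_index(drop=True)

    def metric(self, name: str) -> pd.DataFrame:
        sel = self.frame[self.frame["metric"] == name]
        if sel.empty:
            raise ValueError(f"no rows for metric {name!r}")
        return sel

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class BoxSummary:
    """Five-number summary plus mean, per product."""

    table: pd.DataFrame  # index: product; columns: min, q1, median, q3, max, mean, n


@dataclass
class GroupingResult:
    """ANOVA + Tukey grouping of products for one metric."""

    metric: str
    anova_f: float
    anova_p: float
    alpha: float
    pairwise: pd.DataFrame  # columns: product_a, product_b, meandiff, p_adj, significant
    groups: list  # list of tuples of product labels, ordered by group mean
    group_means: list = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def ranking(self) -> str:
        """Table layout string: groups in parentheses, smallest mean first."""
        parts = []
        for grp in self.groups:
            if len(grp) == 1:
                parts.append(grp[0])
            else:
                parts.append("(" + ",".join(grp) + ")")
        return ", ".join(parts)


def box_summary(table: SampleTable, metric: str) -> BoxSummary:
    """Quartiles (linear interpolation between order statistics), mean, range."""
    sel = table.metric(metric)
    rows = {}
    for product, grp in sel.groupby("product", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"empty group for product {product!r}")
        rows[product] = {
            "min": float(v.min()),
            "q1": float(np.percentile(v, 25, method="linear")),
            "median": float(np.percentile(v, 50, method="linear")),
            "q3": float(np.percentile(v, 75, method="linear")),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "n": int(v.size),
        }
    return BoxSummary(table=pd.DataFrame(rows).T)


def _connected_components(labels: list, edges: set) -> list:
    """Components of the graph over ``labels`` with undirected ``edges``."""
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict = {}
    for lab in labels:
        comps.setdefault(find(lab), []).append(lab)
    return [sorted(c) for c in comps.values()]


def compare_products(
    table: SampleTable, metric: str, alpha: float = 0.05
) -> GroupingResult:
    """One-way ANOVA across products; Tukey HSD grouping when significant.

    Groups are the connected components of the non-significant-pair
    relation, ordered by ascending group mean (smallest first, matching the
    ranking-table convention).  Requires >= 2 products with >= 2 samples
    each.
    """
    sel = table.metric(metric)
    products = sorted(sel["product"].unique())
    if len(products) < 2:
        raise ValueError("need at least 2 products to compare")
    samples = {p: sel.loc[sel["product"] == p, "value"].to_numpy(float) for p in products}
    for p, v in samples.items():
        if v.size < 2:
            raise ValueError(f"product {p!r} has fewer than 2 samples")
    if all(np.ptp(v) == 0 for v in samples.values()):
        if len({v[0] for v in samples.values()}) > 1:
            raise ValueError(
                "zero within-group variance everywhere; the F statistic is undefined"
            )
        # All values identical across the board: trivially one group.
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = sps.f_oneway(*(samples[p] for p in products))
        f_stat, p_value = float(f_stat), float(p_value)

    means = {p: float(v.mean()) for p, v in samples.items()}

    if p_value < alpha:
        values = np.concatenate([samples[p] for p in products])
        labels = np.concatenate([[p] * samples[p].size for p in products])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        pairwise = pd.DataFrame(
            {
                "product_a": res["group1"].astype(str),
                "product_b": res["group2"].astype(str),
                "meandiff": res["meandiff"].astype(float),
                "p_adj": np.asarray(tukey.pvalues, dtype=float),
                "significant": np.asarray(tukey.reject, dtype=bool),
            }
        ).sort_values(["product_a", "product_b"], ignore_index=True)
        edges = {
            (row.product_a, row.product_b)
            for row in pairwise.itertuples()
            if not row.significant
        }
        groups = _connected_components(products, edges)
    else:
        pairwise = pd.DataFrame(
            columns=["product_a", "product_b", "meandiff", "p_adj", "significant"]
        )
        groups = [sorted(products)]

    group_means = [float(np.mean([means[p] for p in g])) for g in groups]
    order = np.argsort(group_means)
    groups = [tuple(sorted(groups[i], key=lambda p: means[p])) for i in order]
    group_means = [group_means[i] for i in order]
    return GroupingResult(
        metric=metric,
        anova_f=f_stat,
        anova_p=p_value,
        alpha=alpha,
        pairwise=pairwise,
        groups=groups,
        group_means=group_means,
    )


def correlate(x, y) -> tuple[float, tuple[float, float]]:
    """Pearson r and least-squares line (slope, intercept) of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return r, (float(slope), float(intercept))
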