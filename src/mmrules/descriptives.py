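"""Cohort descriptive statistics and the comorbidity network summary.

Produces the classic "participant characteristics" table — per category:
group size, multimorbidity (MCD) count and percentage, with a Pearson
chi-square p-value for categorical variables and a two-sample t-test for
continuous ones — and a disease co-occurrence network where node size
tracks prevalence, node colour the share of that disease's patients with
MCD, and edges the number of participants with both diseases, filtered
at a minimum link count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd
from scipy import stats

from .cohort import ConditionProfile

#: age bands used in the characteristics table
AGE_BANDS = ((46, 55), (56, 65), (66, 75), (76, None))


def age_band(age: int) -> str:
    for lo, hi in AGE_BANDS:
        if hi is None and age >= lo:
            return f">{lo - 1}"
        if hi is not None and lo <= age <= hi:
            return f"{lo}-{hi}"
    return "<46"


def chi_square_2xk(table: pd.DataFrame | list[list[int]], correction: bool = False):
    """Pearson chi-square on a contingency table (no continuity correction
    by default, the usual choice for k > 2; pass correction=True for the
    Yates-corrected 2x2 variant)."""
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return chi2, p, dof


def format_p(p: float, threshold: float = 0.001) -> str:
    """Report tiny p-values as '<0.001' rather than a literal zero."""
    if p != p:  # NaN: no test possible
        return ""
    return f"<{threshold}" if p < threshold else f"{p:.3f}"


def prevalence_table(cohort: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """MCD prevalence by category with chi-square tests.

    ``cohort`` needs one row per participant with a boolean ``mcd``
    column and the categorical columns in ``variables`` (default: sex,
    age_band, education, stratum). A continuous ``age`` column, when
    present, is compared between MCD and non-MCD participants by t-test
    and appended as its own row.
    """
    if variables is None:
        variables = [v for v in ("sex", "age_band", "education", "stratum") if v in cohort]
    n_total = len(cohort)
    if n_total == 0:
        raise ValueError("empty cohort")
    rows = []
    for var in variables:
        sub = cohort[cohort[var].notna()]
        ct = pd.crosstab(sub[var], sub["mcd"]).reindex(columns=[False, True], fill_value=0)
        # degenerate tables (an all-zero margin, or a single category) have no test
        if len(ct) < 2 or (ct.to_numpy().sum(axis=0) == 0).any():
            p = float("nan")
        else:
            _, p, _ = chi_square_2xk(ct.to_numpy())
        for cat, row in ct.iterrows():
            n = int(row.sum())
            if n == 0:
                continue
            rows.append(
                {
                    "variable": var,
                    "category": str(cat),
                    "n": n,
                    "n_pct": round(100 * n / n_total, 1),
                    "mcd_count": int(row.get(True, 0)),
                    "mcd_pct": round(100 * row.get(True, 0) / n, 1),
                    "p": format_p(p),
                }
            )
    if "age" in cohort:
        with_mcd = cohort.loc[cohort["mcd"], "age"]
        without = cohort.loc[~cohort["mcd"], "age"]
        t_p = stats.ttest_ind(with_mcd, without, equal_var=False).pvalue
        rows.append(
            {
                "variable": "age",
                "category": "mean(sd)",
                "n": n_total,
                "n_pct": 100.0,
                "mcd_count": int(cohort["mcd"].sum()),
                "mcd_pct": round(100 * cohort["mcd"].mean(), 1),
                "p": format_p(float(t_p)),
            }
        )
    rows.append(
        {
            "variable": "total",
            "category": "all",
            "n": n_total,
            "n_pct": 100.0,
            "mcd_count": int(cohort["mcd"].sum()),
            "mcd_pct": round(100 * cohort["mcd"].mean(), 1),
            "p": "",
        }
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComorbidityNetwork:
    """Disease co-occurrence summary: per-disease prevalence and MCD share,
    pairwise co-occurrence counts above the minimum-link threshold."""

    n: int
    nodes: dict[str, dict[str, float]]  # disease -> {count, prevalence_pct, mcd_pct}
    edges: dict[tuple[str, str], int]  # sorted pair -> co-occurrence count
    min_links: int

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for d, attrs in self.nodes.items():
            g.add_node(d, **attrs)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"disease_a": a, "disease_b": b, "count": w}
            for (a, b), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "count"])


def network_summary(profiles: list[ConditionProfile], min_links: int = 20) -> ComorbidityNetwork:
    """Build the co-occurrence network over all participants.

    Node prevalence is the disease count over the cohort size; node MCD%
    is the fraction of that disease's patients who have MCD; an edge is
    kept only when at least ``min_links`` participants have both diseases.
    """
    n = len(profiles)
    disease_count: dict[str, int] = {}
    disease_mcd: dict[str, int] = {}
    pair_count: dict[tuple[str, str], int] = {}
    for p in profiles:
        for d in p.conditions:
            disease_count[d] = disease_count.get(d, 0) + 1
            if p.mcd:
                disease_mcd[d] = disease_mcd.get(d, 0) + 1
        for a, b in combinations(sorted(p.conditions), 2):
            pair_count[(a, b)] = pair_count.get((a, b), 0) + 1
    nodes = {
        d: {
            "count": c,
            "prevalence_pct": 100 * c / n,
            "mcd_pct": 100 * disease_mcd.get(d, 0) / c,
        }
        for d, c in sorted(disease_count.items())
    }
    edges = {pair: c for pair, c in pair_count.items() if c >= min_links}
    return ComorbidityNetwork(n=n, nodes=nodes, edges=edges, min_links=min_links)
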