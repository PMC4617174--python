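"""Signed Pearson co-expression networks over stress time courses.

Each gene's log2 fold-change values are concatenated across all treatments
into one vector on a shared (treatment, timepoint) grid; every gene pair is
scored by the sample Pearson correlation coefficient r with a two-sided
p-value from the exact t transform t = r sqrt((n-2)/(1-r^2)) on n-2 degrees
of freedom.  Edges satisfying |r| > r_min and p < alpha (strict
inequalities) enter an undirected signed graph.  No multiple-testing
correction is applied by default — the conventional raw 0.05 level — but
Benjamini-Hochberg adjustment is available via ``adjust="bh"``.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConstantSeriesError",
    "MisalignedGridError",
    "pearson_r",
    "pcc_pvalue",
    "build_network",
    "network_summary",
    "edges_dataframe",
]

logger = logging.getLogger(__name__)


class ConstantSeriesError(ValueError):
    """Pearson correlation undefined for a zero-variance series."""


class MisalignedGridError(ValueError):
    """Gene profiles do not share one (treatment, timepoint) grid."""


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx == 0.0 or sy == 0.0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    r = float((xd * yd).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def pcc_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson r at sample size n (t transform)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        logger.info("|r| = 1: p-value set to 0 by convention")
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Genes x (treatment, timepoint) wide matrix of log2 fold changes."""
    required = {"gene", "treatment", "timepoint_h", "log2fc"}
    missing = required - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing columns: {sorted(missing)}")
    wide = profiles.pivot_table(
        index="gene", columns=["treatment", "timepoint_h"], values="log2fc",
        aggfunc="first",
    )
    if wide.isna().any().any():
        gene = wide.index[wide.isna().any(axis=1)][0]
        raise MisalignedGridError(
            f"gene {gene!r} lacks values on the shared (treatment, timepoint) grid"
        )
    return wide.sort_index(axis=1)


def build_network(
    profiles: pd.DataFrame,
    r_min: float = 0.5,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> nx.Graph:
    """Thresholded signed Pearson network over concatenated profiles.

    ``profiles`` is the long table produced by
    :func:`famevol.expression.expression_profiles`.  Every gene becomes a
    node; an edge (a, b) with attributes r, p and sign ("+"/"-") is added
    when |r| > ``r_min`` and p < ``alpha``.  Pairs involving a constant
    profile are skipped with a log message.  With ``adjust="bh"`` the
    p-values are Benjamini-Hochberg adjusted before thresholding.
    """
    wide = _profile_matrix(profiles)
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 genes to build a network")
    n = wide.shape[1]
    genes = list(wide.index)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    pairs, rs, ps = [], [], []
    for a, b in combinations(genes, 2):
        try:
            r = pearson_r(wide.loc[a].to_numpy(), wide.loc[b].to_numpy())
        except ConstantSeriesError:
            logger.info("pair (%s, %s) skipped: constant profile", a, b)
            continue
        pairs.append((a, b))
        rs.append(r)
        ps.append(pcc_pvalue(r, n))
    ps_arr = np.asarray(ps)
    if adjust == "bh" and len(ps_arr):
        ps_arr = stats.false_discovery_control(ps_arr, method="bh")
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (a, b), r, p in zip(pairs, rs, ps_arr):
        if abs(r) > r_min and p < alpha:
            graph.add_edge(a, b, r=float(r), p=float(p), sign="+" if r > 0 else "-")
    graph.graph.update(r_min=r_min, alpha=alpha, n_points=n, adjust=adjust)
    return graph


def network_summary(graph: nx.Graph) -> dict:
    """Node/edge counts and the number of negative edges."""
    n_negative = sum(1 for _, _, d in graph.edges(data=True) if d["sign"] == "-")
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_negative_edges": n_negative,
        "r_min": graph.graph.get("r_min"),
        "alpha": graph.graph.get("alpha"),
        "n_points": graph.graph.get("n_points"),
    }


def edges_dataframe(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (gene_a, gene_b, r, p, sign), sorted."""
    rows = [
        (min(a, b), max(a, b), d["r"], d["p"], d["sign"])
        for a, b, d in graph.edges(data=True)
    ]
    return pd.DataFrame(
        sorted(rows), columns=["gene_a", "gene_b", "r", "p", "sign"]
    )
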