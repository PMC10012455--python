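"""ceRNA (circRNA-miRNA-mRNA) network construction and enrichment.

A sponge triplet (c, m, g) is accepted when the miRNA m has at least one
predicted binding site on both the circRNA c and the mRNA g ("shared MRE"
read as shared miRNA identity), all three are differentially expressed,
and the circRNA-mRNA pair is co-expressed: Pearson correlation of
log2(expression + 1) across samples with |r| >= 0.9 and P < 0.01 (t-test
on n - 2 degrees of freedom).  The network is exported with typed nodes
(circRNA / miRNA / mRNA) and typed edges in SIF and GraphML form for
Cytoscape.  Host-gene annotation enrichment uses the hypergeometric upper
tail over a user-supplied term -> genes map.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .quant import bh_adjust


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and the two-sided P from t = r sqrt((n-2)/(1-r^2)).

    Returns (nan, nan) when either vector has zero variance (undefined,
    never silently zero).  Vectors are used as given; co-expression callers
    apply the log2(value+1) transform first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def coexpression_pairs(
    circ_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_min: float = 0.9,
    alpha: float = 0.01,
    log_transform: bool = True,
    positive_only: bool = False,
) -> pd.DataFrame:
    """All circRNA-mRNA pairs passing the co-expression screen.

    Correlation is computed on log2(value + 1) across the shared sample
    columns (vectorised over all pairs).  ``positive_only`` replaces the
    absolute-value criterion with r >= r_min, the directional form predicted
    by the ceRNA hypothesis.
    """
    missing = [c for c in circ_expr.columns if c not in mrna_expr.columns]
    missing += [c for c in mrna_expr.columns if c not in circ_expr.columns]
    if missing:
        raise ValueError(f"sample columns not shared: {sorted(set(missing))}")
    cols = list(circ_expr.columns)
    n = len(cols)
    if n < 3:
        raise ValueError("need >= 3 shared samples")
    X = circ_expr[cols].to_numpy(dtype=float)
    Y = mrna_expr[cols].to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
        Y = np.log2(Y + 1.0)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    keep = (r >= r_min) if positive_only else (np.abs(r) >= r_min)
    keep &= p < alpha
    keep &= np.isfinite(r)
    ci, gi = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "circ": circ_expr.index.to_numpy()[ci],
            "mrna": mrna_expr.index.to_numpy()[gi],
            "r": r[ci, gi],
            "p": p[ci, gi],
        }
    )
    return out.sort_values(["circ", "mrna"], ignore_index=True)


def build_cerna(
    dec: Sequence[str],
    dem: Sequence[str],
    deg: Sequence[str],
    sites: pd.DataFrame,
    coexpr: pd.DataFrame,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Triplets and the typed ceRNA graph.

    ``sites`` needs columns (mirna, target, kind); ``coexpr`` columns
    (circ, mrna, r, p).  A triplet (c, m, g) is emitted iff c in dec, m in
    dem, g in deg, m has a site on c and on g, and (c, g) passed the
    co-expression screen.  Ordering is deterministic.
    """
    dec_s, dem_s, deg_s = set(dec), set(dem), set(deg)
    circ_sites: dict[str, set[str]] = {}
    mrna_sites: dict[str, set[str]] = {}
    for row in sites.itertuples(index=False):
        if row.mirna not in dem_s:
            continue
        if row.kind == "circRNA" and row.target in dec_s:
            circ_sites.setdefault(row.mirna, set()).add(row.target)
        elif row.kind == "mRNA" and row.target in deg_s:
            mrna_sites.setdefault(row.mirna, set()).add(row.target)
    coexpr_map = {
        (row.circ, row.mrna): (row.r, row.p)
        for row in coexpr.itertuples(index=False)
        if row.circ in dec_s and row.mrna in deg_s
    }
    rows = []
    for m in sorted(set(circ_sites) & set(mrna_sites)):
        for c in sorted(circ_sites[m]):
            for g in sorted(mrna_sites[m]):
                if (c, g) in coexpr_map:
                    r, p = coexpr_map[(c, g)]
                    rows.append(
                        {"circ": c, "mirna": m, "mrna": g, "r": r, "p_corr": p}
                    )
    triplets = pd.DataFrame(rows, columns=["circ", "mirna", "mrna", "r", "p_corr"])
    triplets = triplets.sort_values(["circ", "mirna", "mrna"], ignore_index=True)
    graph = nx.Graph()
    for row in triplets.itertuples(index=False):
        graph.add_node(row.circ, node_type="circRNA")
        graph.add_node(row.mirna, node_type="miRNA")
        graph.add_node(row.mrna, node_type="mRNA")
        graph.add_edge(row.circ, row.mirna, edge_type="binding")
        graph.add_edge(row.mirna, row.mrna, edge_type="binding")
        graph.add_edge(row.circ, row.mrna, edge_type="coexpression", r=float(row.r))
    return triplets, graph


def enrich_hypergeometric(
    query: Sequence[str],
    universe: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of annotation terms in a gene set.

    Upper-tail hypergeometric P = sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n) per
    term, with BH adjustment across tested terms; the conventional raw
    P < 0.05 gate and the adjusted P are both reported.
    """
    uni = set(universe)
    q = set(query)
    outside = q - uni
    if outside:
        raise ValueError(f"query genes outside universe: {sorted(outside)[:5]}")
    N, n = len(uni), len(q)
    rows = []
    for term in sorted(term_map):
        genes = set(term_map[term]) & uni
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & q)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p"] < alpha
    else:
        out["p_adj"] = []
        out["significant"] = []
    return out.sort_values(["p", "term"], ignore_index=True)


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('edge_type', 'link')}\t{b}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
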