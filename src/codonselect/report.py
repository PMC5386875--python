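"""Reporting layer: PSG calling, GO enrichment, set overlaps, PPI degrees.

Turns per-gene branch-site results into a positively-selected-gene (PSG)
list (BH q < 0.05, converged fits only), tests GO terms for PSG
over-representation with the hypergeometric upper tail, intersects PSG
sets with each other and with named gene lists (e.g. a hypoxia-response
catalog), and filters a protein–protein interaction network to hub genes
with more than a minimum number of interactions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .fit import bh_fdr

__all__ = [
    "branch_site_table",
    "call_psgs",
    "hypergeom_enrich",
    "overlap_sets",
    "intersect_named_list",
    "read_edge_list",
    "network_degree_filter",
]


def branch_site_table(results) -> pd.DataFrame:
    """Per-gene branch-site result table with BH q-values.

    q-values are computed across converged genes only; non-converged genes
    keep q = NaN and are never called as PSGs.
    """
    rows = [
        {
            "gene": r.gene_id,
            "lnL_alt": r.lnL_alt,
            "lnL_null": r.lnL_null,
            "lrt": r.lrt_stat,
            "p": r.p_value,
            "p0": r.p0,
            "p1": r.p1,
            "w0": r.omega0,
            "w2": r.omega2,
            "converged": r.converged,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    if len(df):
        conv = df["converged"].to_numpy(dtype=bool)
        if conv.any():
            df.loc[conv, "q"] = bh_fdr(df.loc[conv, "p"])
    return df


def call_psgs(results, alpha: float = 0.05) -> list[str]:
    """Genes whose branch-site LRT survives FDR control at ``alpha``.

    Accepts either BranchSiteResult objects or a table from
    :func:`branch_site_table`.  Lowering alpha can only shrink the list.
    """
    df = results if isinstance(results, pd.DataFrame) else branch_site_table(results)
    if not len(df):
        return []
    mask = df["converged"].astype(bool) & (df["q"] < alpha)
    return sorted(df.loc[mask, "gene"])


def hypergeom_enrich(
    psgs, background, catalog: pd.DataFrame, min_psgs: int = 1
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of PSGs per GO term.

    For a term with K background members, k of the n PSGs, and N background
    genes in total, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Terms with
    fewer than ``min_psgs`` PSG members are not tested (the study's plots
    use at least three); BH q-values are computed across tested terms.
    """
    psgs, background = set(psgs), set(background)
    stray = psgs - background
    if stray:
        raise ValueError(f"PSGs not in background: {sorted(stray)[:5]}")
    cat = catalog[catalog["gene_id"].isin(background)]
    n, N = len(psgs), len(background)
    rows = []
    for term, members in cat.groupby("term_id")["gene_id"]:
        member_set = set(members)
        k = len(member_set & psgs)
        if k < min_psgs:
            continue
        K = len(member_set)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N_bg": N,
                "p": float(hypergeom.sf(k - 1, N, K, n)),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N_bg", "p"])
    df["q"] = bh_fdr(df["p"]) if len(df) else np.nan
    return df.sort_values("p", ignore_index=True) if len(df) else df


def overlap_sets(set1, set2) -> tuple[list[str], list[str], list[str]]:
    """Venn partition (only-in-1, shared, only-in-2) of two gene sets."""
    s1, s2 = set(set1), set(set2)
    return sorted(s1 - s2), sorted(s1 & s2), sorted(s2 - s1)


def intersect_named_list(psgs, named_list) -> pd.DataFrame:
    """PSGs present in a named gene list, matched case-insensitively.

    Returns a DataFrame with the PSG id as given, the matching list entry,
    and a provenance column marking the source list membership.
    """
    lookup = {}
    for name in named_list:
        lookup.setdefault(str(name).casefold(), str(name))
    rows = [
        {"gene": g, "list_entry": lookup[str(g).casefold()], "in_list": True}
        for g in sorted(set(psgs))
        if str(g).casefold() in lookup
    ]
    return pd.DataFrame(rows, columns=["gene", "list_entry", "in_list"])


def read_edge_list(path) -> pd.DataFrame:
    """Two-column TSV of undirected edges; header optional.

    Self-loops are dropped and each unordered pair is kept once.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("edge list needs two columns")
    first = df.iloc[0]
    if first[0].lower() in {"gene1", "source", "node1", "protein1"}:
        df = df.iloc[1:]
    df = df.iloc[:, :2]
    df.columns = ["gene1", "gene2"]
    df = df[df["gene1"] != df["gene2"]]
    pairs = pd.DataFrame(
        np.sort(df[["gene1", "gene2"]].to_numpy(), axis=1),
        columns=["gene1", "gene2"],
    )
    return pairs.drop_duplicates(ignore_index=True)


def network_degree_filter(
    edges: pd.DataFrame, seeds, min_degree: int = 20, induced: bool = False
) -> pd.DataFrame:
    """Seed genes with strictly more than ``min_degree`` interactions.

    Degree is counted in the full network by default (interactors of any
    kind); with ``induced=True`` only edges among the seeds themselves
    count.  A seed with degree exactly ``min_degree`` is dropped.
    """
    seeds = sorted(set(seeds))
    df = edges
    if induced:
        seed_set = set(seeds)
        df = edges[edges["gene1"].isin(seed_set) & edges["gene2"].isin(seed_set)]
    degree = pd.concat([df["gene1"], df["gene2"]]).value_counts()
    rows = [
        {"gene": g, "degree": int(degree.get(g, 0))}
        for g in seeds
        if int(degree.get(g, 0)) > min_degree
    ]
    return pd.DataFrame(rows, columns=["gene", "degree"]).sort_values(
        "degree", ascending=False, ignore_index=True
    )
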