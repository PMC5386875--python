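"""Lineage-level dN/dS comparisons and GO-category rate-shift tests.

Two questions from the study design live here: do whole lineages differ in
their per-gene dN/dS distributions (Wilcoxon rank-sum), and which GO
categories evolved faster on one branch than another?  For the latter each
category's member alignments are concatenated into a supergene, a
free-ratio model supplies per-branch expected nonsynonymous/synonymous
substitution counts (N*dN, S*dS), and a binomial test asks whether branch
X's nonsynonymous fraction exceeds (or falls short of) branch Y's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, chi2, mannwhitneyu

from .alignment import concatenate
from .fit import FreeRatioFit, fit_free_ratio

__all__ = [
    "CategoryRateResult",
    "wilcoxon_rank_sum",
    "select_categories",
    "category_supergene_rates",
    "binomial_rate_shift",
    "node_pair_report",
]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Exact enumeration when both samples have at most 10 observations and no
    ties straddle the groups; otherwise the normal approximation with
    continuity and tie correction.  The statistic is the rank sum of ``x``
    with midranks for ties.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size <= 10 and y.size <= 10 and np.unique(np.r_[x, y]).size == x.size + y.size
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


def select_categories(catalog: pd.DataFrame, ortholog_genes, min_genes: int = 30):
    """Terms annotating at least ``min_genes`` of the ortholog set.

    ``catalog`` columns: gene_id, term_id (term_name optional).  The bound
    is inclusive: a 30-member term passes the default filter.
    """
    genes = set(ortholog_genes)
    present = catalog[catalog["gene_id"].isin(genes)]
    counts = present.groupby("term_id")["gene_id"].nunique()
    return sorted(counts.index[counts >= min_genes])


@dataclass
class CategoryRateResult:
    """Supergene free-ratio estimates for one GO category."""

    term: str
    n_genes: int
    fit: FreeRatioFit

    def branch_counts(self, branch: str) -> tuple[float, float]:
        est = self.fit.estimates[branch]
        return est.nN, est.nS  # N*dN, S*dS

    def compare(self, branch_x: str, branch_y: str) -> dict[str, float]:
        """Binomial elevation/deceleration test of branch X against Y."""
        n_x, s_x = self.branch_counts(branch_x)
        n_y, s_y = self.branch_counts(branch_y)
        p_elev, p_dec = binomial_rate_shift(n_x, s_x, n_y, s_y)
        return {
            "term": self.term,
            "n_genes": self.n_genes,
            "omega_x": self.fit.omegas[branch_x],
            "omega_y": self.fit.omegas[branch_y],
            "n_X": n_x,
            "s_X": s_x,
            "n_Y": n_y,
            "s_Y": s_y,
            "p_elevated": p_elev,
            "p_decelerated": p_dec,
        }


def category_supergene_rates(
    term: str, member_alignments, tree, spec=None, restarts: int = 1
) -> CategoryRateResult:
    """Concatenate a category's members and fit the free-ratio model.

    A single-gene category reduces to that gene's own free-ratio fit (up to
    optimiser start); concatenation order cannot change the likelihood
    because sites are independent.
    """
    members = list(member_alignments)
    supergene = concatenate(members, gene_id=f"supergene:{term}")
    fit = fit_free_ratio(supergene, tree, spec=spec, restarts=restarts)
    return CategoryRateResult(term=term, n_genes=len(members), fit=fit)


def binomial_rate_shift(
    n_X: float, s_X: float, n_Y: float, s_Y: float, method: str = "exact"
) -> tuple[float, float]:
    """Binomial test for a rate shift of branch X relative to branch Y.

    The null proportion is Y's nonsynonymous substitution fraction
    ``p0 = n_Y / (n_Y + s_Y)``; X's expected counts are rounded to the
    nearest integers and the exact binomial upper tail P(X >= n) gives
    ``p_elevated`` (lower tail P(X <= n) gives ``p_decelerated``).  The two
    tails overlap at the observed point, so their sum is >= 1.

    ``method="lr"`` instead uses a directed likelihood-ratio (G) statistic
    on the unrounded counts against chi-square(1)/2.
    """
    if min(n_X, s_X, n_Y, s_Y) < 0:
        raise ValueError("substitution counts must be nonnegative")
    if n_Y + s_Y <= 0:
        raise ValueError("branch Y has no substitutions; null proportion undefined")
    p0 = n_Y / (n_Y + s_Y)
    if method == "exact":
        x = int(round(n_X))
        m = int(round(n_X + s_X))
        if m == 0:
            raise ValueError("branch X has no substitutions to test")
        x = min(x, m)
        p_elev = float(binom.sf(x - 1, m, p0))  # P(X >= x)
        p_dec = float(binom.cdf(x, m, p0))
        return p_elev, p_dec
    if method == "lr":
        m = n_X + s_X
        if m <= 0:
            raise ValueError("branch X has no substitutions to test")
        phat = n_X / m
        with np.errstate(divide="ignore", invalid="ignore"):
            g = 2.0 * (
                (n_X * np.log(phat / p0) if n_X > 0 else 0.0)
                + (s_X * np.log((1 - phat) / (1 - p0)) if s_X > 0 else 0.0)
            )
        g = max(0.0, float(g))
        tail = 0.5 * float(chi2.sf(g, df=1))
        if phat >= p0:
            return tail, 1.0 - tail
        return 1.0 - tail, tail
    raise ValueError(f"unknown method {method!r}")


def node_pair_report(results_by_comparison: dict[str, pd.DataFrame], alpha: float = 0.05):
    """Elevated-category lists per branch comparison and their overlaps.

    ``results_by_comparison`` maps a comparison label (e.g. ``"A:C"``) to a
    DataFrame with columns ``term`` and ``p_elevated`` (as produced by
    :meth:`CategoryRateResult.compare`); all comparisons must cover the
    same term list.  Returns a dict with the per-comparison elevated sets
    at ``p < alpha`` and, for each pair of comparisons, the intersection
    and the two set differences (the Venn partition).
    """
    term_sets = {
        name: frozenset(df["term"]) for name, df in results_by_comparison.items()
    }
    ref = None
    for name, terms in term_sets.items():
        if ref is None:
            ref = terms
        elif terms != ref:
            raise ValueError(f"comparison {name!r} covers a different term list")
    elevated = {
        name: sorted(df.loc[df["p_elevated"] < alpha, "term"])
        for name, df in results_by_comparison.items()
    }
    names = list(elevated)
    overlaps = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = set(elevated[a]), set(elevated[b])
            overlaps[(a, b)] = {
                "only_" + a: sorted(sa - sb),
                "shared": sorted(sa & sb),
                "only_" + b: sorted(sb - sa),
            }
    return {"elevated": elevated, "overlaps": overlaps, "alpha": alpha}
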