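"""End-to-end drivers tying the stages together.

These functions run the whole analysis the package implements — branch-site
scans over a gene set and GO-category supergene rate comparisons — and are
what the command-line interface and reproduction scripts call.
"""

from __future__ import annotations

import pandas as pd

from .fit import fit_branch_site
from .lineage import category_supergene_rates, select_categories
from .report import branch_site_table

__all__ = ["branch_site_scan", "category_rate_scan"]


def branch_site_scan(
    alignments: dict, tree, spec=None, restarts: int = 1
) -> pd.DataFrame:
    """Branch-site LRT for every gene against the tree's foreground.

    ``alignments`` maps gene id -> CodonAlignment on the tree's taxa (prune
    first if needed).  Returns the per-gene table with BH q-values across
    converged fits.
    """
    results = []
    for gid in sorted(alignments):
        results.append(
            fit_branch_site(alignments[gid], tree, spec=spec, restarts=restarts,
                            gene_id=gid)
        )
    return branch_site_table(results)


def category_rate_scan(
    alignments: dict,
    catalog: pd.DataFrame,
    tree,
    comparisons,
    min_genes: int = 30,
    spec=None,
) -> dict[str, pd.DataFrame]:
    """Supergene free-ratio fits and binomial rate-shift tests per GO term.

    ``comparisons`` is a list of ``(branch_x, branch_y)`` pairs; the return
    maps ``"X:Y"`` to a DataFrame of per-term test rows (see
    :meth:`codonselect.lineage.CategoryRateResult.compare`).
    """
    terms = select_categories(catalog, alignments.keys(), min_genes=min_genes)
    rows: dict[str, list] = {f"{x}:{y}": [] for x, y in comparisons}
    for term in terms:
        members = [
            alignments[g]
            for g in catalog.loc[catalog["term_id"] == term, "gene_id"].unique()
            if g in alignments
        ]
        result = category_supergene_rates(term, members, tree, spec=spec)
        for x, y in comparisons:
            rows[f"{x}:{y}"].append(result.compare(x, y))
    return {name: pd.DataFrame(r) for name, r in rows.items()}
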