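"""Maximum-likelihood fits of the codon models and the selection tests.

Three model fits are provided, mirroring the codeml workflow the pipeline
reproduces:

* :func:`fit_m0` — one omega shared by all branches (warm start / baseline);
* :func:`fit_free_ratio` — an independent omega per branch, yielding the
  per-branch (t, omega, N, S, dN, dS) table used for lineage comparisons;
* :func:`fit_branch_site` — branch-site model A on tagged foreground
  branches, alternative (omega2 >= 1 estimated) against null (omega2 = 1),
  with the chi-square(1) LRT.

All fits optimise branch lengths jointly with the model parameters by
bounded quasi-Newton (L-BFGS-B) on log/logit-transformed parameters, with
bounds omega in [1e-4, 999], kappa in [0.01, 100], t in [1e-6, 50].  A
cheap single-ratio fit on a site subsample supplies starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .likelihood import (
    EigenCache,
    SitePatterns,
    branch_site_classes,
    mixture_log_likelihood,
)
from .model import CodonModelSpec, split_substitutions

__all__ = [
    "BranchEstimate",
    "FreeRatioFit",
    "M0Fit",
    "BranchSiteResult",
    "fit_m0",
    "fit_free_ratio",
    "fit_branch_site",
    "lrt_pvalue",
    "bh_fdr",
    "apply_gene_filters",
    "free_ratio_table",
]

OMEGA_BOUNDS = (1e-4, 999.0)
KAPPA_BOUNDS = (0.01, 100.0)
T_BOUNDS = (1e-6, 50.0)

_LOG_OMEGA = tuple(np.log(OMEGA_BOUNDS))
_LOG_KAPPA = tuple(np.log(KAPPA_BOUNDS))
_LOG_T = tuple(np.log(T_BOUNDS))
_LOGIT_B = (-9.2, 9.2)  # proportions / omega0 in (1e-4, 1-1e-4)

_OPTIONS = {"maxiter": 500, "maxfun": 20000, "ftol": 1e-10, "gtol": 1e-6}


# ---------------------------------------------------------------------------
# result containers


@dataclass
class BranchEstimate:
    """Per-branch free-ratio output, the analogue of one codeml table row.

    ``N`` and ``S`` are model-based mutational opportunities (3L times the
    neutral nonsynonymous/synonymous flux fractions under the fitted kappa
    and codon frequencies), so dN/dS equals the branch omega identically;
    ``nN = N*dN`` and ``nS = S*dS`` are expected substitution counts.
    """

    branch: str
    t: float
    omega: float
    N: float
    S: float
    dN: float
    dS: float
    nN: float
    nS: float


@dataclass
class M0Fit:
    lnL: float
    kappa: float
    omega: float
    lengths: dict[str, float]
    converged: bool
    spec: CodonModelSpec


@dataclass
class FreeRatioFit:
    lnL: float
    kappa: float
    lengths: dict[str, float]
    omegas: dict[str, float]
    estimates: dict[str, BranchEstimate]
    converged: bool
    spec: CodonModelSpec
    gene_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": self.gene_id,
                "branch": e.branch,
                "t": e.t,
                "omega": e.omega,
                "N": e.N,
                "S": e.S,
                "dN": e.dN,
                "dS": e.dS,
                "nN": e.nN,
                "nS": e.nS,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class BranchSiteResult:
    """Alternative/null branch-site fits and the LRT for one gene."""

    gene_id: str
    lnL_alt: float
    lnL_null: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    lrt_stat: float
    p_value: float
    converged: bool
    q_value: float | None = None
    null_params: dict = field(default_factory=dict)

    @property
    def class_proportions(self) -> dict[str, float]:
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        denom = self.p0 + self.p1
        return {
            "p0": self.p0,
            "p1": self.p1,
            "p2a": p2 * self.p0 / denom if denom else 0.0,
            "p2b": p2 * self.p1 / denom if denom else p2,
        }


# ---------------------------------------------------------------------------
# shared machinery


def _prepare(aln, tree, spec):
    if len(aln.taxa) < 3:
        raise ValueError(f"{aln.gene_id}: need at least 3 taxa")
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError(
            f"{aln.gene_id}: alignment/tree taxa differ: "
            f"{sorted(set(aln.taxa) ^ set(tree.taxa))}"
        )
    if spec is None:
        spec = CodonModelSpec.f3x4([aln])
    patterns = SitePatterns.from_alignment(aln)
    cache = EigenCache(spec.codon_freqs)
    branch_names = list(tree.branches())
    return spec, patterns, cache, branch_names


def _p_distance(patterns: SitePatterns) -> float:
    """Mean pairwise proportion of differing codon sites (rough t scale)."""
    cods, w = patterns.codons, patterns.weights
    n = cods.shape[0]
    total, diff = 0.0, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ok = (cods[i] >= 0) & (cods[j] >= 0)
            total += w[ok].sum()
            diff += w[ok & (cods[i] != cods[j])].sum()
    return diff / total if total > 0 else 0.0


def _converged(res) -> bool:
    return bool(res.success) or res.status == 1  # status 1: maxiter reached


def _minimize(fun, x0, bounds):
    return minimize(fun, x0, method="L-BFGS-B", bounds=bounds, options=_OPTIONS)


# ---------------------------------------------------------------------------
# M0 (one-ratio)


def fit_m0(
    aln, tree, spec=None, init_omega: float = 0.4, subsample: int | None = 500
) -> M0Fit:
    """Single-omega fit; also the warm start for the richer models.

    When ``subsample`` is set, a first pass runs on a multinomial site
    subsample before polishing on the full data.
    """
    spec, patterns, cache, names = _prepare(aln, tree, spec)
    B = len(names)
    t0 = np.clip(_p_distance(patterns) * 0.6, 0.01, 2.0)
    x0 = np.concatenate(
        [np.full(B, np.log(t0)), [np.log(spec.kappa), np.log(init_omega)]]
    )
    bounds = [_LOG_T] * B + [_LOG_KAPPA, _LOG_OMEGA]

    def make_obj(pats):
        def obj(x):
            lengths = dict(zip(names, np.exp(x[:B])))
            kappa, omega = np.exp(x[B]), np.exp(x[B + 1])
            classes = [(1.0, dict.fromkeys(names, omega))]
            return -mixture_log_likelihood(pats, tree, lengths, classes, kappa, cache)

        return obj

    if subsample is not None and patterns.n_sites > subsample:
        pre = _minimize(make_obj(patterns.subsample(subsample)), x0, bounds)
        x0 = pre.x
    res = _minimize(make_obj(patterns), x0, bounds)
    return M0Fit(
        lnL=-res.fun,
        kappa=float(np.exp(res.x[B])),
        omega=float(np.exp(res.x[B + 1])),
        lengths=dict(zip(names, np.exp(res.x[:B]))),
        converged=_converged(res),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# free-ratio (per-branch omega)


def fit_free_ratio(
    aln, tree, spec=None, restarts: int = 1, m0: M0Fit | None = None
) -> FreeRatioFit:
    """Per-branch omega ML fit with derived substitution bookkeeping.

    Restarts re-run the optimiser from omega starting values 0.2 / 0.8 /
    2.0 (in that order) and keep the best optimum.
    """
    spec, patterns, cache, names = _prepare(aln, tree, spec)
    B = len(names)
    if m0 is None:
        m0 = fit_m0(aln, tree, spec)
    bounds = [_LOG_T] * B + [_LOG_KAPPA] + [_LOG_OMEGA] * B

    def obj(x):
        lengths = dict(zip(names, np.exp(x[:B])))
        kappa = np.exp(x[B])
        omegas = dict(zip(names, np.exp(x[B + 1 :])))
        classes = [(1.0, omegas)]
        return -mixture_log_likelihood(patterns, tree, lengths, classes, kappa, cache)

    t_init = np.log([max(m0.lengths[n], T_BOUNDS[0] * 2) for n in names])
    omega_starts = [m0.omega, 0.2, 0.8, 2.0][: max(1, restarts)]
    best = None
    for w_start in omega_starts:
        x0 = np.concatenate(
            [t_init, [np.log(m0.kappa)], np.full(B, np.log(w_start))]
        )
        res = _minimize(obj, x0, bounds)
        if best is None or res.fun < best.fun:
            best = res

    kappa = float(np.exp(best.x[B]))
    fitted_spec = spec.with_kappa(kappa)
    lengths = dict(zip(names, np.exp(best.x[:B])))
    omegas = dict(zip(names, np.exp(best.x[B + 1 :])))
    estimates = {}
    for name in names:
        parts = split_substitutions(fitted_spec, omegas[name], lengths[name], aln.n_codons)
        estimates[name] = BranchEstimate(
            branch=name,
            t=lengths[name],
            omega=omegas[name],
            N=parts["N"],
            S=parts["S"],
            dN=parts["dN"],
            dS=parts["dS"],
            nN=parts["nN"],
            nS=parts["nS"],
        )
    return FreeRatioFit(
        lnL=-best.fun,
        kappa=kappa,
        lengths=lengths,
        omegas=omegas,
        estimates=estimates,
        converged=_converged(best),
        spec=fitted_spec,
        gene_id=aln.gene_id,
    )


def free_ratio_table(fits) -> pd.DataFrame:
    """Tidy per-gene, per-branch estimate table from FreeRatioFit objects."""
    frames = [f.to_frame() for f in fits]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


# ---------------------------------------------------------------------------
# branch-site model A


def _bs_unpack(x, B):
    lengths_x, kappa_x = x[:B], x[B]
    s, r, w0 = expit(x[B + 1]), expit(x[B + 2]), expit(x[B + 3])
    p0, p1 = s * r, s * (1 - r)
    return np.exp(lengths_x), np.exp(kappa_x), p0, p1, w0


def fit_branch_site(
    aln, tree, spec=None, restarts: int = 2, gene_id: str | None = None
) -> BranchSiteResult:
    """Branch-site positive-selection test on the tree's tagged branches.

    Fits the null (omega2 fixed at 1) and alternative (omega2 >= 1 free)
    branch-site models and returns the likelihood-ratio test against
    chi-square(1).  The alternative is started from the null optimum;
    ``restarts`` adds extra alternative starts at omega2 near the boundary
    and at a larger value, guarding against the local optimum at omega2 = 1.
    """
    spec, patterns, cache, names = _prepare(aln, tree, spec)
    foreground = tree.foreground
    if not foreground:
        raise ValueError(f"{aln.gene_id}: tree has no #1 foreground branches")
    B = len(names)
    m0 = fit_m0(aln, tree, spec, subsample=300)
    w0_init = float(np.clip(m0.omega, 1e-3, 0.9))
    x_common = np.concatenate(
        [
            np.log([max(m0.lengths[n], T_BOUNDS[0] * 2) for n in names]),
            [np.log(m0.kappa), logit(0.85), logit(0.80), logit(w0_init)],
        ]
    )
    bounds_common = [_LOG_T] * B + [_LOG_KAPPA] + [_LOGIT_B] * 3

    def neg_lnl(x, omega2):
        lengths_arr, kappa, p0, p1, w0 = _bs_unpack(x, B)
        lengths = dict(zip(names, lengths_arr))
        classes = branch_site_classes(p0, p1, w0, omega2, foreground, names)
        return -mixture_log_likelihood(patterns, tree, lengths, classes, kappa, cache)

    null_res = _minimize(lambda x: neg_lnl(x, 1.0), x_common, bounds_common)

    bounds_alt = bounds_common + [(np.log(1e-6), np.log(OMEGA_BOUNDS[1] - 1.0))]

    def neg_lnl_alt(x):
        return neg_lnl(x[:-1], 1.0 + np.exp(x[-1]))

    w2_starts = [2.0, 1.02, 4.5][: max(1, restarts)]
    alt_res = None
    for w2 in w2_starts:
        x0 = np.concatenate([null_res.x, [np.log(w2 - 1.0)]])
        res = _minimize(neg_lnl_alt, x0, bounds_alt)
        if alt_res is None or res.fun < alt_res.fun:
            alt_res = res

    lnL_null, lnL_alt = -null_res.fun, -alt_res.fun
    if lnL_alt < lnL_null:
        # nested models: retry the alternative from the null at omega2 -> 1
        x0 = np.concatenate([null_res.x, [np.log(1e-6)]])
        res = _minimize(neg_lnl_alt, x0, bounds_alt)
        if -res.fun > lnL_alt:
            alt_res, lnL_alt = res, -res.fun
    lrt = max(0.0, 2.0 * (lnL_alt - lnL_null))

    _, kappa_a, p0, p1, w0 = _bs_unpack(alt_res.x[:-1], B)
    nl_len, nl_kappa, nl_p0, nl_p1, nl_w0 = _bs_unpack(null_res.x, B)
    return BranchSiteResult(
        gene_id=gene_id if gene_id is not None else aln.gene_id,
        lnL_alt=lnL_alt,
        lnL_null=lnL_null,
        p0=float(p0),
        p1=float(p1),
        omega0=float(w0),
        omega2=float(1.0 + np.exp(alt_res.x[-1])),
        lrt_stat=lrt,
        p_value=lrt_pvalue(lrt),
        converged=_converged(alt_res) and _converged(null_res),
        null_params={
            "kappa": float(nl_kappa),
            "p0": float(nl_p0),
            "p1": float(nl_p1),
            "omega0": float(nl_w0),
        },
    )


# ---------------------------------------------------------------------------
# test statistics and filters


def lrt_pvalue(lrt_stat: float, null: str = "chi2") -> float:
    """Upper-tail p for the branch-site LRT.

    ``null="chi2"`` uses chi-square(1) (conservative); ``null="mixture"``
    uses the 50:50 point-mass/chi-square(1) boundary mixture.
    """
    if lrt_stat < -1e-8:
        raise ValueError(f"negative LRT statistic {lrt_stat}")
    stat = max(0.0, lrt_stat)
    tail = float(chi2.sf(stat, df=1))
    if null == "chi2":
        return tail
    if null == "mixture":
        return 0.5 * tail if stat > 0 else 1.0
    raise ValueError(f"unknown null {null!r}")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_gene_filters(
    estimates, branch: str | None = None, max_ds: float = 1.0, min_count: float = 1.0
):
    """Keep/drop decision for one gene's estimates on the branch under study.

    A gene is dropped when, on that branch, N*dN < 1 or S*dS < 1 (too few
    expected substitutions to estimate a rate) or dS > 1 (saturation).
    Returns ``(keep, reason)`` with ``reason`` None when kept.
    """
    if isinstance(estimates, BranchEstimate):
        est = estimates
    else:
        table = {e.branch: e for e in estimates}
        if branch is None:
            if len(table) != 1:
                raise ValueError("several branches present; name the branch under study")
            (est,) = table.values()
        else:
            est = table[branch]
    n_dn, s_ds = est.N * est.dN, est.S * est.dS
    if n_dn < min_count:
        return False, f"N*dN={n_dn:.4g} < {min_count}"
    if s_ds < min_count:
        return False, f"S*dS={s_ds:.4g} < {min_count}"
    if est.dS > max_ds:
        return False, f"dS={est.dS:.4g} > {max_ds}"
    return True, None
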