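"""Phylogenetic likelihood for codon alignments by Felsenstein pruning.

Alignments are compressed to unique codon-site patterns.  A "model" for one
evaluation is a mixture of site classes, each class assigning one omega per
branch; the single-omega (M0), per-branch-omega (free-ratio) and
branch-site-A models are all special cases of that structure.

Gapped or ambiguous codons enter as missing data: the affected taxon
contributes an all-ones partial likelihood at that site rather than the
column being discarded.

Rate scaling: for each branch the class generators share one scale factor,
the mixture-weighted expected equilibrium rate, so branch lengths are
expected substitutions per codon averaged over site classes.  The simulator
uses the identical convention.
"""

from __future__ import annotations

import numpy as np

from .genetic_code import CODON_INDEX, N_CODONS
from .model import CodonModelSpec, EigenSystem, build_rate_matrix

__all__ = [
    "SitePatterns",
    "EigenCache",
    "branch_site_classes",
    "log_likelihood",
    "mixture_log_likelihood",
]

_MIN_LIK = 1e-300


class SitePatterns:
    """Unique codon-column patterns of an alignment with multiplicities."""

    __slots__ = ("taxa", "codons", "weights")

    def __init__(self, taxa, codons, weights):
        self.taxa = list(taxa)
        self.codons = codons  # (n_taxa, n_patterns) int; -1 = missing
        self.weights = weights  # (n_patterns,) counts

    @classmethod
    def from_alignment(cls, aln) -> "SitePatterns":
        n_taxa, L = len(aln.taxa), aln.n_codons
        if L == 0:
            raise ValueError(f"{aln.gene_id}: zero-length alignment")
        mat = np.empty((n_taxa, L), dtype=np.int16)
        for i, seq in enumerate(aln.sequences):
            mat[i] = [
                CODON_INDEX.get(seq[3 * k : 3 * k + 3], -1) for k in range(L)
            ]
        patterns, counts = np.unique(mat, axis=1, return_counts=True)
        return cls(aln.taxa, patterns, counts.astype(float))

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def subsample(self, n: int, seed: int = 0) -> "SitePatterns":
        """Multinomial site subsample (used for cheap warm-start fits)."""
        total = self.n_sites
        if n >= total:
            return self
        rng = np.random.default_rng(seed)
        w = rng.multinomial(n, self.weights / total).astype(float)
        keep = w > 0
        return SitePatterns(self.taxa, self.codons[:, keep], w[keep])


class EigenCache:
    """Eigensystems of unscaled generators, keyed by (kappa, omega).

    Finite-difference optimisation mostly perturbs branch lengths, which
    leave (kappa, omega) untouched; caching the spectral decompositions
    removes the dominant per-evaluation cost.  Entries are evicted wholesale
    when the cache grows past ``maxsize``.
    """

    def __init__(self, pi: np.ndarray, maxsize: int = 128):
        self.pi = np.asarray(pi, dtype=float)
        self.maxsize = maxsize
        self._store: dict[tuple[float, float], EigenSystem] = {}

    def get(self, kappa: float, omega: float) -> EigenSystem:
        key = (float(kappa), float(omega))
        es = self._store.get(key)
        if es is None:
            if len(self._store) >= self.maxsize:
                self._store.clear()
            spec = CodonModelSpec(kappa, self.pi, "cache")
            es = EigenSystem(build_rate_matrix(spec, omega, scale=False), self.pi)
            self._store[key] = es
        return es


def branch_site_classes(
    p0: float, p1: float, omega0: float, omega2: float, foreground, branches
):
    """Site classes of branch-site model A as (weight, omega-by-branch) pairs.

    Classes: 0 — omega0 everywhere; 1 — neutral everywhere; 2a — omega0 on
    background, omega2 on foreground; 2b — neutral on background, omega2 on
    foreground.  The positive-selection mass 1 - p0 - p1 is split between 2a
    and 2b in proportion p0 : p1.
    """
    if not (p0 >= 0 and p1 >= 0 and p0 + p1 <= 1 + 1e-12):
        raise ValueError(f"invalid class proportions p0={p0}, p1={p1}")
    if not (0 <= omega0 < 1 <= omega2):
        raise ValueError(f"need omega0 < 1 <= omega2, got {omega0}, {omega2}")
    foreground = set(foreground)
    p2 = max(0.0, 1.0 - p0 - p1)
    denom = p0 + p1
    p2a = p2 * p0 / denom if denom > 0 else 0.0
    p2b = p2 * p1 / denom if denom > 0 else p2
    branches = list(branches)

    def omega_map(bg: float, fg: float) -> dict[str, float]:
        return {b: (fg if b in foreground else bg) for b in branches}

    return [
        (p0, omega_map(omega0, omega0)),
        (p1, omega_map(1.0, 1.0)),
        (p2a, omega_map(omega0, omega2)),
        (p2b, omega_map(1.0, omega2)),
    ]


def _node_partial(node, patterns: SitePatterns, P_by_branch, taxon_row):
    """(n_patterns, 61) conditional likelihoods at an internal node."""
    out = None
    for child in node.children:
        P = P_by_branch[child.name]
        if child.is_tip:
            codons = patterns.codons[taxon_row[child.name]]
            contrib = np.ones((patterns.weights.size, N_CODONS))
            obs = codons >= 0
            if obs.any():
                contrib[obs] = P[:, codons[obs]].T
        else:
            contrib = _node_partial(child, patterns, P_by_branch, taxon_row) @ P.T
        out = contrib if out is None else out * contrib
    return out


def mixture_log_likelihood(
    patterns: SitePatterns,
    tree,
    lengths: dict[str, float],
    classes,
    kappa: float,
    cache: EigenCache,
    return_site: bool = False,
):
    """Log-likelihood of a site-class mixture on a fixed tree shape.

    ``classes`` is a list of ``(weight, omega_by_branch)`` pairs whose
    weights sum to one; ``lengths`` maps branch name -> t.  The tree's own
    stored lengths are ignored, which lets optimisers evaluate candidate
    lengths without mutating the tree.
    """
    taxon_row = {t: i for i, t in enumerate(patterns.taxa)}
    branches = tree.branches()
    missing = set(branches) - set(lengths)
    if missing:
        raise ValueError(f"no length for branch(es) {sorted(missing)}")

    # per-branch mixture scale, then per-branch transition matrix per omega
    P_per_class = []
    scale = {}
    for name in branches:
        scale[name] = sum(
            w * cache.get(kappa, om[name]).rate for w, om in classes if w > 0
        )
    for w, om in classes:
        P_map = {}
        if w > 0:
            memo = {}
            for name in branches:
                key = (om[name], lengths[name])
                if key not in memo:
                    es = cache.get(kappa, om[name])
                    memo[key] = es.transition(lengths[name] / scale[name])
                P_map[name] = memo[key]
        P_per_class.append(P_map)

    site_lik = np.zeros(patterns.weights.size)
    pi = cache.pi
    for (w, _), P_map in zip(classes, P_per_class):
        if w <= 0:
            continue
        partial = _node_partial(tree.root, patterns, P_map, taxon_row)
        site_lik += w * (partial @ pi)
    lnl = float(patterns.weights @ np.log(np.maximum(site_lik, _MIN_LIK)))
    if return_site:
        return lnl, site_lik
    return lnl


def log_likelihood(
    aln,
    tree,
    spec: CodonModelSpec,
    omega: float | None = None,
    omega_by_branch: dict[str, float] | None = None,
    classes=None,
    return_site: bool = False,
):
    """Convenience wrapper: validate taxa, compress sites, evaluate lnL.

    Exactly one of ``omega`` (single ratio), ``omega_by_branch``
    (free-ratio style) or ``classes`` (mixture) must be given.  Branch
    lengths are taken from the tree.
    """
    if sum(x is not None for x in (omega, omega_by_branch, classes)) != 1:
        raise ValueError("give exactly one of omega, omega_by_branch, classes")
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError(
            f"alignment/tree taxon mismatch: {sorted(set(aln.taxa) ^ set(tree.taxa))}"
        )
    branches = tree.branches()
    lengths = {}
    for name, node in branches.items():
        if node.length is None or node.length < 0:
            raise ValueError(f"branch {name} lacks a nonnegative length")
        lengths[name] = node.length
    if omega is not None:
        classes = [(1.0, {b: omega for b in branches})]
    elif omega_by_branch is not None:
        missing = set(branches) - set(omega_by_branch)
        if missing:
            raise ValueError(f"no omega for branch(es) {sorted(missing)}")
        classes = [(1.0, dict(omega_by_branch))]
    patterns = SitePatterns.from_alignment(aln)
    cache = EigenCache(spec.codon_freqs)
    return mixture_log_likelihood(
        patterns, tree, lengths, classes, spec.kappa, cache, return_site=return_site
    )
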