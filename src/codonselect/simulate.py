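"""Codon-evolution simulator: ortholog sets with known selection regimes.

The generative model is the exact twin of the inference machinery: root
codons are drawn from the equilibrium frequencies and each branch evolves
sites by the transition matrix ``exp(Q t)`` of the same Goldman–Yang
generator (and the same per-branch mixture rate scaling) that the
likelihood uses.  Stop codons never occur because they are outside the
state space; indels are not simulated, but random codon cells can be masked
to gaps to exercise missing-data handling.

A :class:`SimScenario` bundles the study conditions — tree, gene count and
lengths, per-branch omegas, branch-site genes with a positively selected
foreground site class, and a GO catalog in which designated terms carry a
multiplied omega on designated branches — and
:func:`simulate_ortholog_set` materialises alignments, catalog and a
ground-truth table.  Randomness is a single scenario seed; each gene uses
the substream ``(seed, gene_index)`` so gene sets are reproducible under
reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .genetic_code import N_CODONS, SENSE_CODONS
from .likelihood import branch_site_classes
from .model import CodonModelSpec, build_rate_matrix, EigenSystem, uniform_frequencies
from .trees import HIGHLAND, Phylogeny, make_study_tree

__all__ = [
    "GOCatalogSpec",
    "SimScenario",
    "GroundTruth",
    "simulate_gene",
    "simulate_ortholog_set",
    "simulate_edge_list",
    "study_scenario",
]


@dataclass
class GOCatalogSpec:
    """Shape of the simulated GO catalog.

    The first ``n_elevated`` terms are "elevated": their member genes are
    simulated with ``omega_multiplier`` times the baseline omega on each of
    ``elevated_branches``.  Elevated terms get disjoint member sets; the
    remaining terms draw members at random from the non-elevated genes.
    """

    n_terms: int = 0
    genes_per_term: int = 30
    n_elevated: int = 0
    omega_multiplier: float = 2.0
    elevated_branches: tuple[str, ...] = ("A",)


@dataclass
class SimScenario:
    """Study conditions for one simulated ortholog set."""

    tree: Phylogeny
    n_genes: int = 100
    codon_length_range: tuple[int, int] = (100, 250)
    kappa: float = 2.0
    codon_freqs: np.ndarray = field(default_factory=uniform_frequencies)
    branch_omega: dict[str, float] = field(default_factory=dict)
    default_omega: float = 0.2
    branch_site_genes: int = 0
    bs_foreground: tuple[str, ...] = ()
    bs_p0: float = 0.55
    bs_p1: float = 0.2
    bs_omega0: float = 0.2
    bs_omega2: float = 6.0
    go_catalog_spec: GOCatalogSpec = field(default_factory=GOCatalogSpec)
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        self.validate()

    def validate(self) -> None:
        pi = self.codon_freqs
        if pi.shape != (N_CODONS,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-12:
            raise ValueError("codon_freqs must be 61 nonnegative entries summing to 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        lo, hi = self.codon_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad codon_length_range {self.codon_length_range}")
        branches = set(self.tree.branches())
        unknown = set(self.branch_omega) - branches
        if unknown:
            raise ValueError(f"branch_omega names not in tree: {sorted(unknown)}")
        if any(w < 0 for w in self.branch_omega.values()) or self.default_omega < 0:
            raise ValueError("all omegas must be >= 0")
        if self.branch_site_genes:
            if self.bs_p0 < 0 or self.bs_p1 < 0 or self.bs_p0 + self.bs_p1 > 1:
                raise ValueError("need p0, p1 >= 0 with p0 + p1 <= 1")
            if not (self.bs_omega0 < 1 <= self.bs_omega2):
                raise ValueError("branch-site genes need omega0 < 1 <= omega2")
            fg = set(self.bs_foreground) or self.tree.foreground
            if not fg:
                raise ValueError("branch-site genes need foreground branches")
            if fg - branches:
                raise ValueError(f"foreground not in tree: {sorted(fg - branches)}")
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")

    def omega_map(self, multiplier: float = 1.0, on=()) -> dict[str, float]:
        """Baseline per-branch omega, optionally multiplied on some branches."""
        out = {
            b: self.branch_omega.get(b, self.default_omega)
            for b in self.tree.branches()
        }
        for b in on:
            out[b] *= multiplier
        return out


@dataclass
class GroundTruth:
    """What was actually simulated, for scoring recovery."""

    genes: pd.DataFrame  # gene, n_codons, is_branch_site, elevated_term
    branch_omegas: pd.DataFrame  # gene x branch true (class-0) omega
    terms: pd.DataFrame  # term, elevated, multiplier, branches
    site_classes: dict[str, np.ndarray] = field(default_factory=dict)


def _sample_states(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    """Draw child states from transition rows of their parent states."""
    cum = np.cumsum(P, axis=1)[parents]
    u = rng.random(parents.size)
    return np.minimum((u[:, None] > cum).sum(axis=1), N_CODONS - 1)


def simulate_gene(
    tree: Phylogeny,
    length: int,
    kappa: float = 2.0,
    codon_freqs: np.ndarray | None = None,
    omega_by_branch: dict[str, float] | float = 0.2,
    classes=None,
    gap_fraction: float = 0.0,
    rng=None,
    gene_id: str = "gene",
) -> CodonAlignment:
    """Evolve one codon alignment down a tree.

    Either ``omega_by_branch`` (single site class) or ``classes`` — a list
    of ``(weight, omega_by_branch)`` mixture components as produced by
    :func:`codonselect.likelihood.branch_site_classes` — defines the
    selection regime.  Branch lengths are read from the tree (zero allowed:
    zero time is the identity map); deterministic given ``rng``/seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1 codon")
    rng = np.random.default_rng(rng)
    pi = uniform_frequencies() if codon_freqs is None else np.asarray(codon_freqs)
    branches = tree.branches()
    for name, node in branches.items():
        if node.length is None or node.length < 0:
            raise ValueError(f"branch {name} needs a nonnegative length")
    if classes is None:
        if np.isscalar(omega_by_branch):
            omega_by_branch = dict.fromkeys(branches, float(omega_by_branch))
        classes = [(1.0, dict(omega_by_branch))]
    weights = np.array([w for w, _ in classes], dtype=float)
    if abs(weights.sum() - 1) > 1e-9 or (weights < 0).any():
        raise ValueError("class weights must be nonnegative and sum to 1")

    site_class = rng.choice(len(classes), size=length, p=weights)
    spec = CodonModelSpec(kappa, pi, "sim")
    eigens: dict[float, EigenSystem] = {}
    for _, om in classes:
        for w in om.values():
            if w not in eigens:
                eigens[w] = EigenSystem(build_rate_matrix(spec, w, scale=False), pi)

    states = {None: rng.choice(N_CODONS, size=length, p=pi)}  # root draw
    seqs: dict[str, np.ndarray] = {}

    def scale(name: str) -> float:
        return sum(w * eigens[om[name]].rate for w, om in classes if w > 0)

    def walk(node, parent_states):
        if node is not tree.root:
            t_eff = node.length / scale(node.name)
            child = np.empty(length, dtype=np.int64)
            for k, (w, om) in enumerate(classes):
                mask = site_class == k
                if not mask.any():
                    continue
                P = eigens[om[node.name]].transition(t_eff)
                child[mask] = _sample_states(P, parent_states[mask], rng)
            parent_states = child
            if node.is_tip:
                seqs[node.name] = parent_states
        for c in node.children:
            walk(c, parent_states)

    walk(tree.root, states[None])

    taxa = tree.taxa
    strings = []
    for t in taxa:
        codons = [SENSE_CODONS[s] for s in seqs[t]]
        if gap_fraction > 0:
            mask = rng.random(length) < gap_fraction
            codons = ["---" if m else c for c, m in zip(codons, mask)]
        strings.append("".join(codons))
    aln = CodonAlignment(taxa=taxa, sequences=strings, gene_id=gene_id)
    aln.site_classes = site_class  # type: ignore[attr-defined]
    return aln


def simulate_ortholog_set(scenario: SimScenario):
    """Generate alignments, GO catalog and ground truth for a scenario.

    Returns ``(alignments, catalog, truth)`` where ``alignments`` maps
    gene id -> CodonAlignment and ``catalog`` is a (gene_id, term_id,
    term_name) DataFrame compatible with the lineage-statistics module.
    """
    scenario.validate()
    cat = scenario.go_catalog_spec
    n, gpt = scenario.n_genes, cat.genes_per_term
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    rng_master = np.random.default_rng(scenario.seed)

    if cat.n_elevated * gpt > n:
        raise ValueError("not enough genes for disjoint elevated terms")
    elevated_members = {
        f"GO:SIM{k:04d}": gene_ids[k * gpt : (k + 1) * gpt]
        for k in range(cat.n_elevated)
    }
    elevated_genes = {g for mem in elevated_members.values() for g in mem}

    # branch-site genes: prefer genes outside elevated terms so the two
    # signals stay orthogonal
    pool = [g for g in gene_ids if g not in elevated_genes] or gene_ids
    if scenario.branch_site_genes > len(pool):
        pool = gene_ids
    bs_genes = set(
        rng_master.choice(pool, size=scenario.branch_site_genes, replace=False)
    ) if scenario.branch_site_genes else set()
    fg = set(scenario.bs_foreground) or scenario.tree.foreground

    # remaining (non-elevated) terms sample from non-elevated genes
    catalog_rows = []
    term_rows = []
    for term, members in elevated_members.items():
        for g in members:
            catalog_rows.append((g, term, f"simulated elevated process {term[-4:]}"))
        term_rows.append(
            {
                "term": term,
                "elevated": True,
                "multiplier": cat.omega_multiplier,
                "branches": ",".join(cat.elevated_branches),
            }
        )
    neutral_pool = [g for g in gene_ids if g not in elevated_genes] or gene_ids
    for k in range(cat.n_elevated, cat.n_terms):
        term = f"GO:SIM{k:04d}"
        size = min(gpt, len(neutral_pool))
        members = rng_master.choice(neutral_pool, size=size, replace=False)
        for g in members:
            catalog_rows.append((g, term, f"simulated background process {k:04d}"))
        term_rows.append(
            {"term": term, "elevated": False, "multiplier": 1.0, "branches": ""}
        )

    gene_term = {}
    for g, term, _ in catalog_rows:
        gene_term.setdefault(g, term)

    branch_names = list(scenario.tree.branches())
    lo, hi = scenario.codon_length_range
    alignments: dict[str, CodonAlignment] = {}
    gene_rows, omega_rows = [], []
    site_classes = {}
    for i, gid in enumerate(gene_ids):
        rng = np.random.default_rng([scenario.seed, i])
        length = int(rng.integers(lo, hi + 1))
        elevated_term = gene_term.get(gid) if gid in elevated_genes else None
        om = scenario.omega_map(
            multiplier=cat.omega_multiplier if elevated_term else 1.0,
            on=cat.elevated_branches if elevated_term else (),
        )
        if gid in bs_genes:
            classes = branch_site_classes(
                scenario.bs_p0,
                scenario.bs_p1,
                scenario.bs_omega0,
                scenario.bs_omega2,
                fg,
                branch_names,
            )
            aln = simulate_gene(
                scenario.tree,
                length,
                scenario.kappa,
                scenario.codon_freqs,
                classes=classes,
                gap_fraction=scenario.gap_fraction,
                rng=rng,
                gene_id=gid,
            )
            site_classes[gid] = aln.site_classes
            truth_om = {b: scenario.bs_omega0 for b in branch_names}
        else:
            aln = simulate_gene(
                scenario.tree,
                length,
                scenario.kappa,
                scenario.codon_freqs,
                omega_by_branch=om,
                gap_fraction=scenario.gap_fraction,
                rng=rng,
                gene_id=gid,
            )
            truth_om = om
        alignments[gid] = aln
        gene_rows.append(
            {
                "gene": gid,
                "n_codons": length,
                "is_branch_site": gid in bs_genes,
                "elevated_term": elevated_term,
            }
        )
        omega_rows.append({"gene": gid, **truth_om})

    catalog = pd.DataFrame(
        catalog_rows, columns=["gene_id", "term_id", "term_name"]
    )
    truth = GroundTruth(
        genes=pd.DataFrame(gene_rows),
        branch_omegas=pd.DataFrame(omega_rows).set_index("gene"),
        terms=pd.DataFrame(
            term_rows, columns=["term", "elevated", "multiplier", "branches"]
        ),
        site_classes=site_classes,
    )
    return alignments, catalog, truth


def simulate_edge_list(
    n_nodes: int, degree_distribution=None, seed: int = 0
) -> pd.DataFrame:
    """Undirected, self-loop-free gene–gene edge list with given degrees.

    ``degree_distribution`` is a sequence of target node degrees (a
    graphical degree sequence, realised exactly via Havel–Hakimi and then
    randomly relabelled); empty/None yields an empty edge list.  Node names
    are ``g0000``, ``g0001``, ...
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    names = [f"g{i:04d}" for i in range(n_nodes)]
    if not degree_distribution:
        return pd.DataFrame(columns=["gene1", "gene2"])
    degrees = list(degree_distribution)
    if len(degrees) > n_nodes:
        raise ValueError("more degrees than nodes")
    degrees += [0] * (n_nodes - len(degrees))
    try:
        graph = nx.havel_hakimi_graph(degrees)
    except nx.NetworkXError as err:
        raise ValueError(f"degree sequence not graphical: {err}") from err
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_nodes)
    rows = sorted(
        tuple(sorted((names[perm[u]], names[perm[v]]))) for u, v in graph.edges()
    )
    return pd.DataFrame(rows, columns=["gene1", "gene2"])


def study_scenario(**overrides) -> SimScenario:
    """Default study conditions on the six-taxon topology.

    Baseline per-branch omega 0.3 on the Schizothoracine branches and 0.16
    on the lowland branches, kappa = 2, uniform codon frequencies, gene
    lengths 100–250 codons, branch-site foreground = the highland tips (the
    four-taxon branch-site tree tags only those).
    """
    tree = overrides.pop("tree", make_study_tree())
    branch_omega = overrides.pop(
        "branch_omega",
        {
            **{b: 0.3 for b in ("G_dobula", "P_kaznakovi", "S_gongshanensis",
                                 "S_prenanti", "A", "B", "C")},
            **{b: 0.16 for b in ("C_idella", "D_rerio")},
        },
    )
    kw = dict(
        tree=tree,
        branch_omega=branch_omega,
        default_omega=0.2,
        bs_foreground=tuple(overrides.pop("bs_foreground", HIGHLAND)),
    )
    kw.update(overrides)
    return SimScenario(**kw)
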