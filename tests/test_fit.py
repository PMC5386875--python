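"""Model fitting, the LRT machinery, FDR and the gene filters."""

import numpy as np
import pytest

from codonselect.fit import (
    BranchEstimate,
    apply_gene_filters,
    bh_fdr,
    fit_branch_site,
    fit_free_ratio,
    fit_m0,
    lrt_pvalue,
)
from codonselect.model import CodonModelSpec
from codonselect.simulate import simulate_gene
from codonselect.trees import HIGHLAND, Phylogeny

from conftest import STUDY_OMEGA, make_alignment


@pytest.fixture(scope="module")
def quartet():
    return Phylogeny.from_newick(
        "((T1:0.3,T2:0.3)I:0.4,T3:0.5,T4:0.6);"
    )


class TestM0:
    def test_recovers_simulated_omega(self, quartet):
        aln = simulate_gene(quartet, 900, kappa=2.0, omega_by_branch=0.35,
                            rng=31, gene_id="m0")
        fit = fit_m0(aln, quartet, CodonModelSpec(kappa=2.0))
        assert fit.converged
        assert fit.omega == pytest.approx(0.35, abs=0.08)
        assert fit.kappa == pytest.approx(2.0, rel=0.3)

    def test_needs_three_taxa(self):
        aln = make_alignment([["ATG"], ["ATG"]], taxa=["T1", "T2"])
        tree = Phylogeny.from_newick("(T1:0.1,T2:0.1);")
        with pytest.raises(ValueError, match="3 taxa"):
            fit_m0(aln, tree)


class TestFreeRatio:
    def test_taxon_reordering_invariance(self, quartet):
        aln = simulate_gene(quartet, 400, omega_by_branch=0.3, rng=32, gene_id="g")
        spec = CodonModelSpec(kappa=2.0)
        fit_fwd = fit_free_ratio(aln, quartet, spec)
        shuffled = aln.subset_taxa(["T3", "T1", "T4", "T2"])
        fit_rev = fit_free_ratio(shuffled, quartet, spec)
        for b in fit_fwd.omegas:
            assert fit_fwd.omegas[b] == pytest.approx(fit_rev.omegas[b], abs=0.02)

    def test_identical_sequences_collapse_to_zero_lengths(self, quartet):
        row = ["ATG", "CTT", "GGA", "ACC", "TCT"] * 12
        aln = make_alignment([row] * 4, taxa=["T1", "T2", "T3", "T4"], gene_id="flat")
        fit = fit_free_ratio(aln, quartet)
        assert all(t < 1e-3 for t in fit.lengths.values())

    @pytest.mark.parametrize("omega", [0.1, 1.5])
    def test_relative_recovery_across_omega_range(self, omega):
        """Median branch estimate within 15% of truth from weak to positive
        selection (4000-codon simulation on the study tree)."""
        from codonselect.trees import make_study_tree

        tree = make_study_tree()
        aln = simulate_gene(tree, 4000, kappa=2.0, omega_by_branch=omega,
                            rng=300 + int(10 * omega), gene_id="w")
        fit = fit_free_ratio(aln, tree, CodonModelSpec(kappa=2.0))
        med = float(np.median(list(fit.omegas.values())))
        assert med == pytest.approx(omega, rel=0.15)

    def test_estimate_bookkeeping(self, quartet):
        aln = simulate_gene(quartet, 300, omega_by_branch=0.4, rng=33, gene_id="g")
        fit = fit_free_ratio(aln, quartet)
        for est in fit.estimates.values():
            assert est.N + est.S == pytest.approx(3 * aln.n_codons, abs=1e-6)
            if est.dS > 0:
                assert est.dN / est.dS == pytest.approx(est.omega, rel=1e-6)
        table = fit.to_frame()
        assert set(table["branch"]) == set(quartet.branches())


class TestBranchSite:
    def test_nesting_holds_on_null_gene(self, branch_site_tree):
        branches = list(branch_site_tree.branches())
        classes = [
            (0.7, {b: 0.2 for b in branches}),
            (0.3, {b: 1.0 for b in branches}),
        ]
        aln = simulate_gene(branch_site_tree, 250, classes=classes, rng=34,
                            gene_id="null")
        res = fit_branch_site(aln, branch_site_tree, restarts=1)
        assert res.converged
        assert res.lnL_alt >= res.lnL_null - 1e-6
        assert res.lrt_stat >= 0.0
        assert res.p_value > 0.05  # no selection simulated
        props = res.class_proportions
        assert sum(props.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in props.values())

    def test_requires_foreground(self, branch_site_tree):
        tree = branch_site_tree.copy().set_foreground(())
        aln = simulate_gene(tree, 60, omega_by_branch=0.3, rng=35, gene_id="g")
        with pytest.raises(ValueError, match="foreground"):
            fit_branch_site(aln, tree)


class TestLrtPvalue:
    def test_reference_quantiles(self):
        assert lrt_pvalue(0.0) == 1.0
        assert lrt_pvalue(3.841459) == pytest.approx(0.05, abs=1e-6)
        assert lrt_pvalue(6.634897) == pytest.approx(0.01, abs=1e-6)

    def test_mixture_null_halves_tail(self):
        assert lrt_pvalue(3.841459, null="mixture") == pytest.approx(0.025, abs=1e-6)
        assert lrt_pvalue(0.0, null="mixture") == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            lrt_pvalue(-0.5)


def brute_force_bh(p):
    """Step-up definition computed literally."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([]).size == 0
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(36)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(37)
        p = rng.random(25)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestGeneFilters:
    @staticmethod
    def est(N, dN, S, dS):
        return BranchEstimate("X", 0.1, 0.5, N, S, dN, dS, N * dN, S * dS)

    @pytest.mark.parametrize(
        "N,dN,S,dS,keep,reason_part",
        [
            (200, 0.004, 100, 0.05, False, "N*dN"),   # 0.8 nonsyn subs
            (300, 0.02, 100, 0.005, False, "S*dS"),   # 0.5 syn subs
            (300, 0.02, 100, 1.2, False, "dS"),       # saturated
            (300, 0.005, 100, 0.02, True, None),      # 1.5 / 2.0 / 0.4
        ],
    )
    def test_threshold_semantics(self, N, dN, S, dS, keep, reason_part):
        got_keep, reason = apply_gene_filters(self.est(N, dN, S, dS))
        assert got_keep is keep
        if reason_part:
            assert reason_part in reason

    def test_branch_selection(self):
        ests = [
            BranchEstimate("X", 0.1, 0.5, 300, 100, 0.02, 0.02, 6, 2),
            BranchEstimate("Y", 0.1, 0.5, 300, 100, 0.001, 0.02, 0.3, 2),
        ]
        assert apply_gene_filters(ests, branch="X")[0] is True
        assert apply_gene_filters(ests, branch="Y")[0] is False
        with pytest.raises(ValueError, match="name the branch"):
            apply_gene_filters(ests)
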