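"""Rate matrices, pruning likelihood (vs. enumeration oracle), fitting."""

import itertools

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

import opsinevol as ov
from opsinevol.codons import CODON_AA, SENSE_CODONS
from opsinevol.engine import _Eigen, beta_category_rates, compress_patterns

from conftest import random_alignment


def uniform_pi():
    return np.full(61, 1.0 / 61)


class TestRateMatrix:
    def test_generator_properties(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(61))
        Q = ov.build_rate_matrix(3.1, 0.4, pi)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()
        # rescaled to one expected substitution per unit time
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0)

    def test_neutral_symmetry(self):
        Q = ov.build_rate_matrix(1.0, 1.0, uniform_pi())
        rates = Q[Q > 0]
        assert np.allclose(rates, rates[0])

    def test_synonymous_vs_nonsynonymous_ratio(self):
        # AAA->AAG: K->K transition (synonymous); AAA->AAT: K->N
        # transversion (nonsynonymous): ratio = kappa*pi_AAG/(omega*pi_AAT)
        assert CODON_AA[SENSE_CODONS.index("AAA")] == CODON_AA[SENSE_CODONS.index("AAG")]
        assert CODON_AA[SENSE_CODONS.index("AAA")] != CODON_AA[SENSE_CODONS.index("AAT")]
        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.ones(61))
        kappa, omega = 2.7, 0.3
        Q = ov.build_rate_matrix(kappa, omega, pi)
        i = SENSE_CODONS.index("AAA")
        j1, j2 = SENSE_CODONS.index("AAG"), SENSE_CODONS.index("AAT")
        assert Q[i, j1] / Q[i, j2] == pytest.approx(kappa * pi[j1] / (omega * pi[j2]))

    def test_multi_step_changes_forbidden(self):
        Q = ov.build_rate_matrix(2.0, 0.5, uniform_pi())
        i, j = SENSE_CODONS.index("AAA"), SENSE_CODONS.index("ACG")
        assert Q[i, j] == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="simplex"):
            ov.build_rate_matrix(2.0, 0.5, np.ones(61))
        with pytest.raises(ValueError, match="nonnegative"):
            ov.build_rate_matrix(-1.0, 0.5, uniform_pi())


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        Q = ov.build_rate_matrix(2.0, 0.5, uniform_pi())
        assert np.allclose(ov.transition_matrix(Q, 0.0), np.eye(61))

    def test_rows_stochastic(self):
        rng = np.random.default_rng(5)
        pi = rng.dirichlet(np.ones(61))
        P = ov.transition_matrix(ov.build_rate_matrix(2.0, 0.5, pi), 0.7)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
        assert (P >= -1e-12).all()

    def test_long_time_converges_to_pi(self):
        rng = np.random.default_rng(6)
        pi = rng.dirichlet(np.ones(61) * 5)
        P = ov.transition_matrix(ov.build_rate_matrix(2.0, 0.5, pi), 100.0)
        assert np.abs(P - pi[None, :]).max() < 1e-8

    def test_detailed_balance(self):
        rng = np.random.default_rng(7)
        pi = rng.dirichlet(np.ones(61))
        P = ov.transition_matrix(ov.build_rate_matrix(2.3, 0.6, pi), 0.4)
        flux = pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_eigen_path_matches_expm(self):
        rng = np.random.default_rng(8)
        pi = rng.dirichlet(np.ones(61))
        Q = ov.build_rate_matrix(1.7, 0.9, pi)
        for t in (0.01, 0.3, 2.0):
            assert np.abs(_Eigen(Q, pi).P(t) - scipy.linalg.expm(Q * t)).max() < 1e-10

    def test_invalid_time(self):
        Q = ov.build_rate_matrix(2.0, 0.5, uniform_pi())
        with pytest.raises(ValueError):
            ov.transition_matrix(Q, np.nan)


# ---------------------------------------------------------------------------
# pruning vs. brute-force enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_loglike(aln, tree, kappa, pi, omega):
    """Independent oracle: sum over all state assignments to nodes with
    children (the canonical root may itself be a leaf), with expm
    transition matrices; childless leaves are marginalized in place."""
    Q = ov.build_rate_matrix(kappa, omega, pi)
    Ps = {b: scipy.linalg.expm(Q * tree.branch_lengths[b]) for b in tree.branch_ids()}
    enum_nodes = [u for u in range(tree.n_nodes) if tree.children[u]]
    leaf_of = {u: tree.leaf_label[u] for u in range(tree.n_nodes) if tree.leaf_label[u]}
    row = {t: i for i, t in enumerate(aln.taxa)}
    total = 0.0
    for j in range(aln.n_sites):
        site_p = 0.0
        for assign in itertools.product(range(61), repeat=len(enum_nodes)):
            st_map = dict(zip(enum_nodes, assign))
            root_state = st_map[tree.root]
            if tree.root in leaf_of and root_state not in aln.cells[row[leaf_of[tree.root]]][j]:
                continue
            term = pi[root_state]
            for u in range(tree.n_nodes):
                if u == tree.root:
                    continue
                P = Ps[tree.node_branch[u]]
                parent_state = st_map[tree.parent[u]]
                if u in st_map:
                    term *= P[parent_state, st_map[u]]
                    if u in leaf_of and st_map[u] not in aln.cells[row[leaf_of[u]]][j]:
                        term = 0.0
                        break
                else:
                    cell = aln.cells[row[leaf_of[u]]][j]
                    term *= sum(P[parent_state, s] for s in cell)
            site_p += term
        total += np.log(site_p)
    return total


def random_tree(rng, n_taxa):
    taxa = [f"t{i}" for i in range(n_taxa)]
    if n_taxa == 2:
        nwk = f"({taxa[0]}:{rng.uniform(0.02, 0.5):.3f},{taxa[1]}:{rng.uniform(0.02, 0.5):.3f});"
    else:
        nodes = [f"{t}:{rng.uniform(0.02, 0.5):.3f}" for t in taxa]
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.02, 0.5):.3f}"
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        nwk = "(" + ",".join(nodes) + ");"
    return ov.read_tree(nwk)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_pruning_matches_enumeration(case_seed):
    """Pruning log-likelihood equals brute-force state enumeration on
    random instances with <= 4 taxa and <= 3 sites."""
    rng = np.random.default_rng(case_seed)
    n_taxa = int(rng.integers(2, 5))
    n_sites = int(rng.integers(1, 4))
    tree = random_tree(rng, n_taxa)
    aln = random_alignment(rng, tree.taxa, n_sites)
    kappa = float(rng.uniform(0.5, 5))
    omega = float(rng.uniform(0.05, 3))
    pi = rng.dirichlet(np.ones(61))
    spec = ov.CodonModelSpec(
        kappa=kappa, pi=pi, site_classes=[(1.0, np.full(tree.n_branches, omega))]
    )
    ll = ov.log_likelihood(aln, tree, spec)
    oracle = brute_force_loglike(aln, tree, kappa, pi, omega)
    assert ll == pytest.approx(oracle, abs=1e-8)


class TestLogLikelihood:
    def test_zero_branch_star(self):
        # identical single-codon sequences, zero branch lengths:
        # l = log pi(observed codon)
        tree = ov.read_tree("(a:0.0,b:0.0,c:0.0);")
        k = SENSE_CODONS.index("ATG")
        aln = ov.CodonAlignment(
            taxa=["a", "b", "c"], cells=[[frozenset([k])]] * 3, nt_length=3
        )
        rng = np.random.default_rng(9)
        pi = rng.dirichlet(np.ones(61))
        spec = ov.CodonModelSpec(kappa=2.0, pi=pi, site_classes=[(1.0, np.zeros(3))])
        assert ov.log_likelihood(aln, tree, spec) == pytest.approx(np.log(pi[k]))

    def test_degenerate_mixture_equals_single_class(self, five_leaf_tree):
        rng = np.random.default_rng(10)
        aln = random_alignment(rng, five_leaf_tree.taxa, 20)
        pi = rng.dirichlet(np.ones(61))
        nb = five_leaf_tree.n_branches
        om = np.full(nb, 0.7)
        one = ov.CodonModelSpec(kappa=2.0, pi=pi, site_classes=[(1.0, om)])
        two = ov.CodonModelSpec(
            kappa=2.0, pi=pi, site_classes=[(0.3, om), (0.7, om.copy())]
        )
        assert ov.log_likelihood(aln, five_leaf_tree, one) == pytest.approx(
            ov.log_likelihood(aln, five_leaf_tree, two)
        )

    def test_missing_data_marginalized(self, five_leaf_tree):
        # a fully missing row changes nothing beyond marginalization:
        # likelihood with it must be <= 0 and finite, and dropping an
        # all-missing taxon's contribution equals summing over states
        rng = np.random.default_rng(11)
        aln = random_alignment(rng, five_leaf_tree.taxa, 5, ambiguity=False)
        from opsinevol.codons import FULL_SET

        aln.cells[2] = [FULL_SET] * 5
        pi = rng.dirichlet(np.ones(61))
        spec = ov.CodonModelSpec(
            kappa=2.0, pi=pi, site_classes=[(1.0, np.full(five_leaf_tree.n_branches, 0.5))]
        )
        sub_tree = ov.read_tree(five_leaf_tree.to_newick(), taxa=set(five_leaf_tree.taxa) - {five_leaf_tree.taxa[2]}, extra_leaf="prune")
        sub_aln = aln.subset(sub_tree.taxa)
        sub_spec = ov.CodonModelSpec(
            kappa=2.0, pi=pi, site_classes=[(1.0, np.full(sub_tree.n_branches, 0.5))]
        )
        assert ov.log_likelihood(aln, five_leaf_tree, spec) == pytest.approx(
            ov.log_likelihood(sub_aln, sub_tree, sub_spec), abs=1e-8
        )

    def test_taxa_mismatch(self, five_leaf_tree):
        rng = np.random.default_rng(12)
        aln = random_alignment(rng, ["x", "y"], 3)
        spec = ov.CodonModelSpec(
            kappa=2.0,
            pi=uniform_pi(),
            site_classes=[(1.0, np.full(five_leaf_tree.n_branches, 0.5))],
        )
        with pytest.raises(ValueError, match="absent"):
            ov.log_likelihood(aln, five_leaf_tree, spec)

    def test_pattern_compression_counts(self, five_leaf_tree):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, five_leaf_tree.taxa, 6, ambiguity=False)
        # duplicate all columns; likelihood must exactly double
        dbl = ov.CodonAlignment(
            taxa=aln.taxa, cells=[row + row for row in aln.cells], nt_length=2 * aln.nt_length
        )
        pats = compress_patterns(dbl, five_leaf_tree)
        assert pats.counts.sum() == 12 and len(pats.counts) <= 6
        pi = rng.dirichlet(np.ones(61))
        spec = ov.CodonModelSpec(
            kappa=2.0, pi=pi, site_classes=[(1.0, np.full(five_leaf_tree.n_branches, 0.5))]
        )
        assert ov.log_likelihood(dbl, five_leaf_tree, spec) == pytest.approx(
            2 * ov.log_likelihood(aln, five_leaf_tree, spec)
        )


class TestFrequencies:
    def test_uniform(self, small_sim):
        aln, _, _ = small_sim
        pi = ov.estimate_codon_frequencies(aln, "uniform")
        assert np.allclose(pi, 1 / 61)

    def test_f61_pseudocount_closed_form(self):
        k = SENSE_CODONS.index("AAA")
        aln = ov.CodonAlignment(
            taxa=["a"], cells=[[frozenset([k])] * 10], nt_length=30
        )
        eps = 0.5
        pi = ov.estimate_codon_frequencies(aln, "F61", epsilon=eps)
        assert pi[k] == pytest.approx((10 + eps) / (10 + 61 * eps))

    def test_f3x4_recovers_positional_frequencies(self, five_leaf_tree):
        # simulate under a skewed pi and check F3x4 estimates are close
        rng = np.random.default_rng(14)
        part = ov.BranchPartition(["all"], {b: 0 for b in five_leaf_tree.branch_ids()})
        skew = np.linspace(1, 3, 61)
        pi_true = skew / skew.sum()
        spec = ov.SimulationSpec(
            tree=five_leaf_tree, partition=part, omega_by_class={"all": 1.0},
            pi=pi_true, L=3000, seed=21,
        )
        aln, _ = ov.simulate_alignment(spec)
        pi_hat = ov.estimate_codon_frequencies(aln, "F3x4")
        # F3x4 is a 9-parameter projection; compare at nucleotide level
        assert abs(pi_hat - pi_true).sum() < 0.25

    def test_empty_alignment(self):
        with pytest.raises(ValueError, match="empty"):
            ov.estimate_codon_frequencies(
                ov.CodonAlignment(taxa=[], cells=[], nt_length=0), "F61"
            )


class TestBetaCategories:
    def test_equal_probability_medians(self):
        rates = beta_category_rates(0.5, 1.5, 10)
        assert len(rates) == 10
        assert (np.diff(rates) > 0).all()
        assert (rates > 0).all() and (rates < 1).all()


class TestFitModel:
    def test_m0_recovers_simulated_omega(self, five_leaf_tree):
        part = ov.BranchPartition(["all"], {b: 0 for b in five_leaf_tree.branch_ids()})
        spec = ov.SimulationSpec(
            tree=five_leaf_tree, partition=part, omega_by_class={"all": 0.3},
            kappa=2.0, L=800, seed=17,
        )
        aln, _ = ov.simulate_alignment(spec)
        fit = ov.fit_model(aln, five_leaf_tree, "M0", n_starts=1, seed=1)
        assert fit.convergence["converged"]
        assert fit.estimates["omega"] == pytest.approx(0.3, abs=0.08)
        assert fit.estimates["kappa"] == pytest.approx(2.0, abs=0.5)

    def test_branch_1w_equals_m0(self, small_sim, five_leaf_tree):
        aln, _, _ = small_sim
        f1 = ov.fit_model(aln, five_leaf_tree, "1w", n_starts=1, seed=1)
        f2 = ov.fit_model(aln, five_leaf_tree, "M0", n_starts=1, seed=1)
        assert f1.lnl == pytest.approx(f2.lnl, abs=1e-6)
        assert f1.K == f2.K

    def test_model_a_null_fixes_omega2(self, small_sim, five_leaf_tree, five_leaf_table):
        aln, _, part2 = small_sim
        part = ov.BranchPartition(["all"], {b: 0 for b in five_leaf_tree.branch_ids()})
        fg = part.with_foreground(part2.branches_of_class("snake"))
        fit = ov.fit_model(aln, five_leaf_tree, "ModelA-null", partition=fg,
                           n_starts=1, seed=1, max_iter=60)
        assert fit.estimates["omega2"] == 1.0  # constrained, not optimized
        assert fit.K == 4 + five_leaf_tree.n_branches

    def test_branch_site_requires_foreground(self, small_sim, five_leaf_tree):
        aln, _, part = small_sim
        with pytest.raises(ValueError, match="foreground"):
            ov.fit_model(aln, five_leaf_tree, "ModelA", partition=part)

    def test_unknown_template(self, small_sim, five_leaf_tree):
        aln, _, _ = small_sim
        with pytest.raises(ValueError, match="template"):
            ov.fit_model(aln, five_leaf_tree, "M99")

    def test_refit_from_estimates_is_stable(self, small_sim, five_leaf_tree):
        aln, _, part = small_sim
        f = ov.fit_model(aln, five_leaf_tree, "2w", partition=part, n_starts=1, seed=1)
        g = ov.fit_model(
            aln, five_leaf_tree, "2w", partition=part, n_starts=1, seed=2,
            init={**{k: v for k, v in f.estimates.items()}, "branch_lengths": f.branch_lengths},
        )
        assert g.lnl == pytest.approx(f.lnl, abs=1e-4)
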