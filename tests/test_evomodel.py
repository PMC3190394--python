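import numpy as np
import pytest
from scipy.linalg import expm

from coevoscan import evomodel as em
from coevoscan.properties import AMINO_ACIDS

from conftest import brute_force_site_loglik


class TestAminoAcidModels:
    @pytest.mark.parametrize("name", ["wag", "lg"])
    def test_model_invariants(self, name):
        m = em.load_aa_model(name)
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-12
        assert abs(-np.sum(m.pi * np.diag(m.Q)) - 1.0) < 1e-10
        flux = m.pi[:, None] * m.Q
        assert np.abs(flux - flux.T).max() < 1e-12  # detailed balance

    def test_pi_is_left_null_vector(self, wag):
        assert np.abs(wag.pi @ wag.Q).max() < 1e-8

    def test_equal_rates_uniform_freqs_gives_equal_offdiagonals(self):
        exch = np.ones((20, 20))
        np.fill_diagonal(exch, 0)
        m = em.build_aa_model(exch, np.full(20, 0.05))
        off = m.Q[~np.eye(20, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_malformed_table_rejected(self):
        exch = np.ones((20, 20))
        exch[0, 1] = 2.0  # asymmetric
        with pytest.raises(ValueError):
            em.build_aa_model(exch, np.full(20, 0.05))
        with pytest.raises(ValueError):
            em.build_aa_model(np.ones((20, 20)), np.full(20, 0.06))

    def test_transition_matrix_matches_scipy_expm(self, wag):
        for t in [0.01, 0.5, 3.0]:
            assert np.abs(wag.transition_matrix(t) - expm(wag.Q * t)).max() < 1e-10

    def test_transition_rows_sum_to_one(self, wag):
        for t in [0.0, 0.1, 1.0, 10.0]:
            P = wag.transition_matrix(t)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
            assert P.min() >= 0


class TestCodonModel:
    def test_omega_zero_kills_nonsynonymous_rates(self):
        m = em.build_codon_model(2.0, 0.0)
        aa = em.CODON_AA_INDEX
        off = m.Q.copy()
        np.fill_diagonal(off, 0)
        assert off[aa[:, None] != aa[None, :]].max() == 0.0

    def test_kappa_one_omega_one_uniform_rates_equal(self):
        m = em.build_codon_model(1.0, 1.0)
        off = m.Q[m.Q > 0]
        assert np.allclose(off, off[0])

    def test_detailed_balance_random_parameters(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(61))
        m = em.build_codon_model(3.7, 0.41, pi)
        flux = m.pi[:, None] * m.Q
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_multi_nucleotide_changes_forbidden(self):
        m = em.build_codon_model(2.0, 0.5)
        for i, ci in enumerate(em.SENSE_CODONS[:10]):
            for j, cj in enumerate(em.SENSE_CODONS):
                ndiff = sum(a != b for a, b in zip(ci, cj))
                if ndiff > 1:
                    assert m.Q[i, j] == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            em.build_codon_model(-1.0, 0.5)
        with pytest.raises(ValueError):
            em.build_codon_model(2.0, -0.1)


class TestGammaRates:
    def test_single_category(self):
        g = em.discretize_gamma(0.7, 1)
        assert np.allclose(g.rates, [1.0])

    def test_huge_alpha_collapses_to_one(self):
        g = em.discretize_gamma(1e6, 4)
        assert np.abs(g.rates - 1).max() < 1e-2

    def test_mean_one_and_increasing(self):
        for alpha in [0.1, 0.5, 2.0, 7.0]:
            g = em.discretize_gamma(alpha, 4)
            assert abs(g.probs @ g.rates - 1) < 1e-10
            assert np.all(np.diff(g.rates) > 0)

    def test_bin_means_match_quadrature(self):
        from scipy import integrate, stats

        alpha, K = 0.5, 4
        g = em.discretize_gamma(alpha, K)
        dist = stats.gamma(a=alpha, scale=1 / alpha)
        edges = np.concatenate([[0], dist.ppf(np.arange(1, K) / K), [np.inf]])
        for k in range(K):
            val, _ = integrate.quad(
                lambda x: x * dist.pdf(x), edges[k], min(edges[k + 1], 200),
                limit=200,
            )
            assert abs(g.rates[k] - K * val) < 1e-6


class TestPruning:
    def test_matches_brute_force_amino_acid(self, wag, small_tree,
                                            small_protein_alignment):
        rates = em.discretize_gamma(0.8, 3)
        sl = em.site_log_likelihood(small_protein_alignment, small_tree, wag, rates)
        oracle = brute_force_site_loglik(
            small_protein_alignment, small_tree, wag, rates
        )
        assert np.abs(sl.per_site - oracle).max() < 1e-8
        assert abs(sl.total - sl.per_site.sum()) < 1e-9

    def test_matches_brute_force_codon_three_taxa(self):
        tree = em.Phylogeny.from_newick("(A:0.2,B:0.1,C:0.3);")
        aln = em.CodonAlignment(
            ["A", "B", "C"], ["ATGAAA", "ATGAAG", "ATGCAA"]
        )
        m = em.build_codon_model(2.0, 0.5)
        sl = em.site_log_likelihood(aln, tree, m)
        oracle = brute_force_site_loglik(aln, tree, m)
        assert np.abs(sl.per_site - oracle).max() < 1e-8

    def test_all_gap_column_contributes_zero(self, wag):
        tree = em.Phylogeny.from_newick("(A:0.1,B:0.2);")
        aln = em.ProteinAlignment(["A", "B"], ["-A", "-A"])
        sl = em.site_log_likelihood(aln, tree, wag, em.SINGLE_RATE)
        assert abs(sl.per_site[0]) < 1e-12

    def test_zero_branch_identical_sequences_gives_log_pi(self, wag):
        tree = em.Phylogeny.from_newick("(A:0.0,B:0.0);")
        aln = em.ProteinAlignment(["A", "B"], ["W", "W"])
        sl = em.site_log_likelihood(aln, tree, wag)
        w_idx = AMINO_ACIDS.index("W")
        assert abs(sl.per_site[0] - np.log(wag.pi[w_idx])) < 1e-10

    def test_likelihood_invariant_to_rerooting(self, wag):
        newicks = [
            "((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.02);",
            "(A:0.1,(B:0.2,((C:0.3,D:0.05):0.02):0.15):0.0);",
        ]
        aln = em.ProteinAlignment(["A", "B", "C", "D"], ["ACD", "AFD", "GCW", "ACD"])
        lls = [
            em.site_log_likelihood(aln, em.Phylogeny.from_newick(nwk), wag).total
            for nwk in newicks
        ]
        assert abs(lls[0] - lls[1]) < 1e-8

    def test_gamma_with_huge_alpha_equals_single_rate(self, wag, small_tree,
                                                      small_protein_alignment):
        single = em.site_log_likelihood(
            small_protein_alignment, small_tree, wag, em.SINGLE_RATE
        ).total
        mixed = em.site_log_likelihood(
            small_protein_alignment, small_tree, wag, em.discretize_gamma(1e8, 4)
        ).total
        assert abs(single - mixed) < 1e-6

    def test_label_mismatch_rejected(self, wag, small_tree):
        aln = em.ProteinAlignment(["A", "B", "C", "X"], ["A", "A", "A", "A"])
        with pytest.raises(ValueError, match="labels"):
            em.site_log_likelihood(aln, small_tree, wag)


class TestBranchOptimization:
    def test_two_sequence_distance_matches_closed_form(self):
        # equal-rates model: MLE distance has the classic closed form
        exch = np.ones((20, 20))
        np.fill_diagonal(exch, 0)
        m = em.build_aa_model(exch, np.full(20, 0.05))
        rng = np.random.default_rng(5)
        n = 1500
        a = rng.integers(0, 20, n)
        P = m.transition_matrix(0.6)
        b = np.array([em._sample_rows(P[[x]], rng)[0] for x in a])
        aln = em.ProteinAlignment(
            ["A", "B"],
            ["".join(AMINO_ACIDS[i] for i in a), "".join(AMINO_ACIDS[i] for i in b)],
        )
        tree = em.Phylogeny.from_newick("(A:0.1,B:0.1);")
        opt = em.optimize_branch_lengths(tree, aln, m)
        p_diff = np.mean(a != b)
        closed_form = -(19 / 20) * np.log(1 - 20 * p_diff / 19)
        assert abs(opt.total_length() - closed_form) < 1e-4

    def test_likelihood_never_decreases_and_idempotent(self, wag):
        rng = np.random.default_rng(7)
        true = em.Phylogeny.from_newick(
            "((A:0.15,B:0.05):0.1,(C:0.2,D:0.1):0.05,E:0.3);"
        )
        states = em.simulate_states(true, wag, 400, rng)
        aln = em.indices_to_protein(states, true.leaf_labels)
        start = true.copy()
        start.branch_lengths[start.parent >= 0] = 0.08
        opt = em.optimize_branch_lengths(start, aln, wag)
        ll_start = em.site_log_likelihood(aln, start, wag).total
        ll_opt = em.site_log_likelihood(aln, opt, wag).total
        assert ll_opt >= ll_start - 1e-6
        again = em.optimize_branch_lengths(opt, aln, wag, sweeps=1)
        assert np.abs(again.branch_lengths - opt.branch_lengths).max() < 1e-3

    def test_recovers_simulated_lengths(self, wag):
        rng = np.random.default_rng(13)
        true = em.Phylogeny.from_newick(
            "(((A:0.12,B:0.08):0.1,C:0.3):0.05,(D:0.2,E:0.07):0.15,F:0.25);"
        )
        states = em.simulate_states(true, wag, 2000, rng)
        aln = em.indices_to_protein(states, true.leaf_labels)
        start = true.copy()
        start.branch_lengths[start.parent >= 0] = 0.1
        opt = em.optimize_branch_lengths(start, aln, wag)
        nr = true.parent >= 0
        rel_err = np.abs(opt.branch_lengths[nr] - true.branch_lengths[nr])
        rel_err = rel_err / true.branch_lengths[nr]
        assert np.median(rel_err) < 0.15


class TestAlignments:
    def test_stop_codons_rejected(self):
        with pytest.raises(ValueError, match="stop codon"):
            em.CodonAlignment(["A"], ["ATGTAA"])

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            em.CodonAlignment(["A"], ["ATGA"])

    def test_translation_roundtrip(self):
        aln = em.CodonAlignment(["x", "y"], ["ATGAAA", "ATGGAA"])
        prot = aln.translate()
        assert prot.sequences == ["MK", "ME"]

    def test_fasta_roundtrip(self):
        aln = em.CodonAlignment(["x", "y"], ["ATGAAA", "ATGGAA"])
        again = em.CodonAlignment.from_fasta(aln.to_fasta())
        assert again.taxa == aln.taxa and again.sequences == aln.sequences

    def test_f3x4_frequencies_sum_to_one(self):
        aln = em.CodonAlignment(["x", "y"], ["ATGAAA", "ATGGAA"])
        pi = em.f3x4_frequencies(aln)
        assert abs(pi.sum() - 1) < 1e-12
        assert np.all(pi >= 0)
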