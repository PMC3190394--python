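import numpy as np
import pytest

from coevoscan import coevolution as cv
from coevoscan import evomodel as em
from coevoscan import synthdata as sd
from coevoscan.properties import AA_INDEX, PropertyScale


def _sample(site, events):
    return cv.SubstitutionSample(site=site, events=events)


class TestSampleHistories:
    def test_zero_branch_lengths_give_zero_events(self, wag):
        tree = em.Phylogeny.from_newick("(A:0.0,B:0.0);")
        aln = em.ProteinAlignment(["A", "B"], ["K", "K"])
        samples = cv.sample_substitution_histories(
            0, aln, tree, wag, n_samples=20, seed=1
        )
        assert all(s.total_events() == 0 for s in samples)

    def test_invariant_column_short_tree_low_posterior_count(self, wag):
        tree = em.Phylogeny.from_newick("(A:0.01,B:0.01);")
        aln = em.ProteinAlignment(["A", "B"], ["K", "K"])
        samples = cv.sample_substitution_histories(
            0, aln, tree, wag, n_samples=400, seed=2
        )
        mean_events = np.mean([s.total_events() for s in samples])
        assert mean_events < 0.05

    def test_events_chain_along_each_branch(self, wag):
        tree = em.Phylogeny.from_newick("(A:0.8,B:0.8);")
        aln = em.ProteinAlignment(["A", "B"], ["K", "E"])
        samples = cv.sample_substitution_histories(
            0, aln, tree, wag, n_samples=50, seed=3
        )
        for s in samples:
            for branch_events in s.events.values():
                for (f1, t1), (f2, t2) in zip(branch_events, branch_events[1:]):
                    assert t1 == f2

    def test_two_state_mean_count_matches_analytic_expectation(self):
        """Endpoint-conditioned expected substitution count on one branch,
        2-state chain, against the eigendecomposition closed form."""
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        pi = np.array([2 / 3, 1 / 3])
        t, a, b = 0.7, 0, 1

        # oracle: E[N | a, b] = sum_ij q_ij Int_0^t P(a,i,u) P(j,b,t-u) du / P(a,b,t)
        w, U = np.linalg.eigh(np.diag(np.sqrt(pi)) @ Q @ np.diag(1 / np.sqrt(pi)))
        right = U / np.sqrt(pi)[:, None]
        left = U.T * np.sqrt(pi)[None, :]
        J = np.empty((2, 2))
        for m in range(2):
            for l in range(2):
                if abs(w[m] - w[l]) < 1e-12:
                    J[m, l] = t * np.exp(w[m] * t)
                else:
                    J[m, l] = (np.exp(w[m] * t) - np.exp(w[l] * t)) / (w[m] - w[l])
        Pt = (right * np.exp(w * t)[None, :]) @ left
        expected = 0.0
        for i in range(2):
            for j in range(2):
                if i != j:
                    expected += Q[i, j] * (right[a] * left[:, i] @ J @ (right[j] * left[:, b]))
        expected /= Pt[a, b]

        rng = np.random.default_rng(4)
        M = 10000
        out = [[], [], [], [], []]
        model = em.SubstModel(states=("x", "y"), Q=Q, pi=pi, kind="aa")
        cv._sample_endpoint_paths(
            Q, t, np.full(M, a), np.full(M, b), model.transition_matrix(t),
            rng, out, 0, np.arange(M), np.zeros(M, dtype=int),
        )
        counts = np.bincount(np.concatenate(out[1]), minlength=M)
        se = counts.std() / np.sqrt(M)
        assert abs(counts.mean() - expected) < 3 * se


class TestWeightedVector:
    @pytest.mark.parametrize(
        "frm,to,prop,expected",
        [("D", "E", "charge", 0.0), ("K", "E", "charge", 2.0),
         ("L", "I", "grantham", 5.0)],
    )
    def test_single_event_weights(self, frm, to, prop, expected):
        samples = [_sample(0, {1: [(AA_INDEX[frm], AA_INDEX[to])]})]
        wv = cv.weighted_vector(samples, PropertyScale.get(prop), n_branches=3)
        assert wv.vector[1] == expected

    def test_compensatory_grantham_rejected(self):
        samples = [_sample(0, {1: [(0, 1)]})]
        with pytest.raises(ValueError):
            cv.weighted_vector(
                samples, PropertyScale.get("grantham"), mode="compensatory",
                n_branches=2,
            )

    def test_posterior_mean_over_samples(self):
        scale = PropertyScale.get("charge")
        samples = [
            _sample(0, {0: [(AA_INDEX["K"], AA_INDEX["E"])]}),
            _sample(0, {}),
        ]
        wv = cv.weighted_vector(samples, scale, n_branches=1)
        assert wv.vector[0] == 1.0  # 2.0 averaged over 2 samples
        assert wv.N == 0.5


class TestCorrelationStatistic:
    def _wv(self, vec):
        return cv.WeightedVector(site=0, property_name="charge",
                                 mode="correlated", vector=np.asarray(vec, float),
                                 N=1.0)

    def test_proportional_vectors(self):
        v = self._wv([1, 0, 2, 1])
        assert cv.correlation_statistic(v, self._wv([2, 0, 4, 2])) == pytest.approx(1.0)

    def test_antiproportional_vectors(self):
        v = self._wv([1.0, 0, 2, 1])
        neg = self._wv([-1.0, 0, -2, -1])
        assert cv.correlation_statistic(v, neg) == pytest.approx(-1.0)

    def test_hand_pearson_value(self):
        # (1,0,2,1) vs (0,1,1,2): centered dot product is exactly 0
        v1, v2 = self._wv([1, 0, 2, 1]), self._wv([0, 1, 1, 2])
        assert cv.correlation_statistic(v1, v2) == pytest.approx(0.0)

    def test_constant_vector_undefined(self):
        assert np.isnan(
            cv.correlation_statistic(self._wv([1, 1, 1, 1]), self._wv([1, 0, 1, 0]))
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cv.correlation_statistic(self._wv([1, 0]), self._wv([1, 0, 1]))

    def test_invariant_to_rescaling(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(10), rng.random(10)
        r1 = cv.correlation_statistic(self._wv(a), self._wv(b))
        r2 = cv.correlation_statistic(self._wv(3.5 * a), self._wv(0.2 * b))
        assert r1 == pytest.approx(r2)


class TestClusterCandidates:
    def test_duplicated_vectors_merge_first(self):
        rng = np.random.default_rng(0)
        V = rng.random((6, 12))
        V[3] = 2 * V[0]  # duplicate direction
        N = np.full(6, 3.0)
        cands = cv.cluster_candidates(V, N, "charge")
        first = min(cands, key=lambda g: 1 - g.rho)
        assert set(first.sites) == {0, 3}
        assert first.rho == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_centered_vectors_no_positive_rho(self):
        # rows of a Helmert-like design: centered and mutually orthogonal
        V = np.array([
            [1.0, -1.0, 0.0, 0.0],
            [0.5, 0.5, -1.0, 0.0],
            [1.0, 1.0, 1.0, -3.0],
        ])
        N = np.full(3, 5.0)
        cands = cv.cluster_candidates(V, N, "charge")
        assert all(g.rho <= 1e-9 for g in cands)

    def test_low_variability_sites_excluded(self):
        V = np.vstack([np.eye(3), np.eye(3)])
        N = np.array([5.0, 5.0, 0.2, 5.0, 0.5, 5.0])
        cands = cv.cluster_candidates(V, N, "charge", min_variability=1.0)
        used = {s for g in cands for s in g.sites}
        assert used <= {0, 1, 3, 5}

    def test_nmin_is_group_minimum(self):
        rng = np.random.default_rng(1)
        V = rng.random((5, 8))
        N = np.array([2.0, 7.0, 3.0, 9.0, 4.0])
        for g in cv.cluster_candidates(V, N, "charge"):
            assert g.n_min == pytest.approx(min(N[list(g.sites)]))

    def test_fewer_than_two_variable_sites_empty(self):
        V = np.ones((2, 4))
        N = np.array([5.0, 0.1])
        assert cv.cluster_candidates(V, N, "charge") == []


class TestGroupPvalue:
    def _null(self, n_min, rho):
        n = len(rho)
        return cv.NullDistribution(
            n_min=np.asarray(n_min, float), rho=np.asarray(rho, float),
            replicate=np.zeros(n, dtype=int), n_replicates=1,
        )

    def test_pseudocount_floor(self):
        null = self._null([2] * 100, np.linspace(-0.9, 0.9, 100))
        g = cv.CoevolGroup(sites=(0, 1), property_name="charge",
                           mode="correlated", rho=0.99, n_min=2.0)
        p = cv.group_pvalue(g, null, min_bin_count=10)
        assert p == pytest.approx(1 / 101)

    def test_rho_minus_one_gives_p_one(self):
        null = self._null([2] * 50, np.linspace(-0.9, 0.9, 50))
        g = cv.CoevolGroup(sites=(0, 1), property_name="charge",
                           mode="correlated", rho=-1.0, n_min=2.0)
        p = cv.group_pvalue(g, null, min_bin_count=10)
        assert p == pytest.approx(1.0, abs=1 / 51 + 1e-12)

    def test_monotone_in_rho(self):
        rng = np.random.default_rng(5)
        null = self._null([3] * 300, rng.uniform(-1, 1, 300))
        ps = []
        for rho in [0.2, 0.5, 0.8, 0.95]:
            g = cv.CoevolGroup(sites=(0, 1), property_name="charge",
                               mode="correlated", rho=rho, n_min=3.0)
            ps.append(cv.group_pvalue(g, null, min_bin_count=10))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_nearest_bin_fallback_warns(self):
        # every null entry sits at N_min 3, so the low bin [0, 3) is empty
        null = self._null([3] * 60, np.linspace(-1, 1, 60))
        g = cv.CoevolGroup(sites=(0, 1), property_name="charge",
                           mode="correlated", rho=0.5, n_min=1.0)
        with pytest.warns(UserWarning, match="falling back"):
            cv.group_pvalue(g, null, min_bin_count=10)

    def test_empty_null_rejected(self):
        null = self._null([], [])
        g = cv.CoevolGroup(sites=(0, 1), property_name="charge",
                           mode="correlated", rho=0.5, n_min=2.0)
        with pytest.raises(ValueError):
            cv.group_pvalue(g, null)


class TestNullDistribution:
    def test_single_replicate_recorded(self, wag):
        tree = sd.simulate_tree(8, 0.8, seed=1)
        nd = cv.null_distribution(
            tree, wag, em.discretize_gamma(1.0, 2), n_sites=12,
            properties=("polarity",), n_samples=5, n_reps=1, seed=0,
        )[("polarity", "correlated")]
        assert nd.n_replicates == 1
        assert set(nd.replicate) <= {0}

    def test_seed_determinism(self, wag):
        tree = sd.simulate_tree(8, 0.8, seed=1)
        kwargs = dict(n_sites=10, properties=("charge",), n_samples=5,
                      n_reps=3, seed=42)
        a = cv.null_distribution(tree, wag, em.SINGLE_RATE, **kwargs)
        b = cv.null_distribution(tree, wag, em.SINGLE_RATE, **kwargs)
        ka, kb = a[("charge", "correlated")], b[("charge", "correlated")]
        assert np.array_equal(ka.rho, kb.rho)
        assert np.array_equal(ka.n_min, kb.n_min)

    def test_size_two_null_rho_is_selection_inflated(self, wag):
        """Dendrogram pair candidates are the best-correlated of many
        pairs, so their null rho sits well above 0."""
        tree = sd.simulate_tree(12, 1.0, seed=2)
        nd = cv.null_distribution(
            tree, wag, em.SINGLE_RATE, n_sites=30, properties=("polarity",),
            n_samples=10, n_reps=10, seed=3,
        )[("polarity", "correlated")]
        assert len(nd) > 0
        assert np.median(nd.rho[nd.n_min >= 1]) > 0.0


class TestDetectCoevolution:
    def test_charge_invariant_alignment_gives_no_charge_groups(self):
        # all residues neutral: charge vectors are identically zero
        rng = np.random.default_rng(0)
        neutral = "AGSTVLIPFMW"
        tree = sd.simulate_tree(8, 0.8, seed=5)
        seqs = ["".join(rng.choice(list(neutral), 15)) for _ in range(8)]
        aln = em.ProteinAlignment(tree.leaf_labels, seqs)
        res = cv.detect_coevolution(
            aln, tree, properties=("charge",),
            config=cv.CoevolConfig(n_samples=5, n_bootstrap=5, seed=1,
                                   fit_gamma_shape=False,
                                   optimize_branches=False),
        )
        assert res.significant == []

    def test_end_to_end_determinism(self):
        cfg = sd.SimulationConfig(n_taxa=8, n_codons=15, seed=3)
        aln, tree, _ = sd.simulate_dataset(cfg)
        ccfg = cv.CoevolConfig(n_samples=5, n_bootstrap=10, seed=11,
                               fit_gamma_shape=False)
        r1 = cv.detect_coevolution(aln, tree, ("polarity",), ccfg)
        r2 = cv.detect_coevolution(aln, tree, ("polarity",), ccfg)
        assert r1.to_frame().equals(r2.to_frame())
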