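"""Mutation models: GSM microsatellites and nucleotide substitution."""

import numpy as np
import pytest
import scipy.linalg
import scipy.stats

from coalabc.coalescent import GeneTree
from coalabc.loci import LocusSpec
from coalabc.mutation import (
    MicrosatModel,
    SequenceModel,
    draw_locus_rates,
    mutate_microsat,
    mutate_sequence,
    substitution_probability,
)
from coalabc.scenarios import parse_config
from coalabc.coalescent import simulate_genealogy


def star_tree(n_leaves, depth):
    """A star genealogy: n leaves joined at one root of age `depth` (built
    as a caterpillar with all internal nodes at the same age)."""
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, np.int64)
    time = np.zeros(n_nodes)
    time[n_leaves:] = depth
    parent[0] = n_leaves
    parent[1] = n_leaves
    for k in range(1, n_leaves - 1):
        parent[n_leaves + k - 1] = n_leaves + k
        parent[k + 1] = n_leaves + k
    return GeneTree(
        parent=parent, time=time, n_leaves=n_leaves,
        leaf_sample=np.zeros(n_leaves, np.int64), sample_names=["A"],
    )


def two_leaf_tree(depth):
    return star_tree(2, depth)


class TestLocusRates:
    def test_huge_shape_concentrates_at_mean(self, rng):
        r = draw_locus_rates(5e-4, 1e6, 2000, rng)
        assert np.all(np.abs(r - 5e-4) / 5e-4 < 0.01)

    def test_mean_and_variance(self, rng):
        r = draw_locus_rates(5e-4, 2.0, 100_000, rng)
        assert abs(r.mean() - 5e-4) / 5e-4 < 0.02
        assert abs(r.var() - 5e-4 ** 2 / 2) / (5e-4 ** 2 / 2) < 0.05

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            draw_locus_rates(0.0, 2.0, 5, rng)
        with pytest.raises(ValueError):
            draw_locus_rates(1e-4, 0.0, 5, rng)


class TestMicrosat:
    def test_zero_rates_keep_ancestral_allele(self, rng):
        tree = star_tree(8, 1000.0)
        model = MicrosatModel(mu=0.0, p=0.2)
        rep, off = mutate_microsat(tree, model, rng)
        assert np.all(rep == model.ancestral_repeats)
        assert np.all(off == 0)

    def test_strict_stepwise_when_p_zero(self, rng):
        """P=0 degenerates to the strict stepwise model: parent-child repeat
        differences on a two-leaf tree are bounded by the mutation count."""
        model = MicrosatModel(mu=0.02, p=0.0, range_width=4000, ancestral_repeats=2000)
        # with a huge range no redraws occur; each mutation steps exactly 1,
        # so the leaf-ancestor distance never exceeds the Poisson count and
        # has its parity: verify via variance = mu * t for single-step GSM
        t = 500.0
        tree = two_leaf_tree(t)
        d = []
        for _ in range(4000):
            rep, _ = mutate_microsat(tree, model, rng)
            d.append(rep[0] - model.ancestral_repeats)
        # var of a +-1 random walk with Poisson(mu t) steps is mu t
        assert abs(np.var(d) - model.mu * t) / (model.mu * t) < 0.15

    def test_alleles_confined_to_range(self, rng):
        tree = star_tree(10, 20_000.0)
        model = MicrosatModel(mu=5e-3, p=0.3, range_width=40)
        lo, hi = model.bounds
        for _ in range(300):
            rep, _ = mutate_microsat(tree, model, rng)
            assert rep.min() >= lo and rep.max() <= hi
        assert hi - lo + 1 == 40

    def test_smm_pairwise_variance_on_star_tree(self, rng):
        """Under the strict stepwise model the allele-size variance between
        two copies separated by 2T generations is 2 mu T."""
        mu, T = 5e-3, 1000.0
        model = MicrosatModel(mu=mu, p=0.0, range_width=4000, ancestral_repeats=2000)
        tree = two_leaf_tree(T)
        diffs = []
        for _ in range(4000):
            rep, _ = mutate_microsat(tree, model, rng)
            diffs.append(rep[0] - rep[1])
        expected = 2 * mu * T
        assert abs(np.var(diffs) - expected) / expected < 0.15

    def test_sni_offsets_move_off_lattice(self, rng):
        tree = star_tree(6, 2000.0)
        model = MicrosatModel(mu=0.0, p=0.2, sni_rate=1e-3)
        _, off = mutate_microsat(tree, model, rng)
        # offsets follow a +-1 walk; over many replicates some are nonzero
        offs = np.concatenate(
            [mutate_microsat(tree, model, rng)[1] for _ in range(50)]
        )
        assert np.any(offs != 0)


class TestSubstitutionKernels:
    MODELS = [
        SequenceModel(kind="JC", rate=1.0),
        SequenceModel(kind="K2P", rate=1.0, kappa=8.0),
        SequenceModel(kind="HKY", rate=1.0, kappa=4.0, freqs=(0.3, 0.2, 0.2, 0.3)),
        SequenceModel(kind="TN", rate=1.0, kappa1=3.0, kappa2=6.0,
                      freqs=(0.1, 0.4, 0.2, 0.3)),
    ]

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.kind)
    def test_identity_at_zero_and_rows_sum_to_one(self, model):
        P0 = substitution_probability(model, 0.0)
        assert np.allclose(P0, np.eye(4), atol=1e-12)
        P = substitution_probability(model, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.kind)
    def test_chapman_kolmogorov(self, model):
        P1 = substitution_probability(model, 0.35)
        P2 = substitution_probability(model, 0.85)
        P12 = substitution_probability(model, 1.2)
        assert np.abs(P1 @ P2 - P12).max() < 1e-10

    def test_jc_closed_form_vs_matrix_exponential(self):
        model = SequenceModel(kind="JC", rate=1.0)
        for t in (0.01, 0.3, 2.0):
            P = substitution_probability(model, t)
            E = scipy.linalg.expm(model.rate_matrix() * t)
            assert np.abs(P - E).max() < 1e-12
            q = 0.25 * (1 - np.exp(-4 * t / 3))
            assert P[0, 1] == pytest.approx(q, abs=1e-15)

    def test_k2p_with_equal_rates_reproduces_jc(self):
        jc = SequenceModel(kind="JC", rate=1.0)
        k2p = SequenceModel(kind="K2P", rate=1.0, kappa=1.0)
        for t in (0.05, 0.4, 1.5):
            assert np.abs(
                substitution_probability(jc, t) - substitution_probability(k2p, t)
            ).max() < 1e-12

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            substitution_probability(self.MODELS[0], -0.1)

    @pytest.mark.parametrize("model", MODELS, ids=lambda m: m.kind)
    def test_stationary_frequencies_preserved(self, model):
        pi = model.pi
        P = substitution_probability(model, 0.9)
        assert np.allclose(pi @ P, pi, atol=1e-10)


class TestSequenceSimulation:
    def test_zero_branch_lengths_copy_ancestor(self, rng):
        tree = star_tree(5, 0.0)
        model = SequenceModel(kind="K2P", rate=1e-2, kappa=5.0)
        seqs = mutate_sequence(tree, model, 200, rng)
        assert np.all(seqs == seqs[0])

    def test_invariant_sites_stay_monomorphic(self, rng):
        tree = star_tree(20, 500.0)
        model = SequenceModel(kind="JC", rate=2e-3, invariant=0.10, gamma_shape=2.0)
        n_poly = []
        for _ in range(20):
            seqs = mutate_sequence(tree, model, 1000, rng)
            poly = np.any(seqs != seqs[0], axis=0)
            n_poly.append(poly.sum())
            # at least the invariant 10% of positions can never vary
            assert poly.sum() <= 900
        assert max(n_poly) > 0

    def test_small_distance_divergence_linearizes(self, rng):
        """Two sequences at total distance d differ at ~ d (1 - invariant)
        of their sites for small d."""
        inv = 0.10
        mu, T = 1e-5, 500.0  # one-sided depth; pair distance 2 mu T = 0.01
        model = SequenceModel(kind="K2P", rate=mu, kappa=4.0, invariant=inv)
        tree = two_leaf_tree(T)
        L = 5000
        fracs = []
        for _ in range(60):
            seqs = mutate_sequence(tree, model, L, rng)
            fracs.append(np.mean(seqs[0] != seqs[1]))
        d = 2 * mu * T
        expected = d * (1 - inv)
        got = np.mean(fracs)
        assert abs(got - expected) / expected < 0.10

    def test_stationarity_on_long_branch(self, rng):
        """Simulating a long single branch preserves the stationary base
        frequencies (chi-square goodness of fit on 1e5 sites)."""
        model = SequenceModel(kind="TN", rate=5e-3, kappa1=3.0, kappa2=5.0,
                              freqs=(0.15, 0.35, 0.3, 0.2))
        tree = two_leaf_tree(400.0)  # pair distance 4: well past saturation
        seqs = mutate_sequence(tree, model, 100_000, rng)
        counts = np.bincount(seqs[0], minlength=4)
        expected = np.asarray(model.pi) * counts.sum()
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        assert chi2 < scipy.stats.chi2.ppf(0.999, df=3)

    def test_uniformization_matches_kernel_on_two_sequences(self, rng):
        """Empirical base-change frequencies over one branch match the
        closed-form transition kernel (the simulator uses uniformized jumps,
        the kernel the closed form: two independent routes)."""
        model = SequenceModel(kind="K2P", rate=1e-3, kappa=6.0)
        t = 300.0
        tree = two_leaf_tree(t)
        L = 40_000
        seqs = mutate_sequence(tree, model, L, rng)
        # distance leaf-to-leaf is 2 t mu
        P = substitution_probability(model, 2 * t * model.rate)
        a, b = seqs[0].astype(int), seqs[1].astype(int)
        joint = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                joint[i, j] = np.sum((a == i) & (b == j))
        cond = joint / joint.sum(axis=1, keepdims=True)
        assert np.abs(cond - P).max() < 0.02


class TestEndToEndLocus:
    def test_watterson_segregating_sites_and_pi(self, rng):
        """E[S] = theta * sum 1/i and mean pairwise diversity = theta for a
        constant population (theta = 2 C mu L), within Monte-Carlo error."""
        cfg = parse_config("[samples]\nA 10\n[scenario 1]\npop A 1000\nsample 0 A\n")
        scen = cfg.scenario(1)
        spec = LocusSpec(name="L1", category="H", kind="seq")
        mu, L, n = 2e-6, 1000, 10
        model = SequenceModel(kind="JC", rate=mu)
        theta = 2 * 1000 * mu * L
        S, P = [], []
        iu = np.triu_indices(n, 1)
        for _ in range(5000):
            tree = simulate_genealogy(scen, {}, spec, cfg.samples, rng)
            seqs = mutate_sequence(tree, model, L, rng)
            S.append(int(np.any(seqs != seqs[0], axis=0).sum()))
            D = (seqs[:, None, :] != seqs[None, :, :]).sum(2)
            P.append(D[iu].mean())
        h = sum(1.0 / i for i in range(1, n))
        S = np.asarray(S, float)
        P = np.asarray(P, float)
        se_S = S.std() / np.sqrt(len(S))
        se_P = P.std() / np.sqrt(len(P))
        # finite-sites multiple hits bias expectations slightly downward
        assert abs(S.mean() - theta * h) < max(3 * se_S, 0.02 * theta * h)
        assert abs(P.mean() - theta) < max(3 * se_P, 0.02 * theta)
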