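"""Summary statistics: worked examples, oracle equivalence, invariants."""

import numpy as np
import pytest

from coalabc.sumstats import (
    GenotypeDataset,
    Locus,
    SampleInfo,
    admixture_mle,
    microsat_between,
    microsat_within,
    seq_between,
    seq_within,
    summarize_dataset,
)

from _naive import naive_summarize


def seqs(*strings):
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([[code[c] for c in s] for s in strings], np.uint8)


class TestMicrosatWithin:
    def test_monomorphic_sample(self):
        r = microsat_within(np.array([100, 100, 100, 100]))
        assert r == {"NAL": 1.0, "HET": 0.0, "VAR": 0.0, "MGW": 1.0}

    def test_hand_enumerated_example(self):
        # 4 copies {100,100,104,108}, motif 4: NAL=3, HET=(4/3)(1-(1/4+1/16+1/16)),
        # VAR = sample variance, MGW = 3 states over a 3-state span
        r = microsat_within(np.array([100, 100, 104, 108]), motif=4)
        assert r["NAL"] == 3.0
        assert r["HET"] == pytest.approx((4 / 3) * (1 - (0.25 + 0.0625 + 0.0625)))
        assert r["VAR"] == pytest.approx(np.var([100, 100, 104, 108], ddof=1))
        assert r["VAR"] == pytest.approx(44 / 3)
        assert r["MGW"] == pytest.approx(1.0)

    def test_two_locus_average_is_mean_of_single_locus_values(self):
        ds = GenotypeDataset(samples=[SampleInfo("A", 0, 2)])
        si = np.zeros(4, np.int64)
        ds.loci = [
            Locus("L1", "A", "microsat", np.array([100, 100, 104, 108]), si, motif=4),
            Locus("L2", "A", "microsat", np.array([100, 104, 104, 104]), si, motif=4),
        ]
        v = summarize_dataset(ds, ["NAL"])
        one = microsat_within(ds.loci[0].data, 4)["NAL"]
        two = microsat_within(ds.loci[1].data, 4)["NAL"]
        assert v["NAL_A"] == pytest.approx((one + two) / 2)


class TestMicrosatBetween:
    def test_identical_samples_have_zero_distance(self):
        a = np.array([100, 102, 104, 102])
        r = microsat_between(a, a.copy())
        assert r["DM2"] == 0.0
        das = r["DAS"]
        # DAS is 1 - expected allele sharing; identical frequency
        # distributions still share less than 100% of random copy pairs
        p = np.array([0.25, 0.5, 0.25])
        assert das == pytest.approx(1 - np.sum(p * p))

    def test_fixed_difference_gives_fst_one(self):
        a = np.full(10, 100)
        b = np.full(10, 108)
        r = microsat_between(a, b)
        assert r["FST_NUM"] / r["FST_DEN"] == pytest.approx(1.0)

    def test_toy_frequencies_match_direct_estimator(self):
        # pA=(0.5,0.5), pB=(1,0), n=20 copies each
        a = np.array([100] * 10 + [102] * 10)
        b = np.array([100] * 20)
        r = microsat_between(a, b)
        # direct evaluation of the variance-component estimator
        n1 = n2 = 20
        ntot = 40
        nc = ntot - (n1 ** 2 + n2 ** 2) / ntot
        num = den = 0.0
        for p1, p2 in ((0.5, 1.0), (0.5, 0.0)):
            pbar = (n1 * p1 + n2 * p2) / ntot
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
            num += msp - msg
            den += msp + (nc - 1) * msg
        assert r["FST_NUM"] / r["FST_DEN"] == pytest.approx(num / den)


class TestAdmixtureMLE:
    def _tables(self, vals, counts):
        return [(np.asarray(vals), np.asarray(counts))]

    def test_boundary_pure_parent1(self):
        p1 = self._tables([100, 102], [80, 20])
        p2 = self._tables([100, 102], [20, 80])
        mix = self._tables([100, 102], [800, 200])
        est = admixture_mle(p1, p2, mix)
        assert not est.degenerate
        assert est.r >= 0.99

    def test_symmetric_midpoint_gives_half(self):
        p1 = self._tables([100, 102], [80, 20])
        p2 = self._tables([100, 102], [20, 80])
        mix = self._tables([100, 102], [50, 50])
        est = admixture_mle(p1, p2, mix)
        assert est.r == pytest.approx(0.5, abs=1e-3)

    def test_binomial_closed_form(self):
        # 2 alleles, p1=0.8, p2=0.2, admixed counts 30/70:
        # MLE solves r*0.8+(1-r)*0.2 = 0.3 -> r = 1/6
        p1 = self._tables([1, 2], [80, 20])
        p2 = self._tables([1, 2], [20, 80])
        mix = self._tables([1, 2], [30, 70])
        est = admixture_mle(p1, p2, mix)
        assert est.r == pytest.approx((0.3 - 0.2) / (0.8 - 0.2), abs=1e-4)

    def test_indistinguishable_parents_flagged(self):
        p = self._tables([1, 2], [50, 50])
        est = admixture_mle(p, [(\
            np.asarray([1, 2]), np.asarray([50, 50]))], p)
        assert est.degenerate and est.r == 0.5


class TestSeqStats:
    def test_identical_sequences(self):
        s = seqs("ACGT", "ACGT", "ACGT")
        assert seq_within(s) == {"NHA": 1.0, "NSS": 0.0, "MPD": 0.0, "VPD": 0.0}

    def test_pair_enumeration_example(self):
        s = seqs("AAA", "AAT", "ATT")
        r = seq_within(s)
        assert r["NHA"] == 3.0
        assert r["NSS"] == 2.0
        assert r["MPD"] == pytest.approx((1 + 2 + 1) / 3)
        assert r["VPD"] == pytest.approx(np.var([1, 2, 1], ddof=1))

    def test_duplicating_sequences_keeps_nss(self):
        s = seqs("AAA", "AAT", "ATT")
        s2 = np.concatenate([s, s])
        assert seq_within(s2)["NSS"] == seq_within(s)["NSS"]

    def test_reciprocally_monophyletic_pools_haplotypes(self):
        a = seqs("AAAA", "AAAT")
        b = seqs("TTAA", "TTAT")
        r = seq_between(a, b)
        assert r["NHA2P"] == 4.0

    def test_hudson_fst_extreme(self):
        a = seqs("AAAA", "AAAA")
        b = seqs("TTTT", "TTTT")
        r = seq_between(a, b)
        assert r["FSQ"] == pytest.approx(1.0)

    def test_identical_samples_fst_zero(self):
        a = seqs("AACT", "AGCT", "AACT")
        r = seq_between(a, a.copy())
        assert r["FSQ"] == pytest.approx(0.0, abs=1e-9)


class TestSummarizeDataset:
    SELECTION = [
        "NAL", "HET", "VAR", "MGW", "FST", "DM2", "H2P", "DAS", "LIK",
        "NHA", "NSS", "MPD", "VPD", "NHA2P", "NSS2P", "FSQ",
    ]

    def test_requesting_sequence_stats_without_sequences_errors(self, random_small_dataset):
        ds = random_small_dataset(n_seq=0, seed=5)
        with pytest.raises(ValueError, match="NSS"):
            summarize_dataset(ds, ["NAL", "NSS"])

    def test_unknown_sample_name_errors(self, random_small_dataset):
        ds = random_small_dataset(seed=6)
        with pytest.raises(ValueError, match="unknown sample"):
            summarize_dataset(ds, ["FST_P1_P9"])

    def test_header_is_deterministic_and_order_stable(self, random_small_dataset):
        ds = random_small_dataset(seed=7)
        v1 = summarize_dataset(ds, self.SELECTION)
        v2 = summarize_dataset(ds, self.SELECTION[::-1])
        assert list(v1.index) == list(v2.index)
        assert np.array_equal(v1.to_numpy(), v2.to_numpy())

    def test_oracle_equivalence_on_random_datasets(self, random_small_dataset):
        """Every statistic matches a naive double-loop reimplementation on
        100 random small datasets to 1e-10."""
        for k in range(100):
            ds = random_small_dataset(n_samples=2, n_ind=5, n_mic=2, n_seq=1,
                                      seq_len=20, seed=1000 + k)
            v = summarize_dataset(ds, self.SELECTION)
            naive = naive_summarize(ds, list(v.index))
            for name in v.index:
                assert v[name] == pytest.approx(naive[name], abs=1e-10), name

    def test_label_invariance_under_permutation(self, random_small_dataset):
        """Permuting individuals within samples leaves every statistic
        unchanged."""
        rng = np.random.default_rng(9)
        for k in range(10):
            ds = random_small_dataset(n_samples=2, n_ind=6, seed=2000 + k)
            v1 = summarize_dataset(ds, self.SELECTION)
            ds2 = GenotypeDataset(samples=ds.samples, loci=[])
            for loc in ds.loci:
                perm = np.arange(len(loc.sample_index))
                for s in range(2):
                    idx = np.flatnonzero(loc.sample_index == s)
                    if loc.kind == "microsat":
                        # permute whole individuals (copy pairs)
                        pairs = idx.reshape(-1, 2)
                        pairs = pairs[rng.permutation(len(pairs))]
                        perm[idx] = pairs.ravel()
                    else:
                        perm[idx] = rng.permutation(idx)
                ds2.loci.append(
                    Locus(loc.name, loc.category, loc.kind,
                          loc.data[perm], loc.sample_index.copy(), loc.motif)
                )
            v2 = summarize_dataset(ds2, self.SELECTION)
            assert np.allclose(v1.to_numpy(), v2.to_numpy(), atol=1e-10)

    def test_bounds_over_random_datasets(self, random_small_dataset):
        """HET, H2P, DAS in [0,1]; MGW in (0,1]; FST in [-1,1]."""
        for k in range(200):
            ds = random_small_dataset(n_samples=2, n_ind=4, n_mic=2, n_seq=1,
                                      seq_len=12, seed=3000 + k)
            v = summarize_dataset(ds, ["HET", "H2P", "DAS", "MGW", "FST", "FSQ"])
            for name, x in v.items():
                fam = name.split("_")[0]
                if fam in ("HET", "H2P", "DAS"):
                    assert 0.0 <= x <= 1.0
                elif fam == "MGW":
                    assert 0.0 < x <= 1.0
                elif fam in ("FST", "FSQ"):
                    assert -1.0 <= x <= 1.0

    def test_panmictic_fst_centered_at_zero(self, one_pop_config, rng):
        """Microsatellite FST between two halves of one panmictic sample is
        centered near 0."""
        from coalabc.inference import simulate_dataset
        from coalabc.scenarios import draw_parameters, parse_config

        cfg = parse_config(
            "[priors]\nMU ~ U[1e-4,1e-3]\nP ~ U[0.1,0.3]\n"
            "[loci]\nmicrosat 3 <A> motif=2 mu=MU P=P\n"
            "[samples]\nA 8\nB 8\n"
            "[scenario 1]\npop A 1000\npop B 1000\nsample 0 A\nsample 0 B\nmerge 0 A B\n"
        )
        vals = []
        for _ in range(1000):
            params = draw_parameters(cfg.priors, cfg.conditions, rng)
            ds = simulate_dataset(cfg, cfg.scenario(1), params, rng)
            vals.append(summarize_dataset(ds, ["FST"])["FST_A_B"])
        assert abs(np.mean(vals)) < 0.01
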