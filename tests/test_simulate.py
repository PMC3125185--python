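import numpy as np
import pytest

import popkdic as pk
from popkdic.simulate import Genealogy, expected_autozygosity


def pair_tmrca(gen, a, b):
    anc = {}
    x = a
    while x != -1:
        anc[x] = gen.node_time[x]
        x = gen.parent[x]
    x = b
    while x not in anc:
        x = gen.parent[x]
    return gen.node_time[x]


class TestGenealogy:
    def test_single_deme_pair_tmrca_is_half(self):
        """Pair coalescence at rate 2 (time in 4N units) => E[TMRCA] = 0.5."""
        model = pk.DemographicModel("split", 1)
        rng = np.random.default_rng(1)
        times = [
            pk.simulate_genealogy(model, [2], rng).node_time[2] for _ in range(4000)
        ]
        # sd of Exp(2) is 0.5 -> 4 sigma ~ 0.032
        assert np.mean(times) == pytest.approx(0.5, abs=0.032)

    def test_no_cross_deme_coalescence_before_split(self):
        model = pk.DemographicModel("split", 2, split_time=0.5)
        rng = np.random.default_rng(2)
        for _ in range(50):
            gen = pk.simulate_genealogy(model, [4, 4], rng)
            for a in range(4):
                for b in range(4, 8):
                    assert pair_tmrca(gen, a, b) >= 0.5

    def test_between_deme_tmrca_split(self):
        """Across a split at tau, E[T] = tau + 0.5 (merged ancestral deme)."""
        model = pk.DemographicModel("split", 2, split_time=0.5)
        rng = np.random.default_rng(3)
        times = [
            pair_tmrca(pk.simulate_genealogy(model, [1, 1], rng), 0, 1)
            for _ in range(4000)
        ]
        assert np.mean(times) == pytest.approx(1.0, abs=0.032)

    def test_matches_msprime_island_split(self):
        """Within/between pair TMRCA agree with an independent coalescent
        simulator under the same split-plus-migration demography."""
        msprime = pytest.importorskip("msprime")
        M, tau, reps = 10.0, 0.5, 3000
        model = pk.DemographicModel("island_split", 2, split_time=tau, migration_rate=M)
        rng = np.random.default_rng(4)
        ours_w, ours_b = [], []
        for _ in range(reps):
            gen = pk.simulate_genealogy(model, [2, 2], rng)
            ours_w.append(pair_tmrca(gen, 0, 1))
            ours_b.append(pair_tmrca(gen, 0, 2))
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=0.25)
        dem.add_population(name="B", initial_size=0.25)
        dem.add_population(name="anc", initial_size=0.25)
        dem.set_migration_rate("A", "B", M)
        dem.set_migration_rate("B", "A", M)
        dem.add_population_split(time=tau, derived=["A", "B"], ancestral="anc")
        ref_w, ref_b = [], []
        for ts in msprime.sim_ancestry(
            samples={"A": 1, "B": 1}, demography=dem, ploidy=2,
            num_replicates=reps, random_seed=11,
        ):
            tr = ts.first()
            ref_w.append(tr.tmrca(0, 1))
            ref_b.append(tr.tmrca(0, 2))
        for ours, ref in [(ours_w, ref_w), (ours_b, ref_b)]:
            se = np.hypot(np.std(ours), np.std(ref)) / np.sqrt(reps)
            assert abs(np.mean(ours) - np.mean(ref)) < 4 * se + 1e-9


class TestMutation:
    def test_single_site_always_polymorphic(self):
        model = pk.DemographicModel("split", 2)
        rng = np.random.default_rng(5)
        for _ in range(100):
            gen = pk.simulate_genealogy(model, [3, 3], rng)
            alleles = pk.mutate_one_site(gen, rng)
            assert set(np.unique(alleles)) == {0, 1}

    def test_placement_proportional_to_branch_length(self):
        # two tips, branches of length 0.9 and 0.1 (non-ultrametric star)
        gen = Genealogy(
            parent=np.array([2, 2, -1]),
            node_time=np.array([0.0, 0.9, 1.0]),
            n_leaves=2,
            leaf_demes=np.array([0, 0]),
        )
        rng = np.random.default_rng(6)
        hits = sum(int(pk.mutate_one_site(gen, rng)[0]) for _ in range(3000))
        assert hits / 3000 == pytest.approx(0.9, abs=0.03)


class TestSelfing:
    def test_no_selfing_is_plain_pairing(self):
        rng = np.random.default_rng(7)
        haps = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        demes = np.repeat([0, 1], 10)
        geno, ind_deme = pk.diploidize_with_selfing(haps, demes, np.zeros(2), rng)
        assert np.array_equal(geno[:, :, 0], haps[::2])
        assert np.array_equal(geno[:, :, 1], haps[1::2])
        assert ind_deme.tolist() == [0] * 5 + [1] * 5

    def test_autozygosity_closed_form(self):
        """Mean per-locus autozygosity equals s/(2-s) under geometric
        selfing-generation counts; measured as homozygosity of all-het input."""
        s = 0.5
        assert expected_autozygosity(s) == pytest.approx(1.0 / 3.0)
        rng = np.random.default_rng(8)
        n_ind, L = 6000, 20
        haps = np.zeros((2 * n_ind, L), dtype=np.int8)
        haps[1::2] = 1  # every pair heterozygous at every locus
        geno, _ = pk.diploidize_with_selfing(
            haps, np.zeros(2 * n_ind, dtype=int), np.array([s]), rng
        )
        hom = (geno[:, :, 0] == geno[:, :, 1]).mean()
        assert hom == pytest.approx(1.0 / 3.0, abs=0.015)

    def test_invalid_selfing_rate_rejected(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        with pytest.raises(ValueError, match="selfing"):
            pk.diploidize_with_selfing(haps, np.zeros(4, int), np.array([1.0]), 1)

    def test_generation_cap_bounds_autozygosity(self):
        # at s close to 1 the cap at 10 generations bounds p_auto by 1 - 2^-10
        rng = np.random.default_rng(9)
        n_ind = 4000
        haps = np.zeros((2 * n_ind, 1), dtype=np.int8)
        haps[1::2] = 1
        geno, _ = pk.diploidize_with_selfing(
            haps, np.zeros(2 * n_ind, int), np.array([0.999]), rng
        )
        hom = (geno[:, :, 0] == geno[:, :, 1]).mean()
        assert hom <= 1.0 - 2.0**-10 + 3 * np.sqrt(0.001 / n_ind)
        assert hom > 0.98


class TestHudsonFst:
    def _table(self, geno):
        geno = np.asarray(geno, dtype=np.int32)
        n, l, _ = geno.shape
        return pk.GenotypeTable(
            alleles=geno,
            locus_allele_counts=np.full(l, 2),
            individual_labels=[f"i{j}" for j in range(n)],
        )

    def test_fixed_difference_gives_one(self):
        geno = [[[0, 0]]] * 5 + [[[1, 1]]] * 5
        summ = pk.hudson_fst(self._table(geno), [0] * 5 + [1] * 5)
        assert summ.mean_pairwise_fst == pytest.approx(1.0)

    def test_equal_frequencies_small_negative(self):
        # p1 = p2 = 0.5 with 100 allele copies per deme:
        # num = -2 * 0.25/99, den = 0.5 -> per-locus value ~ -0.0101
        geno = ([[[0, 0]]] * 25 + [[[1, 1]]] * 25) * 2
        labels = [0] * 50 + [1] * 50
        summ = pk.hudson_fst(self._table(geno), labels)
        expect = (-2 * 0.25 / 99) / 0.5
        assert summ.per_locus_fst[0] == pytest.approx(expect, rel=1e-9)

    def test_matches_bruteforce_oracle(self, split2):
        """Vectorized estimator equals a direct per-locus loop to 1e-12."""
        table, labels, summary = split2
        num = den = 0.0
        for l in range(table.n_loci):
            ps, ns = [], []
            for d in (0, 1):
                sub = table.alleles[labels == d + 1, l, :].ravel()
                sub = sub[sub >= 0]
                ns.append(len(sub))
                ps.append(np.mean(sub == 1))
            (p1, p2), (n1, n2) = ps, ns
            num += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den += p1 * (1 - p2) + p2 * (1 - p1)
        assert summary.mean_pairwise_fst == pytest.approx(num / den, abs=1e-12)

    def test_single_deme_rejected(self):
        with pytest.raises(ValueError, match="2 demes"):
            pk.hudson_fst(self._table([[[0, 1]]]), [0])


class TestSimulateDataset:
    def test_panmixia_has_no_fst(self):
        table, summ = pk.simulate_dataset(
            pk.make_model("split", 1), pk.SimConfig(10, 20, seed=1)
        )
        assert len(set(table.population_labels)) == 1
        assert summ.mean_pairwise_fst is None
        assert summ.polymorphic_loci == 20

    def test_same_seed_bitwise_identical(self):
        cfg = pk.SimConfig(10, 15, seed=33)
        m = pk.make_model("m2.0", 2)
        t1, s1 = pk.simulate_dataset(m, cfg)
        t2, s2 = pk.simulate_dataset(m, cfg)
        assert np.array_equal(t1.alleles, t2.alleles)
        assert s1.mean_pairwise_fst == s2.mean_pairwise_fst

    def test_fst_monotone_in_migration(self):
        means = {}
        for name in ["split", "m0.5", "m2.0", "m10"]:
            m = pk.make_model(name, 2)
            vals = [
                pk.simulate_dataset(m, pk.SimConfig(25, 60, seed=400 + i))[1].mean_pairwise_fst
                for i in range(8)
            ]
            means[name] = np.mean(vals)
        assert means["split"] > means["m0.5"] > means["m2.0"] > means["m10"]

    def test_short_split_time_weakens_fst(self):
        """tau = 0.05 gives mean FST around 0.09, ~5-10x below tau = 0.5."""
        m = pk.make_model("split", 2, split_time=0.05)
        vals = [
            pk.simulate_dataset(m, pk.SimConfig(25, 60, seed=600 + i))[1].mean_pairwise_fst
            for i in range(10)
        ]
        assert 0.04 < np.mean(vals) < 0.16

    def test_tree_model_runs_and_differentiates(self):
        table, summ = pk.simulate_dataset(
            pk.make_model("tree", 3), pk.SimConfig(10, 40, seed=2)
        )
        assert summ.mean_pairwise_fst > 0.2
        # most recently split pair (demes 2,3) less diverged than pair (1,3)
        assert summ.pairwise_fst[(1, 2)] < summ.pairwise_fst[(0, 2)]
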