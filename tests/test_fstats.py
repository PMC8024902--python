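import numpy as np
import pandas as pd
import pytest

from isopop.containers import MISSING
from isopop.fstats import (BlockDefinition, PopulationFrequencies, f2, f3,
                           f3_nj_tree, f4, jackknife_mean,
                           outgroup_f3_matrix, pca_project,
                           population_frequencies, two_sided_p)
from isopop.graph import AdmixtureGraph
from isopop.simulate import (SimulationConfig, sample_diploid_genotypes,
                             simulate_graph_frequencies, synthetic_snp_table)

from conftest import make_genotypes


def pf_from_freqs(freq_dict, n_chrom=20):
    pops = list(freq_dict)
    freq = np.vstack([freq_dict[p] for p in pops])
    counts = np.full_like(freq, float(n_chrom))
    snps = None
    return PopulationFrequencies(pops, freq, counts, snps)


@pytest.fixture(scope="module")
def blocks20k():
    return BlockDefinition.equal_count(20_000, 25)


class TestPopulationFrequencies:
    def test_hand_computed_mixed_fixture(self, small_snps):
        # pop A: diploid het (0.5); pop B: pseudo-haploid alt (1.0);
        # pop C: one diploid 2 + one pseudo-haploid 0 -> 2/3
        calls = np.array([[1], [2], [2], [0]], dtype=np.int8)
        g = make_genotypes(calls, small_snps, ["A", "B", "C", "C"],
                           ploidy=["diploid", "pseudo_haploid", "diploid",
                                   "pseudo_haploid"])
        pf = population_frequencies(g)
        assert pf.freq[pf.index("A"), 0] == 0.5
        assert pf.freq[pf.index("B"), 0] == 1.0
        assert pf.freq[pf.index("C"), 0] == pytest.approx(2 / 3)
        assert pf.counts[pf.index("C"), 0] == 3

    def test_missing_data_gives_nan(self, small_snps):
        calls = np.array([[MISSING]], dtype=np.int8)
        g = make_genotypes(calls, small_snps, ["A"])
        pf = population_frequencies(g)
        assert np.isnan(pf.freq[0, 0])


class TestF4:
    def test_identical_arguments_zero(self, blocks20k, rng):
        p = rng.uniform(0.05, 0.95, 20_000)
        q = rng.uniform(0.05, 0.95, 20_000)
        r = rng.uniform(0.05, 0.95, 20_000)
        pf = pf_from_freqs({"W": p, "X": p, "Y": q, "Z": r})
        res = f4(pf, "W", "X", "Y", "Z", blocks20k)
        assert res.estimate == 0.0 and res.z == 0.0

    def test_antisymmetry_exact(self, blocks20k, rng):
        freqs = {k: rng.uniform(0.05, 0.95, 20_000) for k in "WXYZ"}
        pf = pf_from_freqs(freqs)
        a = f4(pf, "W", "X", "Y", "Z", blocks20k)
        b = f4(pf, "X", "W", "Y", "Z", blocks20k)
        assert a.estimate == -b.estimate
        assert a.se == b.se

    def test_linearity_identity(self, blocks20k, rng):
        freqs = {k: rng.uniform(0.05, 0.95, 20_000) for k in "ABCDE"}
        pf = pf_from_freqs(freqs)
        lhs = f4(pf, "A", "B", "C", "D", blocks20k).estimate
        rhs = f4(pf, "A", "B", "C", "E", blocks20k).estimate \
            + f4(pf, "A", "B", "E", "D", blocks20k).estimate
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_allele_flip_invariance(self, blocks20k, rng):
        freqs = {k: rng.uniform(0.05, 0.95, 20_000) for k in "WXYZ"}
        pf = pf_from_freqs(freqs)
        flipped = pf_from_freqs({k: 1.0 - v for k, v in freqs.items()})
        a = f4(pf, "W", "X", "Y", "Z", blocks20k)
        b = f4(flipped, "W", "X", "Y", "Z", blocks20k)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-15)

    def test_snp_order_invariance(self, rng):
        freqs = {k: rng.uniform(0.05, 0.95, 20_000) for k in "WXYZ"}
        pf = pf_from_freqs(freqs)
        blocks = BlockDefinition.equal_count(20_000, 25)
        a = f4(pf, "W", "X", "Y", "Z", blocks)
        perm = rng.permutation(20_000)
        pf2 = pf_from_freqs({k: v[perm] for k, v in freqs.items()})
        blocks2 = BlockDefinition(blocks.block_of_snp[perm])
        b = f4(pf2, "W", "X", "Y", "Z", blocks2)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-15)
        assert a.se == pytest.approx(b.se, rel=1e-9)

    def test_low_snp_flag(self, rng):
        freqs = {k: rng.uniform(0.05, 0.95, 1_000) for k in "WXYZ"}
        pf = pf_from_freqs(freqs)
        res = f4(pf, "W", "X", "Y", "Z",
                 BlockDefinition.equal_count(1_000, 10))
        assert res.low_snp_flag   # fewer than the 30K reliability floor


class TestJackknife:
    def test_se_matches_iid_closed_form(self, rng):
        # independent terms: the weighted block jackknife should agree
        # with the classic SE of the mean within 20%
        ratios = []
        for _ in range(50):
            terms = rng.normal(0.0, 1.0, 5_000)
            blocks = BlockDefinition.equal_count(5_000, 100)
            _, se, _, _ = jackknife_mean(terms, np.ones(5_000, bool),
                                         blocks)
            iid = terms.std(ddof=1) / np.sqrt(5_000)
            ratios.append(se / iid)
        ratios = np.array(ratios)
        # the jackknife SE is itself noisy (~1/sqrt(2m) relative), so the
        # 20% agreement is asserted on the ensemble
        assert abs(ratios.mean() - 1.0) < 0.1
        assert np.all(np.abs(ratios - 1.0) < 0.35)

    def test_two_sided_normal_tail_at_convention(self):
        assert two_sided_p(3.3) == pytest.approx(0.000967, abs=5e-6)


class TestF3:
    def test_self_comparison_nonnegative(self, blocks20k, rng):
        p = rng.uniform(0.05, 0.95, 20_000)
        pf = pf_from_freqs({"C": p})
        res = f3(pf, "C", "C", "C", blocks20k, bias_correction=False)
        assert res.estimate >= 0.0

    def test_admixed_population_negative(self, blocks20k):
        g = AdmixtureGraph(
            {("R", "A"): 0.08, ("R", "B"): 0.08, ("M", "C"): 0.002},
            {"M": ("A", "B", 0.5)})
        cfg = SimulationConfig(n_snps=20_000, seed=3)
        rng = np.random.default_rng(3)
        freqs = simulate_graph_frequencies(g, cfg, rng)
        geno = sample_diploid_genotypes(freqs, {"A": 30, "B": 30, "C": 30},
                                        rng)
        pf = population_frequencies(geno)
        res = f3(pf, "C", "A", "B", blocks20k)
        assert res.estimate < 0 and res.z < -3

    def test_outgroup_f3_monotone_in_shared_drift(self, blocks20k):
        # more shared drift with the outgroup-distal stem -> larger f3
        rng = np.random.default_rng(4)
        results = []
        for shared in (0.01, 0.05, 0.1):
            g = AdmixtureGraph({("R", "O"): 0.05, ("R", "S"): shared,
                                ("S", "A"): 0.02, ("S", "B"): 0.02})
            freqs = simulate_graph_frequencies(
                g, SimulationConfig(n_snps=20_000, seed=5), rng)
            geno = sample_diploid_genotypes(
                freqs, {"O": 20, "A": 20, "B": 20}, rng)
            pf = population_frequencies(geno)
            results.append(f3(pf, "O", "A", "B", blocks20k,
                              bias_correction=False).estimate)
        assert results[0] < results[1] < results[2]


@pytest.fixture(scope="module")
def matrix(world):
    pops = ["NNA", "SNA1a", "SNA1b", "SNA2a"]
    return outgroup_f3_matrix(world["pf"], pops, "OUT",
                              world["blocks"], min_snps=1_000)


class TestOutgroupF3Matrix:

    def test_symmetric(self, matrix):
        m = matrix["f3"].to_numpy()
        assert np.abs(m - m.T).max() < 1e-12

    def test_self_pair_then_sister_highest_in_row(self, matrix):
        row = matrix["f3"].loc["SNA1a"]
        # a population shares all its drift with itself...
        assert row.idxmax() == "SNA1a"
        # ...and, among others, the most with its sister branch
        assert row.drop("SNA1a").idxmax() == "SNA1b"

    def test_flags_match_recomputation(self, world, matrix):
        from isopop.fstats import f3 as f3_fn
        for a in matrix["f3"].index:
            for b in matrix["f3"].columns:
                r = f3_fn(world["pf"], "OUT", a, b, world["blocks"],
                          bias_correction=False)
                expect = r.n_snps < 1_000 or abs(r.z) <= 3.3
                assert matrix["flagged"].loc[a, b] == expect


class TestNjTree:
    def test_additive_distances_recover_topology(self):
        # caterpillar tree with distinct branch lengths is additive
        import skbio
        leaves = ["A", "B", "C", "D", "E"]
        tree = "((A:1,B:2):1,(C:3,D:4):2,E:5);"
        ref = skbio.TreeNode.read([tree])
        dm = ref.tip_tip_distances()
        f3_df = pd.DataFrame(
            1.0 / np.where(dm.data > 0, dm.data, 1.0),
            index=dm.ids, columns=dm.ids)
        np.fill_diagonal(f3_df.values, 1.0)
        newick = f3_nj_tree(f3_df, rooting_pop="E")
        out = skbio.TreeNode.read([newick])
        dm2 = out.tip_tip_distances(list(dm.ids))
        assert np.allclose(dm2.filter(dm.ids).data, dm.data, atol=1e-6)
        assert sorted(t.name for t in out.tips()) == sorted(leaves)

    def test_three_leaves(self):
        f3_df = pd.DataFrame(
            [[1.0, 0.5, 0.25], [0.5, 1.0, 0.2], [0.25, 0.2, 1.0]],
            index=list("ABC"), columns=list("ABC"))
        newick = f3_nj_tree(f3_df, rooting_pop="C")
        assert all(x in newick for x in "ABC")

    def test_nonpositive_entry_names_pair(self):
        f3_df = pd.DataFrame([[1.0, -0.1], [-0.1, 1.0]],
                             index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="A.*B"):
            f3_nj_tree(f3_df, rooting_pop="A")


@pytest.fixture(scope="module")
def structured():
    rng = np.random.default_rng(8)
    snps = synthetic_snp_table(5_000, rng)
    g = AdmixtureGraph({("R", "P1"): 0.08, ("R", "S"): 0.04,
                        ("S", "P2"): 0.08, ("S", "P3"): 0.08})
    freqs = simulate_graph_frequencies(
        g, SimulationConfig(n_snps=5_000, seed=8), rng)
    geno = sample_diploid_genotypes(
        freqs, {"P1": 20, "P2": 20, "P3": 20}, rng, snps=snps)
    return geno, rng


class TestPcaProject:

    def test_full_data_projection_matches_in_analysis(self, structured):
        geno, _ = structured
        coords = pca_project(geno, geno.take_individuals([0]),
                             n_components=4)
        modern = coords[~coords["projected"]].iloc[0]
        proj = coords[coords["projected"]].iloc[0]
        for k in range(1, 5):
            assert proj[f"PC{k}"] == pytest.approx(modern[f"PC{k}"],
                                                   abs=1e-8)

    def test_half_masked_sample_lands_near_full_coordinates(self,
                                                            structured):
        geno, rng = structured
        # one masked copy from each population so PC1-2 span structure
        pick = np.r_[0:5, 20:25, 40:45]
        masked = geno.take_individuals(pick)
        calls = masked.calls.copy()
        calls[rng.random(calls.shape) < 0.5] = MISSING
        masked.calls = calls
        coords = pca_project(geno, masked, n_components=2)
        full = coords[~coords["projected"]].iloc[pick]
        proj = coords[coords["projected"]]
        for k in (1, 2):
            corr = np.corrcoef(full[f"PC{k}"], proj[f"PC{k}"])[0, 1]
            assert corr > 0.9

    def test_all_missing_sample_errors(self, structured):
        geno, _ = structured
        empty = geno.take_individuals([0])
        empty.calls = np.full_like(empty.calls, MISSING)
        with pytest.raises(ValueError, match="no genotypes"):
            pca_project(geno, empty, n_components=2)
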