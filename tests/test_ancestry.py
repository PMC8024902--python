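import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isopop.ancestry import (f4_colonial_filter, local_ancestry_filter,
                             mask_genotypes, masked_retention_filter,
                             haplotypes_to_pseudo_haploid,
                             q_threshold_filter, stepwise_merge,
                             FilterDecision, STRICT_CAPS)
from isopop.containers import GenotypeMatrix, LocalAncestryCalls, QMatrix
from isopop.fstats import BlockDefinition
from isopop.pipeline import demo_graph
from isopop.simulate import (SimulationConfig, sample_diploid_genotypes,
                             simulate_admixed_tracts,
                             simulate_graph_frequencies,
                             synthetic_snp_table)


def make_q(values, components=("IA", "EUR", "AFR"), indigenous=("IA",)):
    inds = [f"i{k}" for k in range(len(values))]
    return QMatrix(inds, list(components), np.array(values),
                   frozenset(indigenous))


def make_la(viterbi, ia_posterior, ancestries=("IA", "EUR", "AFR")):
    """One-individual local-ancestry object from per-slot labels and the
    Indigenous posterior at each slot (rest spread evenly)."""
    viterbi = np.asarray(viterbi, dtype=np.int8)
    ia_post = np.asarray(ia_posterior, dtype=float)
    n_hap, n_snps = viterbi.shape
    post = np.empty((n_hap, n_snps, 3))
    post[:, :, 0] = ia_post
    post[:, :, 1] = post[:, :, 2] = (1.0 - ia_post) / 2.0
    inds = [f"i{k}" for k in range(n_hap // 2)]
    return LocalAncestryCalls(inds, tuple(ancestries), viterbi, post)


class TestQThreshold:
    @pytest.mark.parametrize("ia,passed", [
        (0.951, True),    # strictly above the 95% rule
        (0.95, False),    # boundary fails (strict inequality)
        (1.0, True),
    ])
    def test_threshold_boundaries(self, ia, passed):
        q = make_q([[ia, (1 - ia) * 0.6, (1 - ia) * 0.4]])
        dec = q_threshold_filter(q)
        assert dec[0].passed is passed
        assert dec[0].values["indigenous_fraction"] == pytest.approx(ia)


class TestLocalAncestryFilter:
    def test_default_rule_and_strict_caps(self):
        # 3% European tracts: passes the 5% rule, fails the strict 2% cap
        n = 1000
        viterbi = np.zeros((2, n), dtype=np.int8)
        viterbi[0, :60] = 1              # 3% of 2000 slots EUR
        la = make_la(viterbi, np.where(viterbi > 0, 0.1, 0.9))
        default = local_ancestry_filter(la)
        assert default[0].passed
        strict = local_ancestry_filter(la, per_ancestry_caps=STRICT_CAPS)
        assert not strict[0].passed

    def test_fully_indigenous_passes_all_variants(self):
        viterbi = np.zeros((2, 100), dtype=np.int8)
        la = make_la(viterbi, np.full((2, 100), 0.95))
        assert local_ancestry_filter(la)[0].passed
        assert local_ancestry_filter(
            la, per_ancestry_caps=STRICT_CAPS)[0].passed

    def test_fraction_equals_truth_tally(self, rng):
        snps = synthetic_snp_table(500, rng)
        panels = {a: np.full(500, 0.5) for a in ("IA", "EUR", "AFR")}
        sim = simulate_admixed_tracts(panels, (0.8, 0.15, 0.05), 0.1,
                                      snps, 10, rng)
        dec = local_ancestry_filter(sim.la_truth)
        for k, d in enumerate(dec):
            brute = (sim.la_truth.viterbi[2 * k:2 * k + 2] != 0).mean()
            assert d.values["non_ia_fraction"] == pytest.approx(brute)


class TestStepwiseMerge:
    def test_intersection_rule(self):
        q = [FilterDecision("a", "Q_threshold", True, {}),
             FilterDecision("b", "Q_threshold", True, {})]
        f = [FilterDecision("a", "f4_colonial", True, {}),
             FilterDecision("b", "f4_colonial", False, {})]
        la = [FilterDecision("a", "local_ancestry", True, {}),
              FilterDecision("b", "local_ancestry", True, {})]
        panel = stepwise_merge(q, f, la)
        assert panel["members"] == ["a"]
        audit = panel["audit"].set_index("ind_id")
        assert not audit.loc["b", "selected"]

    def test_counts_equal_set_intersection(self, rng):
        inds = [f"i{k}" for k in range(50)]
        outcome = {f: {i: bool(rng.random() < 0.7) for i in inds}
                   for f in ("Q_threshold", "f4_colonial",
                             "local_ancestry")}
        lists = [[FilterDecision(i, f, outcome[f][i], {}) for i in inds]
                 for f in outcome]
        panel = stepwise_merge(*lists)
        brute = set(inds)
        for f in outcome:
            brute &= {i for i in inds if outcome[f][i]}
        assert set(panel["members"]) == brute

    def test_undecided_counts_as_excluded(self):
        q = [FilterDecision("a", "Q_threshold", True, {})]
        f = [FilterDecision("a", "f4_colonial", None, {})]
        assert stepwise_merge(q, f)["members"] == []


class TestMasking:
    @pytest.mark.parametrize("label,ia_post,masked", [
        (1, 0.85, True),     # non-IA viterbi and low IA posterior
        (1, 0.95, False),    # posterior rescues the slot
        (0, 0.20, False),    # IA viterbi always retained (conjunction)
        (0, 0.95, False),
    ])
    def test_masking_truth_table(self, label, ia_post, masked):
        viterbi = np.full((2, 1), label, dtype=np.int8)
        la = make_la(viterbi, np.full((2, 1), ia_post))
        haps = np.ones((2, 1), dtype=np.int8)
        out = mask_genotypes(haps, la, posterior_min=0.9)
        assert bool(out["haplotypes"][0, 0] == -1) is masked

    def test_or_variant_masks_low_posterior_ia(self):
        viterbi = np.zeros((2, 1), dtype=np.int8)
        la = make_la(viterbi, np.full((2, 1), 0.2))
        haps = np.ones((2, 1), dtype=np.int8)
        assert mask_genotypes(haps, la, conjunction=False)[
            "haplotypes"][0, 0] == -1

    def test_misaligned_grids_error(self):
        la = make_la(np.zeros((2, 5), dtype=np.int8),
                     np.full((2, 5), 0.95))
        with pytest.raises(ValueError, match="grid"):
            mask_genotypes(np.ones((2, 4), dtype=np.int8), la)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(label=st.integers(0, 2),
           post=st.floats(0.0, 1.0 - 1e-9),
           conjunction=st.booleans())
    def test_rule_matches_specification(self, label, post, conjunction):
        viterbi = np.full((2, 1), label, dtype=np.int8)
        la = make_la(viterbi, np.full((2, 1), max(post, 1e-9)
                                      if label == 0 else post))
        haps = np.zeros((2, 1), dtype=np.int8)
        out = mask_genotypes(haps, la, posterior_min=0.9,
                             conjunction=conjunction)
        ia_post = la.posterior[0, 0, 0]
        non_ia = label != 0
        low = ia_post < 0.9
        expect = bool((non_ia and low) if conjunction else (non_ia or low))
        assert bool(out["haplotypes"][0, 0] == -1) is expect

    def test_noise_free_masking_removes_all_foreign_alleles(self, rng):
        snps = synthetic_snp_table(800, rng)
        panels = {"IA": np.full(800, 0.0), "EUR": np.full(800, 1.0),
                  "AFR": np.full(800, 1.0)}
        sim = simulate_admixed_tracts(panels, (0.7, 0.2, 0.1), 0.1, snps,
                                      10, rng)
        out = mask_genotypes(sim.haplotypes, sim.la_truth)
        kept = out["haplotypes"]
        # with IA fixed at 0 and the sources at 1, any surviving 1 is a
        # foreign allele
        assert not ((kept == 1)
                    & (sim.la_truth.viterbi != 0)).any()
        assert (kept[sim.la_truth.viterbi != 0] == -1).all()


class TestRetention:
    @pytest.mark.parametrize("m0,m1,kept", [
        (0.40, 0.55, True),    # mean 47.5% and both retain >= 25%
        (0.10, 0.80, False),   # second haplotype keeps only 20%
        (0.0, 0.0, True),
    ])
    def test_published_rules(self, m0, m1, kept):
        n = 1000
        haps = np.zeros((2, n), dtype=np.int8)
        haps[0, :int(m0 * n)] = -1
        haps[1, :int(m1 * n)] = -1
        out = masked_retention_filter(haps, ["i0"])
        assert (out["retained"] == ["i0"]) is kept


class TestPanelIdempotence:
    def test_filters_are_idempotent_on_selected_panel(self, rng):
        # re-running the screens on the already-selected panel keeps
        # everyone
        values = []
        for _ in range(30):
            ia = rng.uniform(0.85, 1.0)
            rest = 1 - ia
            values.append([ia, rest * 0.7, rest * 0.3])
        q = make_q(values)
        first = q_threshold_filter(q)
        selected = [d.ind_id for d in first if d.passed]
        idx = [q.individuals.index(i) for i in selected]
        q2 = QMatrix(selected, q.components, q.proportions[idx],
                     q.indigenous)
        second = q_threshold_filter(q2)
        assert all(d.passed for d in second)


@pytest.fixture(scope="module")
def colonial_world():
    graph = demo_graph(0.3)
    cfg = SimulationConfig(n_snps=100_000, seed=23)
    rng = np.random.default_rng(23)
    freqs = simulate_graph_frequencies(graph, cfg, rng)
    snps = synthetic_snp_table(100_000, rng)
    base = sample_diploid_genotypes(
        freqs, {"OUT": 15, "AFR": 20, "EUR": 20, "Isthmus": 15}, rng,
        snps=snps)
    tracts = simulate_admixed_tracts(
        {"IA": freqs["Isthmus"], "EUR": freqs["EUR"],
         "AFR": freqs["AFR"]}, (0.85, 0.10, 0.05), 0.12, snps, 3, rng,
        posterior_noise=0.02)
    return {"snps": snps, "base": base, "tracts": tracts,
            "blocks": BlockDefinition.from_positions(snps), "rng": rng,
            "freqs": freqs}


class TestF4ColonialFilter:
    def test_ten_percent_european_individual_fails(self, colonial_world):
        w = colonial_world
        g = GenotypeMatrix(
            np.vstack([w["base"].calls, w["tracts"].genotypes.calls]),
            w["snps"],
            pd.concat([w["base"].individuals,
                       w["tracts"].genotypes.individuals],
                      ignore_index=True))
        dec = f4_colonial_filter(
            g, list(w["tracts"].genotypes.individuals["ind_id"]),
            "Isthmus", "EUR", "AFR", "OUT", w["blocks"], min_snps=1_000)
        assert all(d.passed is False for d in dec)
        assert all(abs(d.values["z_europe"]) >= 3 for d in dec)

    def test_unadmixed_individual_passes(self, colonial_world):
        w = colonial_world
        rng = np.random.default_rng(99)
        extra = sample_diploid_genotypes(
            {"Extra": w["freqs"]["Isthmus"]}, {"Extra": 3}, rng,
            snps=w["snps"])
        g = GenotypeMatrix(
            np.vstack([w["base"].calls, extra.calls]), w["snps"],
            pd.concat([w["base"].individuals, extra.individuals],
                      ignore_index=True))
        dec = f4_colonial_filter(
            g, list(extra.individuals["ind_id"]), "Isthmus", "EUR",
            "AFR", "OUT", w["blocks"], min_snps=1_000)
        assert all(d.passed is True for d in dec)

    def test_sparse_candidate_is_undecided(self, colonial_world):
        w = colonial_world
        sparse = w["base"].take_individuals([0]).calls.copy()
        sparse[:, 500:] = -1
        g = GenotypeMatrix(
            np.vstack([w["base"].calls, sparse]), w["snps"],
            pd.concat([w["base"].individuals,
                       pd.DataFrame({"ind_id": ["sparse0"],
                                     "population": ["Solo"],
                                     "sex": ["unknown"],
                                     "era": ["modern"],
                                     "ploidy_mode": ["diploid"]})],
                      ignore_index=True))
        dec = f4_colonial_filter(g, ["sparse0"], "Isthmus", "EUR", "AFR",
                                 "OUT", w["blocks"], min_snps=1_000)
        assert dec[0].passed is None
        assert "reason" in dec[0].values

    def test_masked_haplotypes_pass(self, colonial_world):
        w = colonial_world
        masked = mask_genotypes(w["tracts"].haplotypes,
                                w["tracts"].la_emitted)
        mh = haplotypes_to_pseudo_haploid(
            masked["haplotypes"], w["snps"],
            list(w["tracts"].la_emitted.individuals))
        g = GenotypeMatrix(
            np.vstack([w["base"].calls, mh.calls]), w["snps"],
            pd.concat([w["base"].individuals, mh.individuals],
                      ignore_index=True))
        cand = {i: [f"{i}_h0", f"{i}_h1"]
                for i in w["tracts"].la_emitted.individuals}
        dec = f4_colonial_filter(g, cand, "Isthmus", "EUR", "AFR", "OUT",
                                 w["blocks"], min_snps=1_000)
        assert all(d.passed is True for d in dec)
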