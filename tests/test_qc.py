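import numpy as np
import pandas as pd
import pytest

from isopop.containers import MISSING, GenotypeMatrix, make_individual_table, \
    make_pileup
from isopop.qc import (damage_profile, downsample_pileup, error_rate_excess,
                       king_kinship, king_kinship_matrix, molecular_decay,
                       mtdna_contamination_fraction, pseudo_haploid_call,
                       read_kinship, reference_bias_check, sex_determination,
                       y_haplogroup_classify)
from isopop.simulate import (DEFAULT_CHROM_LENGTHS, SimulationConfig,
                             sample_ancient_pileup, simulate_pedigree_pair,
                             simulate_sex_reads, simulate_y_markers,
                             synthetic_snp_table)

from conftest import make_genotypes


def pileup_rows(snp_ids, bases, ind="a", baseq=35, mapq=37):
    return make_pileup(pd.DataFrame({
        "ind_id": ind, "snp_id": snp_ids, "base": bases,
        "baseq": baseq, "mapq": mapq, "pos_in_read": 10, "read_len": 50,
        "strand": "+"}))


class TestPseudoHaploidCall:
    def test_single_alt_read_forces_call(self, small_snps):
        snps = small_snps.iloc[:3].reset_index(drop=True)
        p = pileup_rows([snps["snp_id"][0]], [snps["allele_alt"][0]])
        g = pseudo_haploid_call(p, snps)
        assert g.calls[0, 0] == 2
        assert g.calls[0, 1] == MISSING   # uncovered site is missing

    def test_low_quality_and_mismatch_reads_discarded(self, small_snps):
        snps = small_snps.iloc[:1].reset_index(drop=True)
        bad_base = next(b for b in "ACGT"
                        if b not in (snps["allele_ref"][0],
                                     snps["allele_alt"][0]))
        p = pd.concat([
            pileup_rows(snps["snp_id"], [snps["allele_alt"][0]], baseq=5),
            pileup_rows(snps["snp_id"], [bad_base]),
        ], ignore_index=True)
        g = pseudo_haploid_call(p, snps)
        assert g.calls[0, 0] == MISSING

    def test_high_coverage_concordance_with_majority_vote(self, rng):
        snps = synthetic_snp_table(2_000, rng)
        geno = rng.integers(0, 2, 2_000) * 2
        cfg = SimulationConfig(n_snps=2_000, coverage_mean=30.0,
                               damage_rate_5p=0.0, seed=1)
        pile = sample_ancient_pileup(geno, snps, cfg, rng, ind_id="a")
        g = pseudo_haploid_call(pile, snps, seed=2)
        called = g.calls[0] != MISSING
        # a single random read agrees with the 30X majority except at
        # sites hit by rare stray draws
        assert called.mean() > 0.99
        assert (g.calls[0][called] == geno[called]).mean() > 0.999
        assert set(np.unique(g.calls)) <= {0, 2, MISSING}


class TestDownsample:
    def test_target_above_current_is_identity(self, rng, small_snps):
        p = pileup_rows(small_snps["snp_id"][:50], ["A"] * 50)
        out = downsample_pileup(p, 10.0, n_snps=200, rng=rng)
        assert len(out) == len(p)

    def test_binomial_thinning(self, rng):
        snps = synthetic_snp_table(20_000, rng)
        cfg = SimulationConfig(n_snps=20_000, coverage_mean=2.0, seed=3)
        pile = sample_ancient_pileup(np.zeros(20_000, dtype=int), snps,
                                     cfg, rng)
        out = downsample_pileup(pile, 0.5, n_snps=20_000, rng=rng)
        assert len(out) / 20_000 == pytest.approx(0.5, abs=0.02)

    def test_seed_determinism(self, rng):
        snps = synthetic_snp_table(1_000, rng)
        cfg = SimulationConfig(n_snps=1_000, coverage_mean=2.0, seed=4)
        pile = sample_ancient_pileup(np.zeros(1_000, dtype=int), snps,
                                     cfg, rng)
        a = downsample_pileup(pile, 0.5, 1_000, seed=9)
        b = downsample_pileup(pile, 0.5, 1_000, seed=9)
        assert a.equals(b)


class TestDamageAndDecay:
    def test_damage_rate_recovery(self, rng):
        # decay off -> every offset carries the terminal rate, so all
        # positions pool into a tight estimate
        snps = synthetic_snp_table(10_000, rng)
        cfg = SimulationConfig(n_snps=10_000, coverage_mean=5.0,
                               damage_rate_5p=0.3, damage_decay=1.0,
                               seed=5)
        pile = sample_ancient_pileup(np.zeros(10_000, dtype=int), snps,
                                     cfg, rng)
        prof = damage_profile(pile, snps)
        pooled_ct = prof["ct_rate"].mul(prof["ct_n"]).sum() \
            / prof["ct_n"].sum()
        pooled_ga = prof["ga_rate"].mul(prof["ga_n"]).sum() \
            / prof["ga_n"].sum()
        assert pooled_ct == pytest.approx(0.3, abs=0.02)
        assert pooled_ga == pytest.approx(0.3, abs=0.02)
        rates = prof[["ct_rate", "ga_rate"]].to_numpy()
        assert np.nanmin(rates) >= 0 and np.nanmax(rates) <= 1

    def test_damage_decays_inward(self, rng):
        snps = synthetic_snp_table(20_000, rng)
        cfg = SimulationConfig(n_snps=20_000, coverage_mean=3.0,
                               damage_rate_5p=0.4, damage_decay=0.5,
                               seed=15)
        pile = sample_ancient_pileup(np.zeros(20_000, dtype=int), snps,
                                     cfg, rng)
        prof = damage_profile(pile, snps)
        assert prof["ct_rate"].iloc[0] == pytest.approx(0.4, abs=0.06)
        assert prof["ct_rate"].iloc[3] < prof["ct_rate"].iloc[0] / 3

    def test_zero_damage_profile_flat(self, rng):
        snps = synthetic_snp_table(5_000, rng)
        cfg = SimulationConfig(n_snps=5_000, coverage_mean=2.0,
                               damage_rate_5p=0.0, seed=6)
        pile = sample_ancient_pileup(np.zeros(5_000, dtype=int), snps,
                                     cfg, rng)
        prof = damage_profile(pile, snps)
        assert np.nanmax(prof["ct_rate"]) < 0.02

    def test_decay_mle_recovery(self, rng):
        lengths = 30 + rng.geometric(0.02, size=10_000) - 1
        fit = molecular_decay(lengths)
        assert fit["lambda"] == pytest.approx(0.02, abs=0.002)

    def test_constant_lengths_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            fit = molecular_decay([42] * 100)
        assert fit["lambda"] == 0.0
        assert "degenerate" in caplog.text

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            molecular_decay([])


class TestErrorRateExcess:
    def test_identical_genomes_zero(self, rng):
        row = rng.integers(0, 3, 500).astype(np.int8)
        outg = (rng.integers(0, 2, 500) * 2).astype(np.int8)
        assert error_rate_excess(row, row, outg) == 0.0

    def test_flips_toward_derived_recovered(self, rng):
        n = 50_000
        outg = np.zeros(n, dtype=np.int8)       # ancestral = ref
        clean = np.zeros(n, dtype=np.int8)      # fully ancestral genome
        target = clean.copy()
        flip = rng.random(n) < 0.01
        target[flip] = 2                        # 1% flips to derived
        excess = error_rate_excess(target, clean, outg)
        assert excess == pytest.approx(0.01, rel=0.1)

    def test_no_overlap_error(self):
        a = np.array([MISSING, 0], dtype=np.int8)
        b = np.array([0, MISSING], dtype=np.int8)
        o = np.array([0, 0], dtype=np.int8)
        with pytest.raises(ValueError, match="overlap"):
            error_rate_excess(a, b, o)


class TestSexDetermination:
    def test_simulated_xy_called_male(self, rng):
        counts = simulate_sex_reads("XY", 100_000, rng)
        call = sex_determination(counts, DEFAULT_CHROM_LENGTHS, "a")
        assert call.call == "male"
        assert call.ry_ci[0] > 0.075

    def test_xx_without_mismap_is_female_with_ry_zero(self, rng):
        counts = simulate_sex_reads("XX", 100_000, rng, y_mismap=0.0)
        call = sex_determination(counts, DEFAULT_CHROM_LENGTHS, "a")
        assert call.call == "female" and call.ry == 0.0

    def test_too_few_sex_reads_insufficient(self):
        counts = pd.Series({**{str(c): 1000 for c in range(1, 21)},
                            "X": 30, "Y": 20})
        call = sex_determination(counts, DEFAULT_CHROM_LENGTHS, "a")
        assert call.call == "insufficient"


class TestMtdnaContamination:
    def test_all_consensus_zero(self):
        p = pileup_rows(["d1", "d2"], ["A", "C"])
        res = mtdna_contamination_fraction({"d1": "A", "d2": "C"}, p)
        assert res["fraction"] == 0.0

    def test_contaminant_fraction_recovered(self, rng):
        n = 4_000
        mismatch = rng.random(n) < 0.05
        bases = np.where(mismatch, "G", "A")
        p = pileup_rows([f"d{i}" for i in range(n)], bases)
        res = mtdna_contamination_fraction(
            {f"d{i}": "A" for i in range(n)}, p)
        assert res["fraction"] == pytest.approx(0.05, abs=0.01)
        assert res["ci"][0] < 0.05 < res["ci"][1]

    def test_no_coverage_error(self):
        p = pileup_rows(["x"], ["A"])
        with pytest.raises(ValueError, match="diagnostic"):
            mtdna_contamination_fraction({"d1": "A"}, p)


class TestReferenceBias:
    def test_matched_simulators_show_no_difference(self, rng):
        snps = synthetic_snp_table(3_000, rng)
        p = rng.uniform(0.1, 0.9, 3_000)
        calls = 2 * rng.binomial(1, p, size=(40, 3_000))
        era = ["modern"] * 20 + ["ancient"] * 20
        g = make_genotypes(calls, snps, ["P"] * 40, era=era,
                           ploidy=["pseudo_haploid"] * 40)
        res = reference_bias_check(g)
        assert res["tests"]["all"]["p_value"] > 0.01

    def test_alt_dropping_detected(self, rng):
        snps = synthetic_snp_table(3_000, rng)
        p = rng.uniform(0.1, 0.9, 3_000)
        modern = 2 * rng.binomial(1, p, size=(20, 3_000))
        biased = 2 * rng.binomial(1, p, size=(20, 3_000))
        drop = (biased == 2) & (rng.random(biased.shape) < 0.2)
        biased[drop] = 0    # alt reads lost with probability 0.2
        g = make_genotypes(np.vstack([modern, biased]), snps, ["P"] * 40,
                           era=["modern"] * 20 + ["ancient"] * 20,
                           ploidy=["pseudo_haploid"] * 40)
        res = reference_bias_check(g)
        assert res["tests"]["all"]["p_value"] < 1e-6


def _pseudo_haploid(geno, rng):
    allele = np.where(geno == 1, rng.integers(0, 2, geno.size), geno // 2)
    return (2 * allele).astype(np.int8)


class TestReadKinship:
    def build_panel(self, rng, pair_specs, n_snps=10_000):
        freqs = rng.uniform(0.2, 0.8, n_snps)
        snps = synthetic_snp_table(n_snps, rng)
        rows, ids, pairs, truth = [], [], [], []
        for k, rel in enumerate(pair_specs):
            g1, g2 = simulate_pedigree_pair(rel, freqs, rng)
            a, b = f"i{2 * k}", f"i{2 * k + 1}"
            rows += [_pseudo_haploid(g1, rng), _pseudo_haploid(g2, rng)]
            ids += [a, b]
            pairs.append((a, b))
            truth.append(rel)
        g = GenotypeMatrix(
            np.array(rows), snps,
            make_individual_table(ids, ["P"] * len(ids),
                                  era=["ancient"] * len(ids)))
        return g, pairs, truth

    def test_identical_pair_detected_among_unrelated(self, rng):
        g, pairs, truth = self.build_panel(
            rng, ["identical"] + ["unrelated"] * 10)
        res = {r.pair: r.classification for r in read_kinship(g,
                                                              pairs=pairs)}
        assert res[pairs[0]] == "identical"
        assert all(res[p] == "unrelated" for p in pairs[1:])

    def test_all_unrelated_scores_near_one(self, rng):
        g, pairs, _ = self.build_panel(rng, ["unrelated"] * 12,
                                       n_snps=5_000)
        res = read_kinship(g, pairs=pairs)
        scores = np.array([r.value for r in res])
        assert np.abs(scores - 1.0).max() < 0.08
        assert all(r.classification == "unrelated" for r in res)

    def test_single_pair_degenerate_normalization(self, rng, caplog):
        g, pairs, _ = self.build_panel(rng, ["unrelated"], n_snps=2_000)
        with caplog.at_level("WARNING"):
            res = read_kinship(g, pairs=pairs)
        assert res[0].statistic == "READ_P0_raw"
        assert res[0].classification == "no_call"
        assert "degenerate" in caplog.text


class TestKingKinship:
    def test_parent_offspring_quarter(self, rng):
        freqs = rng.uniform(0.2, 0.8, 20_000)
        g1, g2 = simulate_pedigree_pair("first_degree", freqs, rng)
        snps = synthetic_snp_table(20_000, rng)
        g = make_genotypes(np.vstack([g1, g2]), snps, ["P", "P"])
        phi = king_kinship_matrix(g, np.array([0, 1]))
        assert phi[0, 1] == pytest.approx(0.25, abs=0.02)

    def test_self_pair_half(self, rng):
        freqs = rng.uniform(0.2, 0.8, 5_000)
        g1, _ = simulate_pedigree_pair("unrelated", freqs, rng)
        snps = synthetic_snp_table(5_000, rng)
        g = make_genotypes(np.vstack([g1, g1]), snps, ["P", "P"])
        phi = king_kinship_matrix(g, np.array([0, 1]))
        assert phi[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_percentile_rule_flags_at_most_2_5_percent(self, rng):
        freqs = rng.uniform(0.2, 0.8, 3_000)
        calls = np.vstack([rng.binomial(1, freqs, 3_000)
                           + rng.binomial(1, freqs, 3_000)
                           for _ in range(16)])
        snps = synthetic_snp_table(3_000, rng)
        g = make_genotypes(calls, snps, ["P"] * 16)
        out = king_kinship(g)
        results = [r for r in out["results"] if r.classification]
        n_flagged = sum(r.classification == "flagged" for r in results)
        assert n_flagged / len(results) <= 0.025 + 1e-9


Y_PANEL = pd.DataFrame([
    # marker, branch, parent, ancestral, derived
    ("M42", "A0", "ROOT", "A", "C"),
    ("M91", "Q", "A0", "G", "T"),
    ("M3", "Q1b1a1a", "Q", "C", "T"),       # transition: damage-ambiguous
    ("Z780", "Q1b1a1a1", "Q1b1a1a", "A", "C"),
    ("M45", "R", "A0", "A", "G"),           # sibling branch of Q
], columns=["marker", "branch", "parent", "ancestral", "derived"])


class TestYHaplogroup:
    def test_exact_recovery_without_damage(self, rng):
        calls = simulate_y_markers(["A0", "Q", "Q1b1a1a", "Q1b1a1a1"],
                                   Y_PANEL, 0.0, rng)
        res = y_haplogroup_classify(calls, Y_PANEL)
        assert res.haplogroup == "Q1b1a1a1"
        assert not res.conflicts

    def test_transition_only_support_is_tentative(self, rng):
        calls = pd.DataFrame({"marker": ["M42", "M91", "M3"],
                              "allele": ["C", "T", "T"]})
        res = y_haplogroup_classify(calls, Y_PANEL)
        # M3 (C/T) could be deamination: assignment stops at Q, with the
        # deeper node reported tentatively
        assert res.haplogroup == "Q"
        assert res.tentative == "Q1b1a1a"

    def test_conflicting_calls_back_off_to_consistent_ancestor(self):
        calls = pd.DataFrame({
            "marker": ["M42", "M91", "Z780"],
            "allele": ["C", "G", "C"]})   # Z780 derived but M91 ancestral
        res = y_haplogroup_classify(calls, Y_PANEL)
        assert res.haplogroup == "A0"
        assert res.conflicts and \
            res.conflicts[0]["ancestral_on_path"] == ["Q"]

    def test_no_informative_markers_no_call(self):
        res = y_haplogroup_classify(
            pd.DataFrame(columns=["marker", "allele"]), Y_PANEL)
        assert res.haplogroup is None

    def test_damage_only_flips_transition_markers(self, rng):
        calls = simulate_y_markers(["A0", "Q"], Y_PANEL, 1.0, rng)
        merged = calls.merge(Y_PANEL, on="marker")
        for r in merged.itertuples(index=False):
            expected = r.derived if r.branch in ("A0", "Q") else r.ancestral
            if frozenset((r.ancestral, r.derived)) in (frozenset("CT"),
                                                       frozenset("GA")):
                assert r.allele != expected    # flipped by damage
            else:
                assert r.allele == expected
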