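"""One-command orchestration of the full synthetic analysis.

``run_pipeline`` simulates a desk-scale study emulating the
Isthmo-Colombian design — an admixture-graph world with an
UPopI-style admixed Isthmian lineage, colonial three-way admixed
moderns, low-coverage damaged ancients — then runs QC, panel
construction, masking, f-statistics, qpWave, graph fitting and IBD
summaries, writing stage outputs, a manifest and a summary report to a
run directory.  Reruns with the same configuration are deterministic.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import (FilterDecision, f4_colonial_filter,
                       local_ancestry_filter,
                       mask_genotypes, masked_retention_filter,
                       haplotypes_to_pseudo_haploid, q_threshold_filter,
                       stepwise_merge)
from .containers import GenotypeMatrix, QMatrix
from .fstats import (BlockDefinition, f4, f3_nj_tree, outgroup_f3_matrix,
                     population_frequencies)
from .graph import AdmixtureGraph
from .graphfit import AdmixtureGraphModel
from .ibd import (CopyingMatrix, cluster_reduction, ibd_bin_summary,
                  ibd_dating_bins, self_copy_summary)
from .io_formats import (filter_geno_mind, merge_on_shared_snps,
                         min_snp_filter, write_eigenstrat)
from .qc import (damage_profile, molecular_decay, pseudo_haploid_call,
                 read_kinship, sex_determination)
from .qpwave import QpWave
from .simulate import (DEFAULT_CHROM_LENGTHS, SimulationConfig,
                       sample_ancient_pileup, sample_diploid_genotypes,
                       simulate_admixed_tracts, simulate_graph_frequencies,
                       simulate_ibd_segments, simulate_sex_reads,
                       synthetic_snp_table)

logger = logging.getLogger(__name__)


def demo_graph(alpha: float = 0.30) -> AdmixtureGraph:
    """Desk-scale analogue of the study's final model: an outgroup,
    African/European colonial sources, a northern branch, two southern
    streams, and an Isthmian lineage admixed between the two streams'
    source nodes.  Each source node carries two sampled descendant
    leaves (mirroring the paired SNA1 and SNA2 ancient genomes), which
    pins the drift up to the source and makes the admixture proportion
    identifiable from f2 statistics."""
    return AdmixtureGraph(
        drift_edges={
            ("Root", "OUT"): 0.08,
            ("Root", "H1"): 0.02,
            ("H1", "AFR"): 0.12,
            ("H1", "H2"): 0.03,
            ("H2", "EUR"): 0.10,
            ("H2", "AMR"): 0.06,
            ("AMR", "NNA"): 0.03,
            ("AMR", "SNAanc"): 0.02,
            ("SNAanc", "SNA1pre"): 0.015,
            ("SNA1pre", "SNA1a"): 0.02,
            ("SNA1pre", "SNA1b"): 0.025,
            ("SNAanc", "SNA2pre"): 0.01,
            ("SNA2pre", "SNA2a"): 0.02,
            ("SNA2pre", "SNA2b"): 0.03,
            ("UPopI", "Isthmus"): 0.02,
        },
        admixtures={"UPopI": ("SNA2pre", "SNA1pre", alpha)},
    )


#: leaves used when fitting the demo graph to simulated genotypes — the
#: minimal set that keeps the admixture proportion identifiable (each
#: source node retains two sampled descendants) while keeping the
#: residual f4 battery small enough for the worst-|Z| acceptance rule
DEMO_FIT_LEAVES = ("OUT", "SNA1a", "SNA1b", "SNA2a", "SNA2b", "Isthmus")

#: populations sampled in the demo world (statistics also use NNA)
DEMO_SAMPLED_POPS = DEMO_FIT_LEAVES + ("NNA",)


@dataclass
class RunConfig:
    """Thresholds default to the published values; simulation scale is a
    desk-scale stand-in for the array-based study design."""

    seed: int = 0
    n_snps: int = 20_000
    n_blocks: int = 20
    upopi_alpha: float = 0.30
    n_modern_per_pop: int = 15
    n_admixed: int = 25
    n_ancient: int = 3
    ancient_coverage: float = 1.0
    damage_rate_5p: float = 0.2
    colonial_proportions: tuple = (0.85, 0.10, 0.05)
    tract_switch_rate_per_cM: float = 0.12
    geno_max_missing: float = 0.60
    mind_max_missing: float = 0.98
    ancient_min_snps: int = 5_000
    q_min_total: float = 0.95
    la_max_non_ia: float = 0.05
    f4_z_max: float = 3.0
    f4_min_snps: int = 1_000
    posterior_min: float = 0.9
    ibd_pair_rate: float = 3.0
    ibd_mean_length_cM: float = 5.0
    genotype_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, path in self.genotype_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"configured input {key} not found: {path}")
        if self.n_snps < self.n_blocks * 10:
            raise ValueError("n_snps too small for the block count")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; halts on the first failing
    stage, preserving completed outputs."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(10)
    rngs = [np.random.default_rng(s) for s in seeds]
    summary: dict = {"seed": config.seed}
    stage = "init"
    try:
        # ---- simulate ---------------------------------------------------
        stage = "simulate"
        graph = demo_graph(config.upopi_alpha)
        sim_cfg = SimulationConfig(
            n_snps=config.n_snps, seed=config.seed,
            coverage_mean=config.ancient_coverage,
            damage_rate_5p=config.damage_rate_5p)
        freqs = simulate_graph_frequencies(graph, sim_cfg, rngs[0])
        snps = synthetic_snp_table(config.n_snps, rngs[0])
        sizes = {pop: config.n_modern_per_pop
                 for pop in ("OUT", "AFR", "EUR", "NNA", "SNA1a", "SNA1b",
                             "SNA2a", "SNA2b")}
        sizes["Isthmus"] = 2 * config.n_modern_per_pop
        modern = sample_diploid_genotypes(freqs, sizes, rngs[1], snps=snps)
        tracts = simulate_admixed_tracts(
            {"IA": freqs["Isthmus"], "EUR": freqs["EUR"],
             "AFR": freqs["AFR"]},
            config.colonial_proportions, config.tract_switch_rate_per_cM,
            snps, config.n_admixed, rngs[2], posterior_noise=0.02)
        ancient_geno = rngs[3].binomial(
            2, np.tile(freqs["Isthmus"], (config.n_ancient, 1)))
        pileups = [sample_ancient_pileup(
            ancient_geno[i], snps, sim_cfg, rngs[3],
            ind_id=f"AncientIA_{i}") for i in range(config.n_ancient)]
        pileup = pd.concat(pileups, ignore_index=True)
        karyotypes = ["XY" if i % 2 == 0 else "XX"
                      for i in range(config.n_ancient)]
        sex_reads = {f"AncientIA_{i}": simulate_sex_reads(
            karyotypes[i], 100_000, rngs[4])
            for i in range(config.n_ancient)}
        isthmian = {"Isthmus": [f"Isthmus_{i}"
                                for i in range(sizes["Isthmus"])],
                    "SNA1a": [f"SNA1a_{i}"
                              for i in range(config.n_modern_per_pop)]}
        ibd = simulate_ibd_segments(isthmian, config.ibd_pair_rate,
                                    config.ibd_mean_length_cM, rngs[5])
        summary["simulate"] = {"n_snps": config.n_snps,
                               "n_modern": modern.n_individuals,
                               "n_admixed": config.n_admixed,
                               "n_ancient": config.n_ancient}

        # ---- sample QC --------------------------------------------------
        stage = "sample_qc"
        sex_calls = [sex_determination(sex_reads[ind], DEFAULT_CHROM_LENGTHS,
                                       ind_id=ind) for ind in sex_reads]
        _write(pd.DataFrame([{"ind_id": s.ind_id, "Ry": s.ry, "Rx": s.rx,
                              "call": s.call} for s in sex_calls]),
               out / "sex_calls.tsv")
        dmg = damage_profile(pileup[pileup["ind_id"] == "AncientIA_0"], snps)
        _write(dmg, out / "damage_profile.tsv")
        decay = molecular_decay(
            pileup.loc[pileup["ind_id"] == "AncientIA_0", "read_len"])
        ancients = pseudo_haploid_call(pileup, snps, seed=config.seed)
        kin = read_kinship(ancients)
        _write(pd.DataFrame([{"pair": "|".join(k.pair), "score": k.value,
                              "class": k.classification} for k in kin]),
               out / "read_kinship.tsv")
        summary["sample_qc"] = {
            "sex_calls": {s.ind_id: s.call for s in sex_calls},
            "karyotypes_true": dict(zip(sex_reads, karyotypes)),
            "damage_ct_position1": float(dmg["ct_rate"].iloc[0]),
            "read_length_lambda": decay["lambda"],
        }

        # ---- merge and missingness filters ------------------------------
        stage = "merge_filter"
        merged, report = merge_on_shared_snps(modern, ancients,
                                              return_report=True)
        merged = filter_geno_mind(merged, config.geno_max_missing,
                                  config.mind_max_missing)
        merged = min_snp_filter(merged, config.ancient_min_snps)
        write_eigenstrat(merged, out / "merged.geno", out / "merged.snp",
                         out / "merged.ind")
        summary["merge_filter"] = {
            **report,
            "n_individuals_retained": merged.n_individuals,
            "n_ancient_retained": int(
                (merged.individuals["era"] == "ancient").sum())}

        # ---- nearly unadmixed panel -------------------------------------
        stage = "panel"
        blocks = BlockDefinition.from_positions(snps)
        candidates = list(tracts.genotypes.individuals["ind_id"]) \
            + isthmian["Isthmus"]
        # Q matrix: tract truth for admixed, pure Indigenous for panel pops
        n_pure = len(isthmian["Isthmus"])
        q_all = QMatrix(
            list(tracts.q_truth.individuals) + isthmian["Isthmus"],
            list(tracts.q_truth.components),
            np.vstack([tracts.q_truth.proportions,
                       np.tile([1.0, 0.0, 0.0], (n_pure, 1))]),
            frozenset({"IA"}))
        q_dec = q_threshold_filter(q_all, config.q_min_total)
        candidate_matrix = GenotypeMatrix(
            np.vstack([tracts.genotypes.calls, modern.calls,
                       ancients.calls]),
            snps,
            pd.concat([tracts.genotypes.individuals, modern.individuals,
                       ancients.individuals], ignore_index=True))
        f4_dec = f4_colonial_filter(
            candidate_matrix, candidates, "ancient", "EUR", "AFR", "OUT",
            blocks, z_max=config.f4_z_max, min_snps=config.f4_min_snps)
        la_dec = local_ancestry_filter(tracts.la_emitted,
                                       config.la_max_non_ia)
        la_dec += [  # unadmixed panel members carry no non-IA tracts
            FilterDecision(ind, "local_ancestry", True,
                           {"non_ia_fraction": 0.0})
            for ind in isthmian["Isthmus"]]
        panel = stepwise_merge(q_dec, f4_dec, la_dec)
        _write(panel["audit"], out / "panel_audit.tsv")
        summary["panel"] = {"n_candidates": len(candidates),
                            "n_selected": len(panel["members"])}

        # ---- masking ----------------------------------------------------
        stage = "masking"
        masked = mask_genotypes(tracts.haplotypes, tracts.la_emitted,
                                config.posterior_min)
        retention = masked_retention_filter(
            masked["haplotypes"], list(tracts.la_emitted.individuals))
        _write(retention["table"], out / "masked_retention.tsv")
        masked_panel = haplotypes_to_pseudo_haploid(
            masked["haplotypes"], snps,
            list(tracts.la_emitted.individuals))
        summary["masking"] = {
            "mean_masked_fraction": float(masked["masked_fraction"].mean()),
            "n_retained": len(retention["retained"])}

        # ---- population statistics --------------------------------------
        stage = "popstats"
        pf = population_frequencies(merged)
        blocks = BlockDefinition.from_positions(merged.snps)
        stat_pops = ["NNA", "SNA1a", "SNA2a", "Isthmus", "ancient"]
        og = outgroup_f3_matrix(pf, stat_pops, "OUT", blocks,
                                min_snps=config.f4_min_snps, z_min=3.3)
        og["f3"].to_csv(out / "outgroup_f3.tsv", sep="\t",
                        float_format="%.6g")
        newick = f3_nj_tree(og["f3"], rooting_pop="NNA")
        (out / "f3_tree.nwk").write_text(newick + "\n")
        f4_res = f4(pf, "SNA1a", "SNA2a", "Isthmus", "OUT", blocks)
        qpw = QpWave(pf, ["Isthmus", "SNA2a"],
                     ["OUT", "AFR", "EUR", "NNA", "SNA1a", "SNA1b"],
                     blocks).fit()
        summary["popstats"] = {
            "f4_SNA1_SNA2_Isthmus_OUT": {"estimate": f4_res.estimate,
                                         "z": f4_res.z},
            "qpwave_rank0_p": qpw.p_value(0),
            "qpwave_min_streams": qpw.minimum_streams(),
        }
        (out / "qpwave.txt").write_text(str(qpw) + "\n")

        # ---- admixture graph fit ----------------------------------------
        stage = "graph_fit"
        sub = graph_restricted_to(graph, DEMO_FIT_LEAVES)
        model = AdmixtureGraphModel(sub, pf, blocks)
        fit = model.fit(n_starts=6, seed=config.seed)
        (out / "graph_fit.txt").write_text(fit.summary() + "\n")
        summary["graph_fit"] = {
            "alpha_true": config.upopi_alpha,
            "alpha_hat": fit.admixture_proportions.get("UPopI"),
            "worst_abs_z": fit.worst_abs_z,
            "converged": fit.converged}

        # ---- IBD and painting summaries ---------------------------------
        stage = "ibd"
        bins = ibd_bin_summary(ibd, isthmian)
        _write(bins, out / "ibd_bins.tsv")
        dating = ibd_dating_bins(ibd, isthmian)
        _write(dating, out / "ibd_dating.tsv")
        copying = copying_matrix_from_ibd(ibd, isthmian)
        clusters = dict(copying.clusters)
        reduced = cluster_reduction(clusters, copying, min_size=5,
                                    tvd_max=0.03)
        selfcopy = self_copy_summary(copying, reduced["clusters"])
        _write(selfcopy, out / "self_copy.tsv")
        summary["ibd"] = {"n_segments": len(ibd),
                          "n_clusters_reduced": reduced["n_clusters"]}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "isopop_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "thresholds_provenance": {
            "geno_mind": "published (0.60 / 0.98)",
            "ancient_min_snps": "published rule (10,000 on a 545K-SNP "
                                "panel), rescaled to the synthetic panel",
            "q_min_total": "published (95%)",
            "la_max_non_ia": "published (5%)",
            "posterior_min": "published (0.9)",
            "f4_z_max": "published (|Z| < 3)",
            "block_size": "convention (5 Mb)",
        },
        "stages": ["simulate", "sample_qc", "merge_filter", "panel",
                   "masking", "popstats", "graph_fit", "ibd"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float))
    return summary


def graph_restricted_to(graph: AdmixtureGraph, leaves) -> AdmixtureGraph:
    """Prune a graph to the subgraph feeding the given leaves, contracting
    pass-through nodes (their edge lengths add)."""
    import networkx as nx

    g = graph.to_networkx()
    keep = set(leaves)
    needed = set(keep)
    for leaf in keep:
        needed |= nx.ancestors(g, leaf)
    drift = {e: l for e, l in graph.drift_edges.items()
             if e[0] in needed and e[1] in needed}
    admix = {c: v for c, v in graph.admixtures.items() if c in needed}
    # contract chains: node with one drift child, one drift parent, no admix
    while True:
        children, parents = {}, {}
        for (p, c) in drift:
            children.setdefault(p, []).append(c)
            parents.setdefault(c, []).append(p)
        admix_parents = {p for v in admix.values() for p in v[:2]}
        node = next(
            (n for n in children
             if n not in keep and n not in admix and n not in admix_parents
             and n in parents and len(children[n]) == 1
             and len(parents[n]) == 1), None)
        if node is None:
            break
        p, c = parents[node][0], children[node][0]
        drift[(p, c)] = drift.pop((p, node)) + drift.pop((node, c))
    # drop dangling root chains (root with single child and no other role)
    while True:
        children = {}
        parents = {c: p for (p, c) in drift}
        for (p, c) in drift:
            children.setdefault(p, []).append(c)
        admix_parents = {p for v in admix.values() for p in v[:2]}
        roots = [n for n in children if n not in parents
                 and n not in admix]
        trimmed = False
        for r in roots:
            if (len(children[r]) == 1 and r not in keep
                    and r not in admix_parents):
                drift.pop((r, children[r][0]))
                trimmed = True
        if not trimmed:
            break
    return AdmixtureGraph(drift, admix)


def copying_matrix_from_ibd(segments: pd.DataFrame,
                            populations: dict) -> CopyingMatrix:
    """Build a haplotype-copying surrogate from IBD totals: each
    individual's copying vector is its summed shared length with every
    other individual plus a uniform background."""
    inds = [i for members in populations.values() for i in members]
    lengths = pd.DataFrame(1.0, index=inds, columns=inds)
    totals = segments.groupby(["ind_a", "ind_b"])["length_cM"].sum()
    for (a, b), v in totals.items():
        if a in lengths.index and b in lengths.index:
            lengths.loc[a, b] += v
            lengths.loc[b, a] += v
    np.fill_diagonal(lengths.values, 0.0)
    clusters = {ind: pop for pop, members in populations.items()
                for ind in members}
    return CopyingMatrix(lengths, clusters=clusters)
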