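"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design of an Isthmo-Colombian
archaeogenomic survey: a SNP-array panel, leaf populations drifting on an
admixture graph under the Balding-Nichols law, colonial three-way
(Indigenous / European / African) admixture tracts in modern genomes,
low-coverage damaged ancient read pileups, within-population IBD segments,
sex-chromosome read counts and Y-marker panels.  Every generator is
deterministic under a fixed seed and returns the underlying truth so that
downstream inferences can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (GenotypeMatrix, LocalAncestryCalls, QMatrix,
                         make_individual_table, make_pileup, make_snp_table,
                         make_ibd_table)
from .graph import AdmixtureGraph

_DAMAGE_PARTNER = {"C": "T", "T": "C", "G": "A", "A": "G"}


@dataclass
class SimulationConfig:
    """Desk-scale defaults emulating the study conditions.

    ``coverage_mean`` is mean fold-coverage per SNP; ``damage_rate_5p`` is
    the terminal C->T deamination rate at read position 1, decaying
    geometrically inward with factor ``damage_decay``; read lengths are
    ``read_length_min`` plus a geometric tail with per-base decay
    ``read_length_lambda`` (short post-mortem fragments).
    """

    n_snps: int = 20_000
    seed: int = 0
    root_freq_law: tuple = ("uniform", 0.05, 0.95)
    sample_sizes: dict = field(default_factory=dict)
    coverage_mean: float = 0.5
    damage_rate_5p: float = 0.2
    damage_decay: float = 0.5
    contamination_rate: float = 0.0
    read_length_lambda: float = 0.02
    read_length_min: int = 30
    generation_time: float = 25.0

    def __post_init__(self):
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        for r in (self.damage_rate_5p, self.contamination_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def draw_root_frequencies(law: tuple, n_snps: int,
                          rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=n_snps)
    if kind == "beta":
        return rng.beta(law[1], law[2], size=n_snps)
    raise ValueError(f"unknown root frequency law {kind!r}")


def synthetic_snp_table(n_snps: int, rng: np.random.Generator,
                        n_chrom: int = 20,
                        chrom_length_bp: int = 100_000_000) -> pd.DataFrame:
    """Uniformly spaced array panel over ``n_chrom`` chromosomes with a
    flat 1 cM/Mb map and random distinct ref/alt nucleotides."""
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps - per.sum()] += 1
    chroms, positions = [], []
    for c in range(n_chrom):
        pos = np.sort(rng.choice(
            np.arange(1, chrom_length_bp, 100), size=per[c], replace=False))
        chroms.extend([str(c + 1)] * per[c])
        positions.append(pos)
    positions = np.concatenate(positions)
    ref = rng.choice(list("ACGT"), size=n_snps)
    shift = rng.integers(1, 4, size=n_snps)
    bases = np.array(list("ACGT"))
    base_idx = np.searchsorted(bases, ref)
    alt = bases[(base_idx + shift) % 4]
    ids = [f"rs{i}" for i in range(n_snps)]
    return make_snp_table(ids, chroms, positions, None, ref, alt)


# ---------------------------------------------------------------------------
# Graph frequencies and genotypes
# ---------------------------------------------------------------------------

def _drift_frequencies(p: np.ndarray, d: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols child of parent frequencies ``p`` after drift ``d``:
    Beta with mean p and variance d p (1 - p); fixed alleles stay fixed."""
    if not 0.0 <= d < 1.0:
        raise ValueError(f"drift length {d} outside [0, 1)")
    if d == 0.0:
        return p.copy()
    child = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    scale = (1.0 - d) / d
    child[interior] = rng.beta(p[interior] * scale,
                               (1.0 - p[interior]) * scale)
    return child


def simulate_graph_frequencies(graph: AdmixtureGraph, cfg: SimulationConfig,
                               rng: Optional[np.random.Generator] = None,
                               ) -> dict:
    """Per-node allele-frequency arrays for every node of the graph."""
    rng = cfg.rng() if rng is None else rng
    freqs = {}
    g = graph.to_networkx()
    for node in graph.nodes:
        if g.in_degree(node) == 0:
            freqs[node] = draw_root_frequencies(cfg.root_freq_law,
                                                cfg.n_snps, rng)
        elif node in graph.admixtures:
            left, right, alpha = graph.admixtures[node]
            freqs[node] = alpha * freqs[left] + (1.0 - alpha) * freqs[right]
        else:
            parent = next(iter(g.predecessors(node)))
            d = graph.drift_edges[(parent, node)]
            freqs[node] = _drift_frequencies(freqs[parent], d, rng)
    return freqs


def sample_diploid_genotypes(freqs: dict, sample_sizes: dict,
                             rng: np.random.Generator,
                             snps: Optional[pd.DataFrame] = None,
                             era: str = "modern") -> GenotypeMatrix:
    """Binomial(2, p) genotypes for the requested populations.

    ``freqs`` maps population name to a per-SNP frequency vector; all
    vectors must share the panel in ``snps`` (generated if omitted).
    """
    pops = list(sample_sizes)
    n_snps = len(next(iter(freqs.values())))
    if snps is None:
        snps = synthetic_snp_table(n_snps, rng)
    blocks, ind_ids, ind_pops = [], [], []
    for pop in pops:
        n = sample_sizes[pop]
        blocks.append(rng.binomial(2, freqs[pop], size=(n, n_snps)))
        ind_ids.extend(f"{pop}_{i}" for i in range(n))
        ind_pops.extend([pop] * n)
    calls = np.vstack(blocks).astype(np.int8)
    individuals = make_individual_table(ind_ids, ind_pops,
                                        era=[era] * len(ind_ids))
    return GenotypeMatrix(calls, snps, individuals)


def sample_pseudo_haploid_genotypes(freqs: dict, sample_sizes: dict,
                                    rng: np.random.Generator,
                                    snps: Optional[pd.DataFrame] = None,
                                    missing_rate: float = 0.0,
                                    era: str = "ancient") -> GenotypeMatrix:
    """Single sampled allele per SNP coded 0/2, with optional missingness."""
    pops = list(sample_sizes)
    n_snps = len(next(iter(freqs.values())))
    if snps is None:
        snps = synthetic_snp_table(n_snps, rng)
    blocks, ind_ids, ind_pops = [], [], []
    for pop in pops:
        n = sample_sizes[pop]
        calls = 2 * rng.binomial(1, freqs[pop], size=(n, n_snps))
        if missing_rate > 0:
            calls[rng.random((n, n_snps)) < missing_rate] = -1
        blocks.append(calls)
        ind_ids.extend(f"{pop}_{i}" for i in range(n))
        ind_pops.extend([pop] * n)
    individuals = make_individual_table(
        ind_ids, ind_pops, era=[era] * len(ind_ids),
        ploidy_mode=["pseudo_haploid"] * len(ind_ids))
    return GenotypeMatrix(np.vstack(blocks).astype(np.int8), snps, individuals)


# ---------------------------------------------------------------------------
# Ancient read pileups
# ---------------------------------------------------------------------------

def sample_ancient_pileup(genotype: np.ndarray, snps: pd.DataFrame,
                          cfg: SimulationConfig,
                          rng: Optional[np.random.Generator] = None,
                          ind_id: str = "ancient_0",
                          contaminant_freqs: Optional[np.ndarray] = None,
                          ) -> pd.DataFrame:
    """Poisson-depth damaged reads over the SNP panel for one individual.

    ``genotype`` is the true diploid alt dosage (0/1/2) per SNP.  Each read
    carries one allele of the individual, or a contaminant allele drawn from
    ``contaminant_freqs`` with probability ``cfg.contamination_rate``;
    terminal deamination converts C->T near the 5' end and G->A near the
    3' end with geometrically decaying probability.
    """
    rng = cfg.rng() if rng is None else rng
    genotype = np.asarray(genotype)
    n_snps = len(snps)
    depth = rng.poisson(cfg.coverage_mean, size=n_snps)
    snp_idx = np.repeat(np.arange(n_snps), depth)
    n_reads = snp_idx.size
    if n_reads == 0:
        return make_pileup(pd.DataFrame(columns=[
            "ind_id", "snp_id", "base", "baseq", "mapq", "pos_in_read",
            "read_len", "strand"]))

    # true allele: one of the individual's two chromosomes
    alt_prob = genotype[snp_idx] / 2.0
    is_alt = rng.random(n_reads) < alt_prob
    if contaminant_freqs is not None and cfg.contamination_rate > 0:
        contam = rng.random(n_reads) < cfg.contamination_rate
        is_alt[contam] = (rng.random(contam.sum())
                          < contaminant_freqs[snp_idx[contam]])

    ref = snps["allele_ref"].to_numpy(dtype=object)[snp_idx]
    alt = snps["allele_alt"].to_numpy(dtype=object)[snp_idx]
    base = np.where(is_alt, alt, ref).astype(object)

    read_len = cfg.read_length_min + rng.geometric(
        max(cfg.read_length_lambda, 1e-9), size=n_reads) - 1
    pos = rng.integers(1, read_len + 1)
    pos3 = read_len - pos + 1

    decay5 = cfg.damage_rate_5p * cfg.damage_decay ** (pos - 1)
    decay3 = cfg.damage_rate_5p * cfg.damage_decay ** (pos3 - 1)
    u = rng.random(n_reads)
    flip_ct = (base == "C") & (u < decay5)
    flip_ga = (base == "G") & (u < decay3)
    base[flip_ct] = "T"
    base[flip_ga] = "A"

    return make_pileup(pd.DataFrame({
        "ind_id": ind_id,
        "snp_id": snps["snp_id"].to_numpy(dtype=object)[snp_idx],
        "base": base,
        "baseq": rng.integers(30, 42, size=n_reads),
        "mapq": np.full(n_reads, 37),
        "pos_in_read": pos,
        "read_len": read_len,
        "strand": np.where(rng.random(n_reads) < 0.5, "+", "-"),
    }))


# ---------------------------------------------------------------------------
# Colonial admixture tracts
# ---------------------------------------------------------------------------

@dataclass
class TractSimulation:
    genotypes: GenotypeMatrix
    haplotypes: np.ndarray          # (2n, n_snps) 0/1 alt alleles
    la_truth: LocalAncestryCalls
    la_emitted: LocalAncestryCalls
    q_truth: QMatrix


def _markov_tract_labels(genetic_pos: np.ndarray, chrom: np.ndarray,
                         proportions: np.ndarray, switch_rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Ancestry labels along one haplotype: a continuous-time Markov jump
    chain along genetic distance whose stationary law is ``proportions``."""
    labels = np.empty(len(genetic_pos), dtype=np.int8)
    k = len(proportions)
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        cm = genetic_pos[idx]
        state = rng.choice(k, p=proportions)
        if switch_rate <= 0:
            labels[idx] = state
            continue
        next_switch = cm[0] + rng.exponential(1.0 / switch_rate)
        for j, pos in zip(idx, cm):
            while pos >= next_switch:
                state = rng.choice(k, p=proportions)
                next_switch += rng.exponential(1.0 / switch_rate)
            labels[j] = state
    return labels


def simulate_admixed_tracts(panel_freqs: dict, proportions,
                            switch_rate: float, snps: pd.DataFrame,
                            n_individuals: int, rng: np.random.Generator,
                            ancestries: tuple = ("IA", "EUR", "AFR"),
                            viterbi_noise: float = 0.0,
                            posterior_noise: float = 0.0,
                            population: str = "Admixed") -> TractSimulation:
    """Three-way colonial admixture with per-haplotype ancestry tracts.

    Tract labels follow a Markov chain along the genetic map with switch
    intensity ``switch_rate`` per cM and stationary distribution
    ``proportions``; alleles are drawn from the labelled ancestral panel.
    Emitted local-ancestry calls equal the truth blurred by
    ``viterbi_noise`` (label misassignment probability) and
    ``posterior_noise`` (mass spread off the emitted label).
    """
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if viterbi_noise > 0 and posterior_noise <= 0:
        raise ValueError("viterbi_noise requires posterior_noise > 0")
    k = len(ancestries)
    n_snps = len(snps)
    gpos = snps["genetic_pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    freq_stack = np.stack([panel_freqs[a] for a in ancestries])

    n_hap = 2 * n_individuals
    truth = np.empty((n_hap, n_snps), dtype=np.int8)
    haplotypes = np.empty((n_hap, n_snps), dtype=np.int8)
    for h in range(n_hap):
        lab = _markov_tract_labels(gpos, chrom, proportions, switch_rate, rng)
        truth[h] = lab
        haplotypes[h] = rng.binomial(1, freq_stack[lab, np.arange(n_snps)])

    emitted = truth.copy()
    if viterbi_noise > 0:
        flip = rng.random(truth.shape) < viterbi_noise
        emitted[flip] = (truth[flip]
                         + rng.integers(1, k, size=int(flip.sum()))) % k

    eye = np.eye(k)
    post_truth = eye[truth]
    post_emitted = ((1.0 - posterior_noise) * eye[emitted]
                    + posterior_noise / k)

    ind_ids = [f"{population}_{i}" for i in range(n_individuals)]
    calls = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    individuals = make_individual_table(ind_ids,
                                        [population] * n_individuals)
    genotypes = GenotypeMatrix(calls, snps, individuals)
    la_truth = LocalAncestryCalls(ind_ids, tuple(ancestries), truth,
                                  post_truth)
    la_emitted = LocalAncestryCalls(ind_ids, tuple(ancestries), emitted,
                                    post_emitted)
    frac = np.stack([(truth[2 * i:2 * i + 2] == np.arange(k)[:, None, None])
                     .mean(axis=(1, 2)) for i in range(n_individuals)])
    q_truth = QMatrix(ind_ids, list(ancestries), frac,
                      frozenset({ancestries[0]}))
    return TractSimulation(genotypes, haplotypes, la_truth, la_emitted,
                           q_truth)


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

def simulate_ibd_segments(populations: dict, pair_rate: float,
                          mean_length_cM: float,
                          rng: np.random.Generator,
                          map_length_cM: float = 3000.0) -> pd.DataFrame:
    """Poisson segment counts per within-population pair with exponential
    genetic lengths, positioned uniformly on a synthetic map."""
    if mean_length_cM <= 0:
        raise ValueError("mean_length_cM must be positive")
    rows = []
    for pop, inds in populations.items():
        inds = list(inds)
        for i in range(len(inds)):
            for j in range(i + 1, len(inds)):
                for _ in range(rng.poisson(pair_rate)):
                    length = rng.exponential(mean_length_cM)
                    start = rng.uniform(0, map_length_cM)
                    rows.append((inds[i], inds[j], "1", start,
                                 start + length))
    df = pd.DataFrame(rows, columns=["ind_a", "ind_b", "chrom",
                                     "start_cM", "end_cM"])
    return make_ibd_table(df)


# ---------------------------------------------------------------------------
# Sex-chromosome read counts
# ---------------------------------------------------------------------------

#: synthetic karyotype: 20 autosomes with decreasing lengths, then X and Y
DEFAULT_CHROM_LENGTHS = {str(i + 1): int(2.4e8 - 0.9e7 * i)
                         for i in range(20)}
DEFAULT_CHROM_LENGTHS["X"] = 155_000_000
DEFAULT_CHROM_LENGTHS["Y"] = 59_000_000


def simulate_sex_reads(karyotype: str, n_reads: int,
                       rng: np.random.Generator,
                       chrom_lengths: Optional[dict] = None,
                       y_mismap: float = 0.001) -> pd.Series:
    """Multinomial read counts per chromosome for an XX or XY individual.

    Rates scale with chromosome length times copy number; an XX individual
    receives Y reads only at the ``y_mismap`` mismapping floor.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if karyotype not in ("XX", "XY"):
        raise ValueError("karyotype must be XX or XY")
    lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    weights = {}
    for chrom, length in lengths.items():
        if chrom == "X":
            copy = 2.0 if karyotype == "XX" else 1.0
        elif chrom == "Y":
            copy = y_mismap if karyotype == "XX" else 1.0
        else:
            copy = 2.0
        weights[chrom] = length * copy / 2.0
    w = np.array(list(weights.values()))
    counts = rng.multinomial(n_reads, w / w.sum())
    return pd.Series(counts, index=list(weights), name="n_reads")


# ---------------------------------------------------------------------------
# Y-marker panels
# ---------------------------------------------------------------------------

def simulate_y_markers(true_path, panel: pd.DataFrame, damage_rate: float,
                       rng: np.random.Generator,
                       missing_rate: float = 0.0) -> pd.DataFrame:
    """Observed Y-marker alleles: derived on the true haplogroup path,
    ancestral elsewhere, with transition alleles flipped by deamination
    at rate ``damage_rate`` (C<->T and G<->A only)."""
    path = set(true_path)
    rows = []
    for r in panel.itertuples(index=False):
        if missing_rate > 0 and rng.random() < missing_rate:
            continue
        allele = r.derived if r.branch in path else r.ancestral
        pair = frozenset((r.ancestral, r.derived))
        if (damage_rate > 0 and pair in (frozenset("CT"), frozenset("GA"))
                and rng.random() < damage_rate):
            allele = _DAMAGE_PARTNER[allele]
        rows.append((r.marker, allele))
    return pd.DataFrame(rows, columns=["marker", "allele"])


# ---------------------------------------------------------------------------
# Pedigree pairs
# ---------------------------------------------------------------------------

def simulate_pedigree_pair(relationship: str, freqs: np.ndarray,
                           rng: np.random.Generator) -> tuple:
    """Diploid genotype pair with the IBD-sharing pattern of the stated
    relationship: identical (copy), first degree (one allele shared IBD at
    every locus), second degree (one allele shared with probability 1/2),
    unrelated (independent)."""
    freqs = np.asarray(freqs)
    n = freqs.size
    a = rng.binomial(1, freqs, n)
    b = rng.binomial(1, freqs, n)
    g1 = a + b
    if relationship == "identical":
        g2 = g1.copy()
    elif relationship == "unrelated":
        g2 = rng.binomial(1, freqs, n) + rng.binomial(1, freqs, n)
    elif relationship == "first_degree":
        shared = np.where(rng.random(n) < 0.5, a, b)
        g2 = shared + rng.binomial(1, freqs, n)
    elif relationship == "second_degree":
        shared = np.where(rng.random(n) < 0.5, a, b)
        ibd = rng.random(n) < 0.5
        g2 = np.where(ibd, shared, rng.binomial(1, freqs, n)) \
            + rng.binomial(1, freqs, n)
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    return g1.astype(np.int8), g2.astype(np.int8)


@dataclass
class TruthBundle:
    """Truth records emitted alongside a full synthetic study."""

    graph: Optional[AdmixtureGraph] = None
    leaf_frequencies: Optional[dict] = None
    genotypes: Optional[GenotypeMatrix] = None
    tracts: Optional[TractSimulation] = None
    kinship_pairs: Optional[list] = None
    sexes: Optional[dict] = None
    ibd_segments: Optional[pd.DataFrame] = None
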