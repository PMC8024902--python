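"""f-statistics with weighted block-jackknife uncertainty, outgroup-f3
summaries and trees, and PCA with least-squares projection.

Estimates are means over SNPs of allele-frequency products; standard
errors come from a leave-one-block-out jackknife over contiguous genomic
blocks weighted by block SNP counts, which is robust to linkage.  The
sign and argument conventions follow the standard admixture-test usage:
f4(W, X; Y, Z) > 0 indicates that Y shares more drift with W than with X,
and a significantly negative f3(C; A, B) marks C as admixed between
sources related to A and B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MISSING, GenotypeMatrix

Z_REJECT = 3.3          # |Z| convention for rejecting a tree conformation
MIN_SNPS_RELIABLE = 30_000   # below this, statistics carry a low-SNP flag


def two_sided_p(z: float) -> float:
    """Two-sided standard-normal tail probability for a Z score."""
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockDefinition:
    """Assignment of every SNP to one of m contiguous genomic blocks."""

    block_of_snp: np.ndarray

    def __post_init__(self):
        self.block_of_snp = np.asarray(self.block_of_snp, dtype=np.int64)
        if self.n_blocks < 2:
            raise ValueError("need at least 2 jackknife blocks")

    @property
    def n_blocks(self) -> int:
        return int(self.block_of_snp.max()) + 1 if self.block_of_snp.size \
            else 0

    @property
    def n_snps(self) -> int:
        return self.block_of_snp.size

    @classmethod
    def from_positions(cls, snps: pd.DataFrame,
                       block_size_bp: int = 5_000_000) -> "BlockDefinition":
        """Physical blocks of ``block_size_bp`` within each chromosome
        (the AdmixTools convention, default 5 Mb)."""
        key = (snps["chrom"].astype(str) + ":"
               + (snps["physical_pos"] // block_size_bp).astype(str))
        return cls(pd.factorize(key)[0])

    @classmethod
    def equal_count(cls, n_snps: int, n_blocks: int) -> "BlockDefinition":
        """m blocks of near-equal SNP count, contiguous in panel order."""
        return cls(np.minimum(np.arange(n_snps) * n_blocks // n_snps,
                              n_blocks - 1))


# ---------------------------------------------------------------------------
# Weighted block jackknife
# ---------------------------------------------------------------------------

def _block_sums(terms: np.ndarray, used: np.ndarray,
                blocks: BlockDefinition) -> tuple:
    codes = blocks.block_of_snp[used]
    m = blocks.n_blocks
    t = np.bincount(codes, weights=terms, minlength=m)
    n = np.bincount(codes, minlength=m).astype(float)
    return t, n


def jackknife_mean(terms: np.ndarray, used: np.ndarray,
                   blocks: BlockDefinition) -> tuple:
    """Mean over SNPs with weighted block-jackknife SE.

    Uses the Busing weighted-jackknife variance with block SNP counts as
    weights; empty blocks are ignored.
    """
    t, n = _block_sums(terms, used, blocks)
    keep = n > 0
    t, n = t[keep], n[keep]
    m = keep.sum()
    if m < 2:
        raise ValueError("fewer than 2 non-empty jackknife blocks")
    n_tot = n.sum()
    theta = t.sum() / n_tot
    loo = (t.sum() - t) / (n_tot - n)
    h = n_tot / n
    tau = h * theta - (h - 1.0) * loo
    theta_j = m * theta - ((1.0 - n / n_tot) * loo).sum()
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / m
    return float(theta), float(np.sqrt(var)), int(n_tot), int(m)


def jackknife_mean_vector(term_matrix: np.ndarray, used_matrix: np.ndarray,
                          blocks: BlockDefinition) -> tuple:
    """Joint jackknife for a vector of SNP-mean statistics.

    ``term_matrix`` is (k, n_snps) with arbitrary values where unused;
    ``used_matrix`` the matching boolean mask.  Returns the estimate
    vector and its jackknife covariance (pairwise Busing weighting).
    """
    k, _ = term_matrix.shape
    m = blocks.n_blocks
    t = np.zeros((k, m))
    n = np.zeros((k, m))
    for i in range(k):
        t[i], n[i] = _block_sums(term_matrix[i][used_matrix[i]],
                                 used_matrix[i], blocks)
    if (n.sum(axis=0) == 0).any():
        keep = n.sum(axis=0) > 0
        t, n = t[:, keep], n[:, keep]
        m = int(keep.sum())
    if m < 2:
        raise ValueError("fewer than 2 non-empty jackknife blocks")
    n_tot = n.sum(axis=1, keepdims=True)
    theta = t.sum(axis=1, keepdims=True) / n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (t.sum(axis=1, keepdims=True) - t) / (n_tot - n)
        h = n_tot / n
    loo = np.where(np.isfinite(loo), loo, theta)
    h = np.where(np.isfinite(h), h, n_tot)
    tau = h * theta - (h - 1.0) * loo
    theta_j = m * theta - ((1.0 - n / n_tot) * loo).sum(axis=1,
                                                        keepdims=True)
    dev = (tau - theta_j) / np.sqrt(np.maximum(h - 1.0, 1e-12))
    cov = dev @ dev.T / m
    return theta.ravel(), cov


# ---------------------------------------------------------------------------
# Population allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class PopulationFrequencies:
    """Per-population alternative-allele frequencies and chromosome counts.

    Diploid individuals contribute two chromosomes per non-missing call;
    pseudo-haploid individuals contribute one (their 0/2 code is a single
    sampled allele).
    """

    pops: list
    freq: np.ndarray     # (n_pops, n_snps), NaN where no data
    counts: np.ndarray   # chromosomes observed
    snps: pd.DataFrame

    def index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None


def population_frequencies(g: GenotypeMatrix,
                           grouping: Optional[dict] = None
                           ) -> PopulationFrequencies:
    """Frequencies per population (or per custom grouping of ind_ids)."""
    if grouping is None:
        grouping = {pop: list(sub["ind_id"]) for pop, sub in
                    g.individuals.groupby("population", sort=False)}
    idx = {ind: i for i, ind in enumerate(g.individuals["ind_id"])}
    ph = (g.individuals["ploidy_mode"] == "pseudo_haploid").to_numpy()
    pops = list(grouping)
    freq = np.full((len(pops), g.n_snps), np.nan)
    counts = np.zeros((len(pops), g.n_snps))
    for p, pop in enumerate(pops):
        rows = np.array([idx[i] for i in grouping[pop]])
        calls = g.calls[rows]
        present = calls != MISSING
        is_ph = ph[rows][:, None]
        alt = np.where(present, calls, 0).astype(float)
        alt = np.where(is_ph, alt / 2.0, alt)
        chrom = np.where(present, np.where(is_ph, 1.0, 2.0), 0.0)
        n = chrom.sum(axis=0)
        counts[p] = n
        with np.errstate(invalid="ignore"):
            freq[p] = np.where(n > 0, alt.sum(axis=0) / np.maximum(n, 1),
                               np.nan)
    return PopulationFrequencies(pops, freq, counts, g.snps)


# ---------------------------------------------------------------------------
# f2 / f3 / f4
# ---------------------------------------------------------------------------

@dataclass
class FStatResult:
    name: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    @property
    def low_snp_flag(self) -> bool:
        return self.n_snps < MIN_SNPS_RELIABLE

    @property
    def p_value(self) -> float:
        return two_sided_p(self.z)

    def __str__(self):
        return (f"{self.name}{self.pops}: {self.estimate:.6g} "
                f"+/- {self.se:.3g} (Z = {self.z:.2f}, "
                f"n = {self.n_snps} SNPs / {self.n_blocks} blocks)")


def _result(name, pops, terms, used, blocks) -> FStatResult:
    est, se, n_snps, m = jackknife_mean(terms, used, blocks)
    z = est / se if se > 0 else 0.0
    return FStatResult(name, tuple(pops), est, se, z, n_snps, m)


def _bias_term(pf: PopulationFrequencies, i: int) -> np.ndarray:
    """Unbiased correction for Var(p-hat): p(1-p)/(n-1) chromosomes."""
    p, n = pf.freq[i], pf.counts[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = p * (1.0 - p) / (n - 1.0)
    return np.where(n > 1, corr, 0.0)


def f4(pf: PopulationFrequencies, w: str, x: str, y: str, z: str,
       blocks: BlockDefinition) -> FStatResult:
    """f4(W, X; Y, Z) = E[(pW - pX)(pY - pZ)]; positive values indicate
    excess affinity of Y (relative to Z) for W over X."""
    iw, ix, iy, iz = (pf.index(p) for p in (w, x, y, z))
    used = np.isfinite(pf.freq[[iw, ix, iy, iz]]).all(axis=0)
    terms = ((pf.freq[iw] - pf.freq[ix])
             * (pf.freq[iy] - pf.freq[iz]))[used]
    return _result("f4", (w, x, y, z), terms, used, blocks)


def f3(pf: PopulationFrequencies, c: str, a: str, b: str,
       blocks: BlockDefinition, bias_correction: bool = True) -> FStatResult:
    """f3(C; A, B) = E[(pC - pA)(pC - pB)], optionally with the
    finite-sample correction for the variance of pC.  Outgroup-f3 shared
    drift is computed with the correction off."""
    ic, ia, ib = (pf.index(p) for p in (c, a, b))
    used = np.isfinite(pf.freq[[ic, ia, ib]]).all(axis=0)
    terms = ((pf.freq[ic] - pf.freq[ia])
             * (pf.freq[ic] - pf.freq[ib]))
    if bias_correction:
        terms = terms - _bias_term(pf, ic)
    return _result("f3", (c, a, b), terms[used], used, blocks)


def f2(pf: PopulationFrequencies, a: str, b: str,
       blocks: BlockDefinition, bias_correction: bool = True) -> FStatResult:
    ia, ib = pf.index(a), pf.index(b)
    used = np.isfinite(pf.freq[[ia, ib]]).all(axis=0)
    terms = (pf.freq[ia] - pf.freq[ib]) ** 2
    if bias_correction:
        terms = terms - _bias_term(pf, ia) - _bias_term(pf, ib)
    return _result("f2", (a, b), terms[used], used, blocks)


def f2_basis(pf: PopulationFrequencies, leaves, blocks: BlockDefinition,
             bias_correction: bool = True) -> dict:
    """All pairwise f2 among ``leaves`` with joint jackknife covariance."""
    leaves = list(leaves)
    pairs = [(a, b) for i, a in enumerate(leaves) for b in leaves[i + 1:]]
    k = len(pairs)
    terms = np.zeros((k, pf.freq.shape[1]))
    used = np.zeros((k, pf.freq.shape[1]), dtype=bool)
    for r, (a, b) in enumerate(pairs):
        ia, ib = pf.index(a), pf.index(b)
        u = np.isfinite(pf.freq[[ia, ib]]).all(axis=0)
        t = (pf.freq[ia] - pf.freq[ib]) ** 2
        if bias_correction:
            t = t - _bias_term(pf, ia) - _bias_term(pf, ib)
        terms[r], used[r] = np.where(u, t, 0.0), u
    est, cov = jackknife_mean_vector(terms, used, blocks)
    return {"pairs": pairs, "estimate": est, "cov": cov,
            "n_snps": int(used.all(axis=0).sum())}


def f4_matrix(pf: PopulationFrequencies, left, right,
              blocks: BlockDefinition) -> dict:
    """f4(left_i, left_0; right_j, right_0) for the qpWave rank test,
    with the joint jackknife covariance of its entries."""
    left, right = list(left), list(right)
    li, ri = [pf.index(p) for p in left], [pf.index(p) for p in right]
    rows = [(i, j) for i in range(1, len(left))
            for j in range(1, len(right))]
    k = len(rows)
    terms = np.zeros((k, pf.freq.shape[1]))
    used = np.zeros((k, pf.freq.shape[1]), dtype=bool)
    for r, (i, j) in enumerate(rows):
        u = np.isfinite(pf.freq[[li[i], li[0], ri[j], ri[0]]]).all(axis=0)
        t = ((pf.freq[li[i]] - pf.freq[li[0]])
             * (pf.freq[ri[j]] - pf.freq[ri[0]]))
        terms[r], used[r] = np.where(u, t, 0.0), u
    est, cov = jackknife_mean_vector(terms, used, blocks)
    F = est.reshape(len(left) - 1, len(right) - 1)
    return {"F": F, "cov": cov, "left": left, "right": right,
            "n_snps": int(used.all(axis=0).sum())}


# ---------------------------------------------------------------------------
# Outgroup-f3 matrix and NJ tree
# ---------------------------------------------------------------------------

def outgroup_f3_matrix(pf: PopulationFrequencies, pops, outgroup: str,
                       blocks: BlockDefinition,
                       min_snps: int = MIN_SNPS_RELIABLE,
                       z_min: float = Z_REJECT) -> dict:
    """Symmetric shared-drift matrix f3(outgroup; A, B) over all pairs.

    Pairs with fewer than ``min_snps`` SNPs or |Z| <= ``z_min`` are
    flagged for downstream exclusion.
    """
    pops = list(pops)
    n = len(pops)
    est = np.full((n, n), np.nan)
    flagged = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i, n):
            r = f3(pf, outgroup, pops[i], pops[j], blocks,
                   bias_correction=False)
            est[i, j] = est[j, i] = r.estimate
            bad = r.n_snps < min_snps or abs(r.z) <= z_min
            flagged[i, j] = flagged[j, i] = bad
    return {"f3": pd.DataFrame(est, index=pops, columns=pops),
            "flagged": pd.DataFrame(flagged, index=pops, columns=pops)}


def f3_nj_tree(f3_df: pd.DataFrame, rooting_pop: str) -> str:
    """Neighbor-joining tree on inverse outgroup-f3 distances, rooted on
    the designated outgroup leaf; returns newick."""
    import skbio

    pops = list(f3_df.index)
    values = f3_df.to_numpy(float)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive f3 for pair ({pops[i]}, {pops[j]}); "
            "cannot invert to a distance")
    dist = 1.0 / values
    np.fill_diagonal(dist, 0.0)
    dm = skbio.DistanceMatrix((dist + dist.T) / 2.0, ids=pops)
    tree = skbio.tree.nj(dm)
    if rooting_pop not in pops:
        raise KeyError(f"rooting population {rooting_pop!r} not in matrix")
    tip = tree.find(rooting_pop)
    rooted = tree.root_at(tip.parent) if tip.parent is not None else tree
    return str(rooted).strip()


# ---------------------------------------------------------------------------
# PCA with projection
# ---------------------------------------------------------------------------

def pca_project(g_modern: GenotypeMatrix, g_lowcov: Optional[GenotypeMatrix],
                n_components: int = 10, shrink: bool = False) -> pd.DataFrame:
    """PCs from modern data; least-squares projection of sparse samples.

    Modern genotypes are centred at 2p and scaled by sqrt(p(1-p)), with
    residual missingness mean-imputed.  A low-coverage or masked sample is
    projected by solving the least-squares fit of its non-missing,
    standardized genotypes onto the SNP loadings restricted to those
    sites.  With ``shrink`` the in-analysis scores are deflated by an
    eigenvalue-based factor so they are comparable with projected ones.
    """
    dos = g_modern.dosage()
    p = np.nanmean(dos, axis=0) / 2.0
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    dos = dos[:, informative]
    p = p[informative]
    scale = np.sqrt(p * (1.0 - p))
    X = (dos - 2.0 * p) / scale
    X[~np.isfinite(X)] = 0.0

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T

    if shrink and len(s) > k:
        noise = float(np.mean(s[k:] ** 2))
        factors = np.sqrt(np.maximum(s[:k] ** 2 - noise, 0.0)) / s[:k]
        scores = scores * factors

    rows = [pd.DataFrame({
        "ind_id": g_modern.individuals["ind_id"],
        "population": g_modern.individuals["population"],
        "projected": False,
        **{f"PC{i + 1}": scores[:, i] for i in range(k)},
    })]
    if g_lowcov is not None:
        ldos = g_lowcov.dosage()[:, informative]
        proj = np.zeros((len(ldos), k))
        for r in range(len(ldos)):
            obs = np.isfinite(ldos[r])
            if not obs.any():
                raise ValueError(
                    f"sample {g_lowcov.individuals['ind_id'].iat[r]} has "
                    "no genotypes overlapping the PCA panel")
            x = (ldos[r, obs] - 2.0 * p[obs]) / scale[obs]
            proj[r], *_ = np.linalg.lstsq(loadings[obs], x, rcond=None)
        rows.append(pd.DataFrame({
            "ind_id": g_lowcov.individuals["ind_id"],
            "population": g_lowcov.individuals["population"],
            "projected": True,
            **{f"PC{i + 1}": proj[:, i] for i in range(k)},
        }))
    return pd.concat(rows, ignore_index=True)
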