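"""Readers, writers and dataset-level filters for genotype panels.

Supported on-disk formats are the plain-text conventions of the field:
EIGENSTRAT triplets (.geno/.snp/.ind), PLINK text (.ped/.map, import only),
whitespace-delimited Q matrices, and TSV tables for local-ancestry calls,
IBD segments and read pileups.  The filters mirror PLINK semantics: the
``--geno`` site filter runs before the ``--mind`` individual filter, and
both remove rows whose missing fraction strictly exceeds the threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    MISSING, STRAND_AMBIGUOUS_PAIRS, TRANSITION_PAIRS, FormatError,
    GenotypeMatrix, LocalAncestryCalls, QMatrix, make_ibd_table,
    make_individual_table, make_pileup, make_snp_table,
)

logger = logging.getLogger(__name__)

_SEX_TO_CODE = {"male": "M", "female": "F", "unknown": "U"}
_CODE_TO_SEX = {"M": "male", "F": "female", "U": "unknown"}


# ---------------------------------------------------------------------------
# EIGENSTRAT triplet
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read an EIGENSTRAT triplet.

    The .geno file holds one line per SNP, one digit per individual, with
    9 coding a missing call; digits are alternative-allele counts.  The
    .ind file may carry two optional trailing columns (era, ploidy_mode)
    beyond the classic ind/sex/population triple.
    """
    ind_rows = []
    with open(ind_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 5):
                raise FormatError(
                    f"{ind_path}:{lineno}: expected 3 or 5 columns")
            ind_id, sex_code, pop = parts[:3]
            era = parts[3] if len(parts) == 5 else "modern"
            ploidy = parts[4] if len(parts) == 5 else None
            ind_rows.append((ind_id, pop, _CODE_TO_SEX.get(sex_code, "unknown"),
                             era, ploidy))
    individuals = make_individual_table(
        [r[0] for r in ind_rows], [r[1] for r in ind_rows],
        sex=[r[2] for r in ind_rows], era=[r[3] for r in ind_rows],
        ploidy_mode=None if ind_rows and ind_rows[0][4] is None
        else [r[4] for r in ind_rows])

    snp = pd.read_csv(snp_path, sep=r"\s+", header=None,
                      names=["snp_id", "chrom", "genetic_pos",
                             "physical_pos", "allele_ref", "allele_alt"],
                      dtype={"snp_id": str, "chrom": str})
    snps = make_snp_table(snp["snp_id"], snp["chrom"], snp["physical_pos"],
                          snp["genetic_pos"], snp["allele_ref"],
                          snp["allele_alt"])

    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(individuals):
                raise FormatError(
                    f"{geno_path}:{lineno}: {len(line)} genotypes for "
                    f"{len(individuals)} individuals")
            if set(line) - set("0129"):
                bad = sorted(set(line) - set("0129"))[0]
                raise FormatError(
                    f"{geno_path}:{lineno}: genotype symbol {bad!r} "
                    "outside {0,1,2,9}")
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    calls = np.array(rows, dtype=np.int8).T if rows else \
        np.zeros((len(individuals), 0), dtype=np.int8)
    if calls.shape[1] != len(snps):
        raise FormatError(
            f"{geno_path}: {calls.shape[1]} SNP lines for {len(snps)} "
            "SNP-table entries")
    calls[calls == 9] = MISSING
    return GenotypeMatrix(calls, snps, individuals)


def write_eigenstrat(g: GenotypeMatrix, geno_path, snp_path, ind_path) -> None:
    codes = g.calls.astype(np.int16).copy()
    codes[codes == MISSING] = 9
    with open(geno_path, "w") as fh:
        for j in range(g.n_snps):
            fh.write("".join(map(str, codes[:, j])) + "\n")
    with open(snp_path, "w") as fh:
        for r in g.snps.itertuples(index=False):
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.genetic_pos:.6f}\t"
                     f"{r.physical_pos}\t{r.allele_ref}\t{r.allele_alt}\n")
    with open(ind_path, "w") as fh:
        for r in g.individuals.itertuples(index=False):
            fh.write(f"{r.ind_id}\t{_SEX_TO_CODE[r.sex]}\t{r.population}\t"
                     f"{r.era}\t{r.ploidy_mode}\n")


# ---------------------------------------------------------------------------
# PLINK text import
# ---------------------------------------------------------------------------

def import_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Import a PLINK .ped/.map pair as alternative-allele counts.

    Only biallelic sites are accepted.  Per site the major observed allele
    is taken as reference and the minor as alternative (alphabetic
    tie-break); a monomorphic site receives the first unused nucleotide as
    a placeholder alternative.  A 0/0 genotype is missing.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "genetic_pos", "physical_pos"],
                     dtype={"chrom": str, "snp_id": str})
    n_snps = len(mp)

    ind_ids, pops, sexes = [], [], []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}")
            fid, iid, _pat, _mat, sex_code, _pheno = parts[:6]
            ind_ids.append(iid)
            pops.append(fid)
            sexes.append({"1": "male", "2": "female"}.get(sex_code, "unknown"))
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(ind_ids),
                                                          n_snps, 2)

    refs, alts = [], []
    calls = np.full((len(ind_ids), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :].ravel()
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(
                f"site {mp['snp_id'].iloc[j]} is not biallelic: "
                f"{sorted(uniq)}")
        if len(uniq) == 0:
            ref, alt = "A", "C"
        elif len(uniq) == 1:
            ref = uniq[0]
            alt = next(b for b in "ACGT" if b != ref)
        else:
            order = np.lexsort((uniq, -counts))
            ref, alt = uniq[order[0]], uniq[order[1]]
        refs.append(ref)
        alts.append(alt)
        pair = alleles[:, j, :]
        present = (pair != "0").all(axis=1)
        calls[present, j] = (pair[present] == alt).sum(axis=1)

    all_missing = (calls == MISSING).all(axis=1)
    for iid in np.asarray(ind_ids, dtype=object)[all_missing]:
        logger.warning("individual %s has no called genotypes; retained", iid)

    snps = make_snp_table(mp["snp_id"], mp["chrom"], mp["physical_pos"],
                          mp["genetic_pos"].where(mp["genetic_pos"] > 0),
                          refs, alts)
    individuals = make_individual_table(ind_ids, pops, sex=sexes)
    return GenotypeMatrix(calls, snps, individuals)


# ---------------------------------------------------------------------------
# Q matrix / local ancestry / IBD / pileup tables
# ---------------------------------------------------------------------------

def read_q_matrix(path, indigenous=()) -> QMatrix:
    """Read a whitespace-delimited Q table; header = ind_id + components."""
    df = pd.read_csv(path, sep=r"\s+")
    if df.columns[0] != "ind_id":
        raise FormatError("Q matrix header must start with ind_id")
    comps = list(df.columns[1:])
    return QMatrix(list(df["ind_id"]), comps,
                   df[comps].to_numpy(float), frozenset(indigenous))


def write_q_matrix(q: QMatrix, path) -> None:
    df = pd.DataFrame(q.proportions, columns=q.components)
    df.insert(0, "ind_id", q.individuals)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_local_ancestry(path, ancestries=("IA", "EUR", "AFR")) -> LocalAncestryCalls:
    """Read a long-format local-ancestry TSV.

    Columns: ind_id, hap (0/1), snp_index, viterbi, then post_<ancestry>
    for each ancestry.  Rows must cover every haplotype x SNP slot.
    """
    df = pd.read_csv(path, sep="\t")
    individuals = list(dict.fromkeys(df["ind_id"]))
    ind_pos = {ind: i for i, ind in enumerate(individuals)}
    n_snps = int(df["snp_index"].max()) + 1
    n_hap = 2 * len(individuals)
    vit = np.full((n_hap, n_snps), -1, dtype=np.int8)
    post = np.full((n_hap, n_snps, len(ancestries)), np.nan)
    hap_row = 2 * df["ind_id"].map(ind_pos).to_numpy() + df["hap"].to_numpy()
    snp_idx = df["snp_index"].to_numpy()
    code = {a: i for i, a in enumerate(ancestries)}
    vit[hap_row, snp_idx] = df["viterbi"].map(code).to_numpy()
    for k, anc in enumerate(ancestries):
        post[hap_row, snp_idx, k] = df[f"post_{anc}"].to_numpy()
    if (vit < 0).any() or np.isnan(post).any():
        raise FormatError("local-ancestry table does not cover every slot")
    return LocalAncestryCalls(individuals, tuple(ancestries), vit, post)


def write_local_ancestry(la: LocalAncestryCalls, path) -> None:
    n_hap, n_snps = la.viterbi.shape
    hap = np.tile(np.repeat([0, 1], n_snps), len(la.individuals))
    rows = {
        "ind_id": np.repeat(np.asarray(la.individuals, dtype=object),
                            2 * n_snps),
        "hap": hap,
        "snp_index": np.tile(np.arange(n_snps), n_hap),
        "viterbi": np.asarray(la.ancestries, dtype=object)[
            la.viterbi.ravel()],
    }
    for k, anc in enumerate(la.ancestries):
        rows[f"post_{anc}"] = la.posterior[:, :, k].ravel()
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6f")


def read_ibd_table(path) -> pd.DataFrame:
    return make_ibd_table(pd.read_csv(path, sep="\t"))


def write_ibd_table(df: pd.DataFrame, path) -> None:
    make_ibd_table(df).to_csv(path, sep="\t", index=False,
                              float_format="%.6f")


def read_pileup(path) -> pd.DataFrame:
    return make_pileup(pd.read_csv(path, sep="\t"))


def write_pileup(df: pd.DataFrame, path) -> None:
    make_pileup(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Panel merging
# ---------------------------------------------------------------------------

def merge_on_shared_snps(g1: GenotypeMatrix, g2: GenotypeMatrix,
                         return_report: bool = False):
    """Merge two panels on SNPs shared by (chrom, physical_pos).

    Allele labels are reconciled by flipping counts (0 <-> 2) when the
    second panel lists the pair in reversed ref/alt order.  Strand-ambiguous
    (A/T, C/G) sites and sites with irreconcilable allele pairs are dropped
    and tallied in the report.
    """
    overlap1 = set(g1.individuals["ind_id"]) & set(g2.individuals["ind_id"])
    if overlap1:
        raise FormatError(
            f"panels share individual ids, e.g. {sorted(overlap1)[0]!r}")

    key1 = {(c, p): i for i, (c, p) in
            enumerate(zip(g1.snps["chrom"], g1.snps["physical_pos"]))}
    idx1, idx2, flip = [], [], []
    n_ambiguous = n_mismatch = 0
    for j, (c, p) in enumerate(zip(g2.snps["chrom"], g2.snps["physical_pos"])):
        i = key1.get((c, p))
        if i is None:
            continue
        r1, a1 = g1.snps["allele_ref"].iat[i], g1.snps["allele_alt"].iat[i]
        r2, a2 = g2.snps["allele_ref"].iat[j], g2.snps["allele_alt"].iat[j]
        if frozenset((r1, a1)) in STRAND_AMBIGUOUS_PAIRS:
            n_ambiguous += 1
            continue
        if (r1, a1) == (r2, a2):
            idx1.append(i); idx2.append(j); flip.append(False)
        elif (r1, a1) == (a2, r2):
            idx1.append(i); idx2.append(j); flip.append(True)
        else:
            n_mismatch += 1
            logger.warning("dropping %s: alleles %s/%s vs %s/%s",
                           g1.snps["snp_id"].iat[i], r1, a1, r2, a2)
    if not idx1:
        logger.warning("merge produced an empty SNP intersection")

    idx1 = np.asarray(idx1, dtype=int)
    idx2 = np.asarray(idx2, dtype=int)
    flip = np.asarray(flip, dtype=bool)
    calls2 = g2.calls[:, idx2].copy()
    if flip.any():
        sub = calls2[:, flip]
        flipped = np.where(sub == MISSING, MISSING, 2 - sub)
        calls2[:, flip] = flipped.astype(np.int8)
    merged = GenotypeMatrix(
        np.vstack([g1.calls[:, idx1], calls2]),
        g1.snps.iloc[idx1].reset_index(drop=True),
        pd.concat([g1.individuals, g2.individuals], ignore_index=True),
    )
    report = {"n_shared": int(len(idx1)),
              "n_flipped": int(flip.sum()),
              "n_strand_ambiguous_dropped": n_ambiguous,
              "n_allele_mismatch_dropped": n_mismatch}
    if return_report:
        return merged, report
    return merged


# ---------------------------------------------------------------------------
# Missingness and site-class filters
# ---------------------------------------------------------------------------

def filter_geno_mind(g: GenotypeMatrix, geno_max_missing: float,
                     mind_max_missing: float) -> GenotypeMatrix:
    """PLINK-order missingness filter: sites first, then individuals.

    A site is removed when its missing fraction strictly exceeds
    ``geno_max_missing``; individuals are then re-evaluated on the
    surviving sites against ``mind_max_missing``.
    """
    for t in (geno_max_missing, mind_max_missing):
        if not 0 <= t <= 1:
            raise ValueError(f"threshold {t} outside [0, 1]")
    keep_snps = np.flatnonzero(g.snp_missing_fraction() <= geno_max_missing)
    g2 = g.take_snps(keep_snps)
    keep_inds = np.flatnonzero(
        g2.individual_missing_fraction() <= mind_max_missing)
    out = g2.take_individuals(keep_inds)
    logger.info("filter_geno_mind removed %d SNPs and %d individuals",
                g.n_snps - out.n_snps, g.n_individuals - out.n_individuals)
    return out


def min_snp_filter(g: GenotypeMatrix, min_snps: int) -> GenotypeMatrix:
    """Drop individuals with fewer than ``min_snps`` non-missing calls."""
    if min_snps < 0:
        raise ValueError("min_snps must be >= 0")
    n_called = (~g.missing_mask).sum(axis=1)
    return g.take_individuals(np.flatnonzero(n_called >= min_snps))


def snp_subset(g: GenotypeMatrix,
               mode: str = "all") -> GenotypeMatrix:
    """Restrict to a deamination-robust SNP class.

    ``no_CT_GA`` removes sites whose allele pair is {C,T} or {G,A};
    ``transversions_only`` keeps only transversion pairs.  For biallelic
    sites the two rules select identical panels; both names are kept
    because both appear in standard aDNA workflows.
    """
    if mode == "all":
        return g.take_snps(np.arange(g.n_snps))
    pairs = g.allele_pairs()
    if mode in ("no_CT_GA", "transversions_only"):
        # for biallelic SNPs the only transitions are {C,T} and {G,A}, so
        # removing those pairs and keeping transversions select the same set
        keep = [p not in TRANSITION_PAIRS for p in pairs]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return g.take_snps(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(window: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared genotype correlation for a SNP window.

    ``window`` is individuals x SNPs with NaN at missing calls.
    """
    obs = ~np.isnan(window)
    z = np.where(obs, window, 0.0)
    n = obs.T.astype(float) @ obs
    sx = z.T @ obs
    sxx = (z * z).T @ obs
    sxy = z.T @ z
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_x = sxx / n - (sx / n) ** 2
        r2 = cov ** 2 / (var_x * var_x.T)
    r2[~np.isfinite(r2)] = 0.0  # zero-variance or empty overlap
    return r2


def ld_prune(g: GenotypeMatrix, window_snps: int = 200, step_snps: int = 25,
             r2_max: float = 0.4) -> list:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` style).

    Within each window the later SNP of any pair with r^2 above ``r2_max``
    is removed; the window then slides by ``step_snps``.  Returns the kept
    snp_ids, deterministically given input order.
    """
    dosage = g.dosage()
    removed = np.zeros(g.n_snps, dtype=bool)
    chrom_codes = g.snps["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_codes):
        cols = np.flatnonzero(chrom_codes == chrom)
        start = 0
        while start < len(cols):
            win = cols[start:start + window_snps]
            active = win[~removed[win]]
            if len(active) > 1:
                r2 = _pairwise_r2(dosage[:, active])
                for a in range(len(active)):
                    if removed[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if removed[active[b]]:
                            continue
                        if r2[a, b] > r2_max:
                            removed[active[b]] = True
            if start + window_snps >= len(cols):
                break
            start += step_snps
    return list(g.snps["snp_id"].to_numpy()[~removed])
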