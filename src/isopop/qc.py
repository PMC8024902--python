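"""Ancient- and modern-sample quality control.

Covers the read-level validation battery applied to low-coverage ancient
genomes — random-read pseudo-haploid calling, downsampling, terminal
deamination profiles, molecular-decay fits, derived-allele error excess,
read-count molecular sexing (Ry and Rx), mitochondrial contamination from
non-consensus calls, window-mismatch (READ-style) and KING-robust kinship,
and damage-aware Y-haplogroup classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (MISSING, TRANSITION_PAIRS, GenotypeMatrix,
                         make_individual_table, make_pileup)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pseudo-haploid calling and downsampling
# ---------------------------------------------------------------------------

def pseudo_haploid_call(pileup: pd.DataFrame, snps: pd.DataFrame,
                        min_baseq: int = 20, min_mapq: int = 30,
                        seed: int = 0) -> GenotypeMatrix:
    """Random-read haploid genotypes: one surviving read per SNP, coded
    0 (reference) or 2 (alternative); no read leaves the site missing.

    Reads failing the base/mapping quality thresholds or matching neither
    allele are discarded before the uniform draw.
    """
    rng = np.random.default_rng(seed)
    snp_pos = {s: i for i, s in enumerate(snps["snp_id"])}
    ref = snps["allele_ref"].to_numpy(dtype=object)
    alt = snps["allele_alt"].to_numpy(dtype=object)

    ind_ids = list(dict.fromkeys(pileup["ind_id"]))
    ind_pos = {ind: i for i, ind in enumerate(ind_ids)}
    calls = np.full((len(ind_ids), len(snps)), MISSING, dtype=np.int8)

    df = pileup[(pileup["baseq"] >= min_baseq)
                & (pileup["mapq"] >= min_mapq)].copy()
    df = df[df["snp_id"].isin(snp_pos)]
    snp_idx = df["snp_id"].map(snp_pos).to_numpy()
    base = df["base"].to_numpy(dtype=object)
    is_ref = base == ref[snp_idx]
    is_alt = base == alt[snp_idx]
    keep = is_ref | is_alt
    df = df.assign(_snp=snp_idx, _alt=is_alt,
                   _prio=rng.random(len(df)))[keep]
    chosen = df.loc[df.groupby(["ind_id", "_snp"])["_prio"].idxmax()]
    rows = chosen["ind_id"].map(ind_pos).to_numpy()
    calls[rows, chosen["_snp"].to_numpy()] = np.where(
        chosen["_alt"].to_numpy(), 2, 0)

    individuals = make_individual_table(
        ind_ids, ["ancient"] * len(ind_ids), era=["ancient"] * len(ind_ids),
        ploidy_mode=["pseudo_haploid"] * len(ind_ids))
    return GenotypeMatrix(calls, snps, individuals)


def downsample_pileup(pileup: pd.DataFrame, target_coverage: float,
                      n_snps: int,
                      rng: Optional[np.random.Generator] = None,
                      seed: int = 0) -> pd.DataFrame:
    """Thin reads to ``target_coverage`` by independent retention.

    Retention probability is target over the individual's current mean
    coverage (reads per SNP), capped at one.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    parts = []
    for ind, sub in pileup.groupby("ind_id", sort=False):
        current = len(sub) / n_snps
        p = 1.0 if current <= target_coverage else target_coverage / current
        parts.append(sub[rng.random(len(sub)) < p] if p < 1.0 else sub)
    return make_pileup(pd.concat(parts, ignore_index=True) if parts
                       else pileup)


# ---------------------------------------------------------------------------
# Damage and decay diagnostics
# ---------------------------------------------------------------------------

def damage_profile(pileup: pd.DataFrame, snps: pd.DataFrame,
                   n_positions: int = 10) -> pd.DataFrame:
    """Empirical terminal-deamination rates by read offset.

    C->T rates are tallied at reference-C sites whose alternative allele is
    not T (so polymorphism cannot mimic damage), by distance from the 5'
    end; G->A symmetrically from the 3' end.  The rate at each offset is
    T reads over C-plus-T reads (alternative-allele reads are excluded
    from the denominator, as when counting mismatches to a reference).
    """
    ref = dict(zip(snps["snp_id"], snps["allele_ref"]))
    alt = dict(zip(snps["snp_id"], snps["allele_alt"]))
    r = pileup["snp_id"].map(ref)
    a = pileup["snp_id"].map(alt)
    pos5 = pileup["pos_in_read"].to_numpy()
    pos3 = (pileup["read_len"] - pileup["pos_in_read"] + 1).to_numpy()
    base = pileup["base"].to_numpy(dtype=object)

    ct_site = (r == "C") & (a != "T")
    ga_site = (r == "G") & (a != "A")
    rows = []
    for offset in range(1, n_positions + 1):
        sel5 = ct_site.to_numpy() & (pos5 == offset) & np.isin(base,
                                                               ("C", "T"))
        sel3 = ga_site.to_numpy() & (pos3 == offset) & np.isin(base,
                                                               ("G", "A"))
        n5 = int(sel5.sum())
        n3 = int(sel3.sum())
        rows.append({
            "offset": offset,
            "ct_rate": float((base[sel5] == "T").mean()) if n5 else np.nan,
            "ct_n": n5,
            "ga_rate": float((base[sel3] == "A").mean()) if n3 else np.nan,
            "ga_n": n3,
        })
    return pd.DataFrame(rows)


def molecular_decay(read_lengths, min_length: Optional[int] = None) -> dict:
    """Geometric maximum-likelihood fit of the read-length distribution.

    Returns the per-base decay constant lambda and the mean length; the
    shifted-geometric MLE is 1 / (mean - L0 + 1) with L0 the shortest
    retained length.  A degenerate (constant) length distribution returns
    lambda 0 with a warning.
    """
    lengths = np.asarray(list(read_lengths), dtype=float)
    if min_length is not None:
        lengths = lengths[lengths >= min_length]
    if lengths.size == 0:
        raise ValueError("no read lengths to fit")
    mean = float(lengths.mean())
    if np.ptp(lengths) == 0:
        logger.warning("constant read lengths: decay fit is degenerate")
        return {"lambda": 0.0, "mean_length": mean, "n_reads": lengths.size}
    L0 = float(lengths.min())
    lam = 1.0 / (mean - L0 + 1.0)
    return {"lambda": lam, "mean_length": mean, "n_reads": lengths.size}


def error_rate_excess(target: np.ndarray, error_free: np.ndarray,
                      outgroup: np.ndarray) -> float:
    """Excess derived-allele fraction of an ancient genome.

    The outgroup genotype polarizes each site (homozygous calls only);
    the statistic is the derived-allele fraction of the target minus that
    of the error-free reference genome over sites non-missing in all
    three.  All present-day humans carry equal derived fractions, so a
    positive excess indicates sequencing or damage error.
    """
    target = np.asarray(target)
    error_free = np.asarray(error_free)
    outgroup = np.asarray(outgroup)
    usable = ((target != MISSING) & (error_free != MISSING)
              & np.isin(outgroup, (0, 2)))
    if not usable.any():
        raise ValueError("no sites overlap across target, reference "
                         "and outgroup")
    anc_is_ref = outgroup[usable] == 0

    def derived_fraction(row):
        dos = row[usable] / 2.0
        return float(np.where(anc_is_ref, dos, 1.0 - dos).mean())

    return derived_fraction(target) - derived_fraction(error_free)


# ---------------------------------------------------------------------------
# Molecular sex
# ---------------------------------------------------------------------------

@dataclass
class SexCallResult:
    ind_id: str
    ry: float
    ry_ci: tuple
    rx: float
    rx_ci: tuple
    call: str


def sex_determination(read_counts: pd.Series, chrom_lengths: dict,
                      ind_id: str = "", min_sex_reads: int = 100,
                      ry_female_max: float = 0.016,
                      ry_male_min: float = 0.075,
                      rx_male_max: float = 0.6,
                      rx_female_min: float = 0.8) -> SexCallResult:
    """Molecular sex from shotgun read counts via Ry and Rx.

    Ry = nY / (nX + nY) with a normal-approximation CI; a CI entirely
    below ``ry_female_max`` is female, entirely above ``ry_male_min`` is
    male.  Rx averages, over autosomes, the X-alignment rate relative to
    each autosome's rate (1 expected for XX, 0.5 for XY) with a CI from
    the spread across autosomes; below ``rx_male_max`` male, above
    ``rx_female_min`` female.  Disagreement yields "inconsistent"; too
    few sex-chromosome reads yields "insufficient".
    """
    n_x = float(read_counts.get("X", 0))
    n_y = float(read_counts.get("Y", 0))
    n_sex = n_x + n_y
    if n_sex < min_sex_reads:
        return SexCallResult(ind_id, np.nan, (np.nan, np.nan), np.nan,
                             (np.nan, np.nan), "insufficient")
    ry = n_y / n_sex
    half = 1.96 * np.sqrt(max(ry * (1 - ry), 1e-12) / n_sex)
    ry_ci = (ry - half, ry + half)
    if ry_ci[1] < ry_female_max:
        ry_call = "female"
    elif ry_ci[0] > ry_male_min:
        ry_call = "male"
    else:
        ry_call = None

    autosomes = [c for c in read_counts.index if c not in ("X", "Y")]
    x_rate = n_x / chrom_lengths["X"]
    ratios = np.array([
        x_rate / (read_counts[c] / chrom_lengths[c])
        for c in autosomes if read_counts[c] > 0])
    rx = float(ratios.mean())
    spread = 1.96 * ratios.std(ddof=1) / np.sqrt(len(ratios))
    rx_ci = (rx - spread, rx + spread)
    if rx_ci[1] < rx_male_max:
        rx_call = "male"
    elif rx_ci[0] > rx_female_min:
        rx_call = "female"
    else:
        rx_call = None

    if ry_call and rx_call:
        call = ry_call if ry_call == rx_call else "inconsistent"
    else:
        call = ry_call or rx_call or "inconsistent"
    return SexCallResult(ind_id, ry, ry_ci, rx, rx_ci, call)


# ---------------------------------------------------------------------------
# Mitochondrial contamination (non-consensus fraction)
# ---------------------------------------------------------------------------

def mtdna_contamination_fraction(consensus: dict, pileup: pd.DataFrame,
                                 min_baseq: int = 20,
                                 alpha: float = 0.05) -> dict:
    """Pooled non-consensus base fraction at haplogroup-diagnostic sites.

    ``consensus`` maps diagnostic position ids to the consensus base.
    Returns the point estimate with a Clopper-Pearson binomial CI.
    """
    df = pileup[(pileup["baseq"] >= min_baseq)
                & pileup["snp_id"].isin(consensus)]
    n = len(df)
    if n == 0:
        raise ValueError("no covered diagnostic positions")
    mismatch = int((df["base"].to_numpy(dtype=object)
                    != df["snp_id"].map(consensus).to_numpy(dtype=object))
                   .sum())
    lo = stats.beta.ppf(alpha / 2, mismatch, n - mismatch + 1) \
        if mismatch > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, mismatch + 1, n - mismatch) \
        if mismatch < n else 1.0
    return {"fraction": mismatch / n, "ci": (float(lo), float(hi)),
            "n_bases": n, "n_mismatch": mismatch}


# ---------------------------------------------------------------------------
# Reference bias
# ---------------------------------------------------------------------------

def reference_bias_check(g: GenotypeMatrix) -> dict:
    """Mean alternative-allele proportion per individual under the three
    deamination-robust SNP subsets, with a modern-vs-ancient rank-sum test
    per subset."""
    from .io_formats import snp_subset

    results = {}
    tables = []
    for mode in ("all", "no_CT_GA", "transversions_only"):
        sub = snp_subset(g, mode)
        dos = sub.dosage()
        with np.errstate(invalid="ignore"):
            prop = np.nanmean(dos, axis=1) / 2.0
        all_missing = np.isnan(prop)
        for ind in sub.individuals["ind_id"].to_numpy()[all_missing]:
            logger.warning("individual %s has no calls in mode %s; excluded",
                           ind, mode)
        tables.append(pd.DataFrame({
            "ind_id": sub.individuals["ind_id"],
            "era": sub.individuals["era"],
            "mode": mode,
            "alt_proportion": prop,
        }))
        era = sub.individuals["era"].to_numpy()
        modern = prop[(era == "modern") & ~all_missing]
        ancient = prop[(era == "ancient") & ~all_missing]
        if len(modern) and len(ancient):
            stat, p = stats.mannwhitneyu(modern, ancient,
                                         alternative="two-sided")
            results[mode] = {"statistic": float(stat), "p_value": float(p)}
        else:
            results[mode] = {"statistic": np.nan, "p_value": np.nan}
    return {"per_individual": pd.concat(tables, ignore_index=True),
            "tests": results}


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipResult:
    pair: tuple
    statistic: str
    value: float
    classification: str


#: READ's published normalized-P0 class boundaries
READ_CUTOFFS = {"identical": 0.625, "first_degree": 0.8125,
                "second_degree": 0.90625}


def _read_classify(score: float) -> str:
    if score < READ_CUTOFFS["identical"]:
        return "identical"
    if score < READ_CUTOFFS["first_degree"]:
        return "first_degree"
    if score < READ_CUTOFFS["second_degree"]:
        return "second_degree"
    return "unrelated"


def read_kinship(g: GenotypeMatrix, pairs: Optional[list] = None,
                 window_size_bp: int = 1_000_000,
                 min_windows: int = 5) -> list:
    """Window-mismatch kinship for pseudo-haploid pairs (READ-style).

    P0 is the pairwise mismatch fraction in non-overlapping physical
    windows; each pair's mean P0 is normalized by the median across all
    pairs (so a cohort dominated by unrelated pairs scores ~1) and
    classified with READ's default cutoffs.
    """
    ind_ids = list(g.individuals["ind_id"])
    idx = {ind: i for i, ind in enumerate(ind_ids)}
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ind_ids)
                 for b in ind_ids[i + 1:]]
    window = (g.snps["chrom"].astype(str) + ":"
              + (g.snps["physical_pos"] // window_size_bp).astype(str))
    win_codes = pd.factorize(window)[0]
    n_windows = win_codes.max() + 1

    mean_p0 = {}
    for a, b in pairs:
        ca, cb = g.calls[idx[a]], g.calls[idx[b]]
        both = (ca != MISSING) & (cb != MISSING)
        mism = both & (ca != cb)
        n_per = np.bincount(win_codes[both], minlength=n_windows)
        m_per = np.bincount(win_codes[mism], minlength=n_windows)
        ok = n_per > 0
        if ok.sum() < min_windows:
            mean_p0[(a, b)] = np.nan
            continue
        mean_p0[(a, b)] = float((m_per[ok] / n_per[ok]).mean())

    valid = [v for v in mean_p0.values() if np.isfinite(v)]
    results = []
    if len(valid) < 2:
        logger.warning("READ normalization degenerate with %d scored "
                       "pair(s); reporting raw P0", len(valid))
        for pair, p0 in mean_p0.items():
            results.append(KinshipResult(pair, "READ_P0_raw", p0, "no_call"))
        return results
    median = float(np.median(valid))
    for pair, p0 in mean_p0.items():
        if not np.isfinite(p0):
            results.append(KinshipResult(pair, "READ_P0_normalized",
                                         np.nan, "no_call"))
            continue
        score = p0 / median
        results.append(KinshipResult(pair, "READ_P0_normalized", score,
                                     _read_classify(score)))
    return results


def king_kinship_matrix(g: GenotypeMatrix, ind_index: np.ndarray
                        ) -> np.ndarray:
    """KING-robust kinship from het concordance and opposite homozygotes."""
    calls = g.calls[ind_index]
    n = len(ind_index)
    phi = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            ci, cj = calls[i], calls[j]
            both = (ci != MISSING) & (cj != MISSING)
            het_i = int(((ci == 1) & both).sum())
            het_j = int(((cj == 1) & both).sum())
            het_both = int(((ci == 1) & (cj == 1) & both).sum())
            opp_hom = int((((ci == 0) & (cj == 2))
                           | ((ci == 2) & (cj == 0))).sum())
            denom = het_i + het_j
            if denom == 0:
                continue
            phi[i, j] = phi[j, i] = (het_both - 2 * opp_hom) / denom
    return phi


def king_kinship(g: GenotypeMatrix, percentile: float = 97.5) -> dict:
    """Within-population KING-robust kinship with percentile exclusion.

    Pairs above their population's ``percentile`` kinship threshold are
    flagged; from each flagged pair the member with more missing SNPs is
    excluded, iterating until no flagged pair remains among retained
    individuals.  This accommodates the elevated background relatedness of
    isolated, endogamous populations.
    """
    results, excluded = [], []
    missing = g.missing_mask.sum(axis=1)
    for pop in dict.fromkeys(g.individuals["population"]):
        idx = g.population_indices(pop)
        if len(idx) < 2:
            continue
        ids = g.individuals["ind_id"].to_numpy()[idx]
        phi = king_kinship_matrix(g, idx)
        iu = np.triu_indices(len(idx), k=1)
        values = phi[iu]
        threshold = float(np.nanpercentile(values, percentile))
        for a, b, v in zip(iu[0], iu[1], values):
            results.append(KinshipResult(
                (ids[a], ids[b]), "KING_kinship", float(v),
                "flagged" if v > threshold else "retained"))
        active = set(range(len(idx)))
        while True:
            flagged = [(a, b) for a, b in zip(*iu)
                       if a in active and b in active
                       and phi[a, b] > threshold]
            if not flagged:
                break
            a, b = max(flagged, key=lambda p: phi[p[0], p[1]])
            drop = a if missing[idx[a]] >= missing[idx[b]] else b
            active.discard(drop)
            excluded.append(ids[drop])
    return {"results": results, "excluded": excluded}


# ---------------------------------------------------------------------------
# Damage-aware Y-haplogroup classification
# ---------------------------------------------------------------------------

@dataclass
class YClassification:
    haplogroup: Optional[str]
    tentative: Optional[str]
    status: pd.DataFrame
    conflicts: list


def y_haplogroup_classify(calls: pd.DataFrame, panel: pd.DataFrame,
                          damage_aware: bool = True) -> YClassification:
    """Assign the deepest haplogroup branch supported by clean calls.

    Every call at a {C,T} or {G,A} marker is damage-ambiguous when
    ``damage_aware`` (post-mortem deamination can flip either state);
    assignment requires at least one non-ambiguous derived call on the
    node itself and tolerates no non-ambiguous ancestral call on the
    root-to-node path.  Branches supported only by ambiguous derived
    calls extend the assignment tentatively.
    """
    parent = dict(zip(panel["branch"], panel["parent"]))
    children = {}
    for b, p in parent.items():
        children.setdefault(p, set()).add(b)

    info = panel.set_index("marker")
    status_rows = []
    derived_clean, derived_amb, ancestral_clean = set(), set(), set()
    for r in calls.itertuples(index=False):
        if r.marker not in info.index:
            continue
        rec = info.loc[r.marker]
        pair = frozenset((rec["ancestral"], rec["derived"]))
        ambiguous = damage_aware and pair in TRANSITION_PAIRS
        if r.allele == rec["derived"]:
            state = "derived"
            (derived_amb if ambiguous else derived_clean).add(rec["branch"])
        elif r.allele == rec["ancestral"]:
            state = "ancestral"
            if not ambiguous:
                ancestral_clean.add(rec["branch"])
        else:
            state = "no_call"
        status_rows.append({"marker": r.marker, "branch": rec["branch"],
                            "state": state, "damage_ambiguous": ambiguous})
    status = pd.DataFrame(status_rows, columns=["marker", "branch", "state",
                                                "damage_ambiguous"])
    if not (derived_clean | derived_amb):
        return YClassification(None, None, status, [])

    def path(branch):
        out = []
        while branch in parent:
            out.append(branch)
            branch = parent[branch]
        return out[::-1]  # root-most first

    def consistent(branch):
        return [b for b in path(branch) if b in ancestral_clean]

    best, best_depth, conflicts = None, -1, []
    for branch in derived_clean:
        p = path(branch)
        bad = consistent(branch)
        if bad:
            conflicts.append({"branch": branch, "ancestral_on_path": bad})
            # back off to the nearest ancestor whose path is clean
            p = [b for b in p if b not in bad]
            p = p[:next((i for i, b in enumerate(p)
                         if consistent(b)), len(p))]
            candidates = [b for b in p if b in derived_clean
                          and not consistent(b)]
            if not candidates:
                continue
            branch, p = candidates[-1], path(candidates[-1])
        if len(p) > best_depth:
            best, best_depth = branch, len(p)

    tentative = None
    if best is not None:
        frontier = best
        while True:
            deeper = [c for c in children.get(frontier, ())
                      if c in derived_amb and not consistent(c)]
            if not deeper:
                break
            frontier = sorted(deeper)[0]
        tentative = frontier if frontier != best else None
    elif derived_amb:
        tentative = max((b for b in derived_amb if not consistent(b)),
                        key=lambda b: len(path(b)), default=None)
    return YClassification(best, tentative, status, conflicts)
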