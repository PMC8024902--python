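"""Nearly-unadmixed panel construction and local-ancestry masking.

Colonial-era European and African admixture pervades modern Indigenous
American genomes; pre-colonial analyses therefore select individuals by
three independent screens — a global ancestry-proportion threshold
(ADMIXTURE-style Q matrix), an f4 test against European/African sources,
and a genome-wide local-ancestry fraction — whose positive results are
merged by intersection.  For everyone else, non-Indigenous haplotype
segments are masked to missing and masked haplotypes are retained only
when enough of the genome survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (MISSING, GenotypeMatrix, LocalAncestryCalls,
                         QMatrix, make_individual_table)
from .fstats import BlockDefinition, f4, population_frequencies

Q_MIN_TOTAL = 0.95        # "more than 95% Indigenous components"
LA_MAX_NON_IA = 0.05      # "less than 5% of non-IA ancestry"
STRICT_CAPS = {"AFR": 0.01, "EUR": 0.02}   # strict-panel per-ancestry caps
POSTERIOR_MIN = 0.9       # masking posterior threshold
F4_Z_MAX = 3.0            # colonial-admixture screen
F4_Z_MAX_STRICT = 2.0


@dataclass
class FilterDecision:
    ind_id: str
    filter_name: str
    passed: Optional[bool]      # None = undecided (insufficient data)
    values: dict


def q_threshold_filter(q: QMatrix,
                       min_total: float = Q_MIN_TOTAL) -> list:
    """Pass individuals whose Indigenous components sum strictly above
    ``min_total``."""
    frac = q.indigenous_fraction()
    return [FilterDecision(ind, "Q_threshold", bool(v > min_total),
                           {"indigenous_fraction": float(v)})
            for ind, v in frac.items()]


def f4_colonial_filter(g: GenotypeMatrix, candidates, ancient_indigenous: str,
                       europe_pop: str, africa_pop: str, outgroup: str,
                       blocks: BlockDefinition, z_max: float = F4_Z_MAX,
                       min_snps: int = 10_000) -> list:
    """Screen each candidate X with f4(ancientIndigenous, X; source, outgroup)
    for the European and African sources.

    A candidate passes when |Z| < ``z_max`` for both sources; candidates
    with fewer than ``min_snps`` informative SNPs in either test are
    undecided and excluded with a reason.  The strict panel uses
    ``z_max = 2``.

    ``candidates`` is a list of ind_ids, or a mapping of candidate name
    to the ind_ids carrying its data (e.g. the two masked haplotypes of
    one individual).
    """
    if not isinstance(candidates, dict):
        candidates = {ind: [ind] for ind in candidates}
    grouping = {pop: list(sub["ind_id"]) for pop, sub in
                g.individuals.groupby("population", sort=False)
                if pop in (ancient_indigenous, europe_pop, africa_pop,
                           outgroup)}
    for ind, members in candidates.items():
        grouping[f"__ind__{ind}"] = list(members)
    pf = population_frequencies(g, grouping)

    decisions = []
    for ind in candidates:
        values = {}
        ok = True
        undecided = False
        for label, source in (("europe", europe_pop), ("africa", africa_pop)):
            r = f4(pf, ancient_indigenous, f"__ind__{ind}", source,
                   outgroup, blocks)
            values[f"z_{label}"] = r.z
            values[f"n_snps_{label}"] = r.n_snps
            if r.n_snps < min_snps:
                undecided = True
            elif abs(r.z) >= z_max:
                ok = False
        if undecided:
            values["reason"] = f"fewer than {min_snps} overlapping SNPs"
            decisions.append(FilterDecision(ind, "f4_colonial", None, values))
        else:
            decisions.append(FilterDecision(ind, "f4_colonial", ok, values))
    return decisions


def local_ancestry_filter(la: LocalAncestryCalls,
                          max_non_ia: float = LA_MAX_NON_IA,
                          per_ancestry_caps: Optional[dict] = None,
                          ia_label: str = "IA") -> list:
    """Pass individuals by genome-wide non-Indigenous Viterbi fraction.

    The default rule passes when the fraction of haplotype-SNP slots not
    labelled Indigenous is strictly below ``max_non_ia``; the strict
    variant instead caps each non-Indigenous ancestry separately
    (e.g. under 1% African and under 2% European).
    """
    ia = la.ancestry_code(ia_label)
    decisions = []
    for i, ind in enumerate(la.individuals):
        vit = la.viterbi[2 * i:2 * i + 2]
        values = {
            anc: float((vit == k).mean())
            for k, anc in enumerate(la.ancestries)}
        if per_ancestry_caps is None:
            passed = float((vit != ia).mean()) < max_non_ia
            values["non_ia_fraction"] = float((vit != ia).mean())
        else:
            passed = all(values[anc] < cap
                         for anc, cap in per_ancestry_caps.items())
        decisions.append(FilterDecision(ind, "local_ancestry", bool(passed),
                                        values))
    return decisions


def stepwise_merge(*decision_lists) -> dict:
    """Intersect the positive results of the independent screens.

    Returns panel membership plus an audit table showing every
    individual's outcome under each filter (undecided counts as failed).
    """
    audit = {}
    for decisions in decision_lists:
        for d in decisions:
            audit.setdefault(d.ind_id, {})[d.filter_name] = d.passed
    rows = []
    members = []
    filter_names = [dl[0].filter_name for dl in decision_lists if dl]
    for ind, outcomes in audit.items():
        ok = all(outcomes.get(f) is True for f in filter_names)
        rows.append({"ind_id": ind, **{f: outcomes.get(f)
                                       for f in filter_names},
                     "selected": ok})
        if ok:
            members.append(ind)
    return {"members": members,
            "audit": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_genotypes(haplotypes: np.ndarray, la: LocalAncestryCalls,
                   posterior_min: float = POSTERIOR_MIN,
                   ia_label: str = "IA",
                   conjunction: bool = True) -> dict:
    """Mask non-Indigenous haplotype alleles to missing.

    A haplotype-SNP slot is masked when the Viterbi label is not
    Indigenous AND the Indigenous posterior falls below
    ``posterior_min`` (the published rule); ``conjunction=False`` masks
    when either condition holds.  Returns the masked haplotypes (-1 at
    masked slots) and the per-individual masked fraction.
    """
    haplotypes = np.asarray(haplotypes)
    if haplotypes.shape != la.viterbi.shape:
        raise ValueError(
            f"haplotype grid {haplotypes.shape} does not match "
            f"local-ancestry grid {la.viterbi.shape}")
    ia = la.ancestry_code(ia_label)
    non_ia = la.viterbi != ia
    low_post = la.posterior[:, :, ia] < posterior_min
    mask = (non_ia & low_post) if conjunction else (non_ia | low_post)
    masked = np.where(mask, -1, haplotypes).astype(np.int8)
    frac = pd.Series(
        mask.reshape(len(la.individuals), -1).mean(axis=1),
        index=la.individuals, name="masked_fraction")
    return {"haplotypes": masked, "masked_fraction": frac}


def masked_retention_filter(masked_haplotypes: np.ndarray,
                            individuals: list,
                            max_mean_missing: float = 0.5,
                            min_retained_per_hap: float = 0.25) -> dict:
    """Keep individuals whose masked haplotypes retain enough genome:
    mean missingness of the two haplotypes at most ``max_mean_missing``
    and at least ``min_retained_per_hap`` of SNPs present in each."""
    masked_haplotypes = np.asarray(masked_haplotypes)
    miss = (masked_haplotypes == -1).mean(axis=1).reshape(-1, 2)
    mean_ok = miss.mean(axis=1) <= max_mean_missing
    per_hap_ok = (1.0 - miss >= min_retained_per_hap).all(axis=1)
    table = pd.DataFrame({
        "ind_id": individuals,
        "missing_hap0": miss[:, 0],
        "missing_hap1": miss[:, 1],
        "retained": mean_ok & per_hap_ok,
    })
    return {"retained": [i for i, ok in zip(individuals, mean_ok & per_hap_ok)
                         if ok],
            "table": table}


def haplotypes_to_pseudo_haploid(haplotypes: np.ndarray, snps: pd.DataFrame,
                                 individuals: list,
                                 population: str = "Masked"
                                 ) -> GenotypeMatrix:
    """Expose phased (possibly masked) haplotypes as pseudo-haploid
    samples, one row per haplotype, for frequency-based statistics."""
    haplotypes = np.asarray(haplotypes)
    calls = np.where(haplotypes == -1, MISSING, 2 * haplotypes).astype(np.int8)
    ids = [f"{ind}_h{h}" for ind in individuals for h in (0, 1)]
    table = make_individual_table(
        ids, [population] * len(ids), era=["modern"] * len(ids),
        ploidy_mode=["pseudo_haploid"] * len(ids))
    return GenotypeMatrix(calls, snps, table)
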