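"""Core in-memory containers for genotype panels and their companion tables.

The genotype matrix follows the EIGENSTRAT orientation (individuals x SNPs)
with alternative-allele dosage codes 0/1/2 and ``-1`` for missing.  Ancient,
pseudo-haploid individuals carry only {0, 2, -1}: a single sampled read is
reported as a homozygous haploid call, the convention used by random-read
("haplocall") genotyping of low-coverage ancient genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
NUCLEOTIDES = frozenset("ACGT")

#: allele pairs that cannot be distinguished by a deamination artifact check
TRANSITION_PAIRS = (frozenset("CT"), frozenset("GA"))
#: allele pairs unresolvable across strand flips at merge time
STRAND_AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))

SNP_COLUMNS = ["snp_id", "chrom", "physical_pos", "genetic_pos",
               "allele_ref", "allele_alt"]
IND_COLUMNS = ["ind_id", "population", "sex", "era", "ploidy_mode"]


class FormatError(ValueError):
    """Raised when an on-disk table violates its format contract."""


def make_snp_table(snp_id, chrom, physical_pos, genetic_pos=None,
                   allele_ref=None, allele_alt=None) -> pd.DataFrame:
    """Assemble a validated SNP table.

    When ``genetic_pos`` is omitted it is interpolated at 1 cM/Mb from the
    physical position, the conventional fallback for array panels without a
    fine-scale map.
    """
    physical_pos = np.asarray(physical_pos, dtype=np.int64)
    if genetic_pos is None:
        genetic_pos = physical_pos / 1e6
    df = pd.DataFrame({
        "snp_id": np.asarray(snp_id, dtype=object),
        "chrom": np.asarray(chrom, dtype=object),
        "physical_pos": physical_pos,
        "genetic_pos": np.asarray(genetic_pos, dtype=float),
        "allele_ref": np.asarray(allele_ref, dtype=object),
        "allele_alt": np.asarray(allele_alt, dtype=object),
    })
    validate_snp_table(df)
    return df


def validate_snp_table(df: pd.DataFrame) -> None:
    if list(df.columns) != SNP_COLUMNS:
        raise FormatError(f"SNP table columns must be {SNP_COLUMNS}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"duplicate snp_id {dup!r}")
    for col in ("allele_ref", "allele_alt"):
        bad = ~df[col].isin(NUCLEOTIDES)
        if bad.any():
            raise FormatError(f"{col} contains non-ACGT symbol "
                              f"{df.loc[bad, col].iloc[0]!r}")
    if (df["allele_ref"] == df["allele_alt"]).any():
        raise FormatError("monomorphic allele pair (ref == alt)")
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["physical_pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise FormatError(
                f"physical positions not strictly increasing on chrom {chrom}")


def make_individual_table(ind_id, population, sex=None, era=None,
                          ploidy_mode=None) -> pd.DataFrame:
    n = len(ind_id)
    if sex is None:
        sex = ["unknown"] * n
    if era is None:
        era = ["modern"] * n
    if ploidy_mode is None:
        # ancient samples default to pseudo-haploid random-read calls
        ploidy_mode = ["pseudo_haploid" if e == "ancient" else "diploid"
                       for e in era]
    df = pd.DataFrame({
        "ind_id": np.asarray(ind_id, dtype=object),
        "population": np.asarray(population, dtype=object),
        "sex": np.asarray(sex, dtype=object),
        "era": np.asarray(era, dtype=object),
        "ploidy_mode": np.asarray(ploidy_mode, dtype=object),
    })
    validate_individual_table(df)
    return df


def validate_individual_table(df: pd.DataFrame) -> None:
    if list(df.columns) != IND_COLUMNS:
        raise FormatError(f"individual table columns must be {IND_COLUMNS}")
    if df["ind_id"].duplicated().any():
        dup = df.loc[df["ind_id"].duplicated(), "ind_id"].iloc[0]
        raise FormatError(f"duplicate ind_id {dup!r}")
    if not df["sex"].isin({"male", "female", "unknown"}).all():
        raise FormatError("sex must be male/female/unknown")
    if not df["era"].isin({"modern", "ancient"}).all():
        raise FormatError("era must be modern/ancient")
    if not df["ploidy_mode"].isin({"diploid", "pseudo_haploid"}).all():
        raise FormatError("ploidy_mode must be diploid/pseudo_haploid")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of alternative-allele counts.

    ``calls`` is an int8 array with entries in {0, 1, 2, MISSING}.  Rows of
    pseudo-haploid individuals may contain only {0, 2, MISSING}.
    """

    calls: np.ndarray
    snps: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs")
        self.validate()

    def validate(self) -> None:
        validate_snp_table(self.snps)
        validate_individual_table(self.individuals)
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = self.calls[~ok].flat[0]
            raise FormatError(f"genotype code {bad} outside {{0,1,2,missing}}")
        ph = (self.individuals["ploidy_mode"] == "pseudo_haploid").to_numpy()
        if ph.any() and np.isin(self.calls[ph], 1).any():
            raise FormatError("pseudo-haploid individual carries a het call")

    # -- basic views ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def snp_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def individual_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def dosage(self) -> np.ndarray:
        """calls as float with NaN at missing slots."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    # -- subsetting -------------------------------------------------------
    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.snps.iloc[index].reset_index(drop=True),
            self.individuals.copy(),
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index],
            self.snps.copy(),
            self.individuals.iloc[index].reset_index(drop=True),
        )

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(
            (self.individuals["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no individuals in population {population!r}")
        return idx

    def allele_pairs(self) -> list[frozenset]:
        return [frozenset((r, a)) for r, a in
                zip(self.snps["allele_ref"], self.snps["allele_alt"])]

    def is_transition(self) -> np.ndarray:
        return np.array([p in TRANSITION_PAIRS for p in self.allele_pairs()])


@dataclass
class QMatrix:
    """ADMIXTURE-style cluster-proportion matrix.

    ``indigenous`` flags the components interpreted as Indigenous-American
    ancestry when filtering for nearly unadmixed individuals.
    """

    individuals: list
    components: list
    proportions: np.ndarray
    indigenous: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.individuals),
                                      len(self.components)):
            raise FormatError("Q-matrix shape mismatch")
        if (self.proportions < -1e-9).any() or (self.proportions > 1 + 1e-9).any():
            raise FormatError("Q proportions outside [0, 1]")
        rows = self.proportions.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-6:
            raise FormatError("Q-matrix rows must sum to 1 +/- 1e-6")
        unknown = self.indigenous - set(self.components)
        if unknown:
            raise FormatError(f"unknown indigenous components {sorted(unknown)}")

    def indigenous_fraction(self) -> pd.Series:
        cols = [i for i, c in enumerate(self.components)
                if c in self.indigenous]
        return pd.Series(self.proportions[:, cols].sum(axis=1),
                         index=self.individuals, name="indigenous_fraction")


@dataclass
class LocalAncestryCalls:
    """Per-haplotype local-ancestry labels with per-SNP posteriors.

    ``viterbi`` has shape (2 * n_individuals, n_snps) with integer codes
    indexing ``ancestries``; ``posterior`` has shape
    (2 * n_individuals, n_snps, n_ancestries) and rows summing to one.
    Haplotypes 2i and 2i+1 belong to individual i.
    """

    individuals: list
    ancestries: tuple
    viterbi: np.ndarray
    posterior: np.ndarray

    def __post_init__(self):
        self.viterbi = np.asarray(self.viterbi, dtype=np.int8)
        self.posterior = np.asarray(self.posterior, dtype=float)
        n_hap, n_snps = self.viterbi.shape
        if n_hap != 2 * len(self.individuals):
            raise FormatError("expected two haplotypes per individual")
        if self.posterior.shape != (n_hap, n_snps, len(self.ancestries)):
            raise FormatError("posterior shape mismatch")
        if np.abs(self.posterior.sum(axis=2) - 1.0).max() > 1e-6:
            raise FormatError("posteriors must sum to 1 +/- 1e-6")
        picked = np.take_along_axis(
            self.posterior, self.viterbi[:, :, None].astype(np.int64), axis=2)
        if (picked <= 0).any():
            raise FormatError("viterbi label has zero posterior support")

    @property
    def n_snps(self) -> int:
        return self.viterbi.shape[1]

    def ancestry_code(self, label: str) -> int:
        return self.ancestries.index(label)


def canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with (ind_a, ind_b) sorted lexicographically per row."""
    out = df.copy()
    swap = out["ind_a"] > out["ind_b"]
    out.loc[swap, ["ind_a", "ind_b"]] = out.loc[swap, ["ind_b", "ind_a"]].values
    return out


def make_ibd_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an IBD-segment table.

    Expected columns: ind_a, ind_b, chrom, start_cM, end_cM (length_cM is
    recomputed).  Segment genetic lengths must be positive.
    """
    required = ["ind_a", "ind_b", "chrom", "start_cM", "end_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"IBD table missing columns {missing}")
    out = canonical_pairs(df[required].copy())
    out["length_cM"] = out["end_cM"] - out["start_cM"]
    if (out["length_cM"] <= 0).any():
        raise FormatError("IBD segment with non-positive genetic length")
    if (out["ind_a"] == out["ind_b"]).any():
        raise FormatError("IBD segment pairs an individual with itself")
    return out.reset_index(drop=True)


PILEUP_COLUMNS = ["ind_id", "snp_id", "base", "baseq", "mapq",
                  "pos_in_read", "read_len", "strand"]


def make_pileup(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pileup missing columns {missing}")
    out = df[PILEUP_COLUMNS].copy().reset_index(drop=True)
    if not out["base"].isin(NUCLEOTIDES).all():
        raise FormatError("pileup base outside ACGT")
    if (out[["baseq", "mapq"]] < 0).any().any():
        raise FormatError("negative quality score")
    return out
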