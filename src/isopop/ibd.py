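"""IBD-segment and haplotype-painting summaries.

Within-population IBD sharing is summarized as the average total shared
length per pair in length bins (recent bottlenecks and endogamy enrich
long segments); between-population sharing in three length categories
(1-5, 5-10, >10 cM) proxies admixture age strata.  Painting summaries
operate on ChromoPainter-style copying matrices: total variation distance
between copying vectors, the cluster-reduction rule used to prune
unstable fineSTRUCTURE clusters, and within-cluster self-copy lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import make_ibd_table

logger = logging.getLogger(__name__)

#: nine default length bins (cM); the upper bin is open-ended
DEFAULT_BIN_EDGES = (1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 15.0, 20.0,
                     np.inf)
#: admixture-dating categories (cM): oldest, intermediate, youngest
DATING_CATEGORIES = ((1.0, 5.0), (5.0, 10.0), (10.0, np.inf))


def ibd_bin_summary(segments: pd.DataFrame, populations: dict,
                    bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Average total within-population IBD length per pair, by length bin.

    ``populations`` maps population name to its individuals; the
    denominator is the number of possible pairs n(n-1)/2, so pairs
    sharing nothing still dilute the average.  Populations of size one
    are skipped with a warning.
    """
    segments = make_ibd_table(segments)
    edges = np.asarray(bin_edges, dtype=float)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})"
              for i in range(len(edges) - 1)]
    ind_to_pop = {ind: pop for pop, inds in populations.items()
                  for ind in inds}
    pop_a = segments["ind_a"].map(ind_to_pop)
    pop_b = segments["ind_b"].map(ind_to_pop)
    within = segments[(pop_a == pop_b) & pop_a.notna()].copy()
    within["population"] = pop_a[within.index]
    within["bin"] = pd.cut(within["length_cM"], edges, right=False,
                           labels=labels)

    rows = []
    for pop, inds in populations.items():
        n = len(inds)
        if n < 2:
            logger.warning("population %s has %d individual(s); IBD "
                           "average undefined, skipped", pop, n)
            continue
        n_pairs = n * (n - 1) / 2
        sub = within[within["population"] == pop]
        sums = sub.groupby("bin", observed=False)["length_cM"].sum()
        for label in labels:
            rows.append({"population": pop, "bin": label,
                         "average_total_cM": sums.get(label, 0.0) / n_pairs,
                         "n_pairs": int(n_pairs)})
    return pd.DataFrame(rows)


def ibd_dating_bins(segments: pd.DataFrame, populations: dict,
                    categories=DATING_CATEGORIES,
                    min_long_blocks: int = 2, long_cM: float = 5.0,
                    min_short_blocks: int = 4) -> pd.DataFrame:
    """Between-population mean summed IBD per length category.

    Only individual pairs sharing at least ``min_long_blocks`` segments
    longer than ``long_cM`` and ``min_short_blocks`` shorter ones enter
    the averages (the published noise filter).  Length categories map
    onto admixture-age strata: short segments are oldest.
    """
    segments = make_ibd_table(segments)
    ind_to_pop = {ind: pop for pop, inds in populations.items()
                  for ind in inds}
    seg = segments.assign(
        pop_a=segments["ind_a"].map(ind_to_pop),
        pop_b=segments["ind_b"].map(ind_to_pop)).dropna(
            subset=["pop_a", "pop_b"])

    rows = []
    grouped = seg.groupby(["ind_a", "ind_b"], sort=False)
    pair_stats = []
    for (a, b), sub in grouped:
        n_long = int((sub["length_cM"] > long_cM).sum())
        n_short = int((sub["length_cM"] < long_cM).sum())
        if n_long < min_long_blocks or n_short < min_short_blocks:
            continue
        sums = [sub.loc[(sub["length_cM"] >= lo)
                        & (sub["length_cM"] < hi), "length_cM"].sum()
                for lo, hi in categories]
        pa, pb = sorted((sub["pop_a"].iat[0], sub["pop_b"].iat[0]))
        pair_stats.append((pa, pb, *sums))
    cols = ["pop_a", "pop_b"] + [f"sum_{lo:g}_{hi:g}cM"
                                 for lo, hi in categories]
    pair_df = pd.DataFrame(pair_stats, columns=cols)
    for (pa, pb), sub in pair_df.groupby(["pop_a", "pop_b"]):
        row = {"pop_a": pa, "pop_b": pb, "n_pairs": len(sub)}
        for c in cols[2:]:
            row[f"mean_{c}"] = float(sub[c].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Copying-matrix summaries
# ---------------------------------------------------------------------------

@dataclass
class CopyingMatrix:
    """Recipients x donors chunk summaries with a cluster assignment.

    ``lengths`` holds summed copied chunk lengths (recipients index,
    donors columns); ``counts`` the chunk counts; both non-negative.
    Self-copying (the diagonal) is excluded from individual-level
    comparisons.
    """

    lengths: pd.DataFrame
    counts: Optional[pd.DataFrame] = None
    clusters: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.lengths.to_numpy() < 0).any():
            raise ValueError("negative copied length")
        if self.counts is not None and (self.counts.to_numpy() < 0).any():
            raise ValueError("negative chunk count")

    def normalized_vector(self, individual: str) -> pd.Series:
        row = self.lengths.loc[individual].copy()
        if individual in row.index:
            row[individual] = 0.0
        total = row.sum()
        if total <= 0:
            raise ValueError(f"{individual} has an empty copying vector")
        return row / total


def tvd(a, b) -> float:
    """Total variation distance between two copying vectors.

    Vectors are normalized to sum one; TVD = 0.5 * sum |a_i - b_i|,
    in [0, 1] with 0 for identical profiles and 1 for disjoint support.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(0.5 * np.abs(a / a.sum() - b / b.sum()).sum())


def _cluster_mean_vectors(copying: CopyingMatrix, clusters: dict
                          ) -> pd.DataFrame:
    vecs = {}
    for cluster in sorted(set(clusters.values())):
        members = [i for i, c in clusters.items() if c == cluster]
        vecs[cluster] = pd.concat(
            [copying.normalized_vector(m) for m in members], axis=1
        ).mean(axis=1)
    return pd.DataFrame(vecs).T


def cluster_reduction(clusters: dict, copying: CopyingMatrix,
                      min_size: int = 5, tvd_max: float = 0.03) -> dict:
    """Merge unstable clusters into their nearest neighbour.

    A cluster is merged when its size is below ``min_size`` or its
    mean-copying-vector TVD to the nearest cluster falls below
    ``tvd_max``; the target is the nearest cluster by TVD (label order
    breaks ties), and the rule iterates to a fixed point.
    """
    clusters = dict(clusters)
    merges = []
    while len(set(clusters.values())) > 1:
        means = _cluster_mean_vectors(copying, clusters)
        names = list(means.index)
        sizes = {c: sum(1 for v in clusters.values() if v == c)
                 for c in names}
        nearest, nearest_tvd = {}, {}
        for c in names:
            others = [(tvd(means.loc[c], means.loc[o]), o)
                      for o in names if o != c]
            d, o = min(others)
            nearest[c], nearest_tvd[c] = o, d
        victims = [c for c in names
                   if sizes[c] < min_size or nearest_tvd[c] < tvd_max]
        if not victims:
            break
        victim = sorted(victims)[0]
        target = nearest[victim]
        for ind, c in clusters.items():
            if c == victim:
                clusters[ind] = target
        merges.append((victim, target))
    return {"clusters": clusters, "merges": merges,
            "n_clusters": len(set(clusters.values()))}


def self_copy_summary(copying: CopyingMatrix, clusters: dict
                      ) -> pd.DataFrame:
    """Per-individual copied length from own-cluster donors (self
    excluded), the isolation signal behind cluster self-copy violins."""
    rows = []
    for ind, cluster in clusters.items():
        row = copying.lengths.loc[ind]
        own = [d for d, c in clusters.items() if c == cluster and d != ind]
        self_len = float(row[own].sum())
        total = float(row.sum() - (row[ind] if ind in row.index else 0.0))
        rows.append({"ind_id": ind, "cluster": cluster,
                     "self_copy_length": self_len,
                     "self_copy_fraction": self_len / total if total > 0
                     else np.nan})
    return pd.DataFrame(rows)
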