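"""Rank tests for the number of independent ancestry streams (qpWave).

Given "left" (test) and "right" (reference) population sets, the matrix
F[i, j] = f4(left_i, left_0; right_j, right_0) has rank r when the left
populations derive from r + 1 independent streams relative to the rights.
Each rank is scored by the minimized chi-square residual of the best
rank-r approximation under the jackknife covariance of F, with
(|L| - 1 - r)(|R| - 1 - r) degrees of freedom.  A rank-0 p-value above
0.01 means a pair of left populations is consistent with a single shared
ancestry stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fstats import BlockDefinition, PopulationFrequencies, f4_matrix

logger = logging.getLogger(__name__)

P_SINGLE_SOURCE = 0.01   # rank-test rejection threshold


@dataclass
class RankResult:
    rank: int
    chisq: float
    dof: int
    p_value: float

    @property
    def neglog10_p(self) -> float:
        with np.errstate(divide="ignore"):
            return float(-np.log10(self.p_value))


class QpWave:
    """Model object for the left/right f4 rank test.

    Parameters
    ----------
    pf : PopulationFrequencies
    left, right : sequences of population names; the first entry of each
        is the basis population differenced against.
    blocks : BlockDefinition for the jackknife.
    """

    def __init__(self, pf: PopulationFrequencies, left, right,
                 blocks: BlockDefinition):
        self.left = list(left)
        self.right = list(right)
        if len(self.left) < 2:
            raise ValueError("need at least two left populations")
        if len(self.right) < len(self.left) + 1:
            logger.warning("qpWave is under-determined unless "
                           "|right| >= |left| + 1")
        self._fm = f4_matrix(pf, self.left, self.right, blocks)

    def fit(self, max_rank: int | None = None,
            ridge: float = 1e-9) -> "QpWaveResults":
        F = self._fm["F"]
        Q = self._fm["cov"]
        # guard against a singular jackknife covariance
        try:
            evals = np.linalg.eigvalsh(Q)
            if evals.min() <= ridge * evals.max():
                raise np.linalg.LinAlgError
            Qinv = np.linalg.inv(Q)
        except np.linalg.LinAlgError:
            logger.warning("jackknife covariance near-singular; applying "
                           "ridge regularization")
            scale = np.trace(Q) / len(Q) or 1.0
            Q = Q + ridge * scale * np.eye(len(Q))
            Qinv = np.linalg.inv(Q)

        L1, R1 = F.shape
        top = min(L1, R1) - 1 if max_rank is None else max_rank
        results = []
        for r in range(top + 1):
            dof = (L1 - r) * (R1 - r)
            if dof <= 0:
                break
            chisq = self._rank_chisq(F, Qinv, r)
            results.append(RankResult(
                r, chisq, dof, float(stats.chi2.sf(chisq, dof))))
        return QpWaveResults(self, results)

    @staticmethod
    def _rank_chisq(F: np.ndarray, Qinv: np.ndarray, rank: int) -> float:
        """Minimized GLS residual of the best rank-r approximation,
        by alternating generalized least squares on the two factors."""
        L1, R1 = F.shape
        f = F.ravel()
        if rank == 0:
            return float(f @ Qinv @ f)
        u, s, vt = np.linalg.svd(F, full_matrices=False)
        A = u[:, :rank] * s[:rank]
        B = vt[:rank]
        prev = np.inf
        for _ in range(200):
            # x = (A B).ravel() is linear in each factor in turn
            MB = np.kron(A, np.eye(R1))              # columns index vec(B)
            B = _gls_solve(MB, f, Qinv).reshape(rank, R1)
            MA = np.kron(np.eye(L1), B.T)            # columns index vec(A)
            A = _gls_solve(MA, f, Qinv).reshape(L1, rank)
            resid = f - (A @ B).ravel()
            chisq = float(resid @ Qinv @ resid)
            if prev - chisq < 1e-12 * (1.0 + abs(chisq)):
                break
            prev = chisq
        return chisq


def _gls_solve(M: np.ndarray, y: np.ndarray, Qinv: np.ndarray) -> np.ndarray:
    lhs = M.T @ Qinv @ M
    rhs = M.T @ Qinv @ y
    return np.linalg.lstsq(lhs, rhs, rcond=None)[0]


class QpWaveResults:
    """Per-rank chi-square scores and p-values with a summary table."""

    def __init__(self, model: QpWave, ranks: list):
        self.model = model
        self.ranks = ranks

    def p_value(self, rank: int) -> float:
        return self.ranks[rank].p_value

    def minimum_streams(self, alpha: float = P_SINGLE_SOURCE) -> int:
        """Smallest number of ancestry streams not rejected at ``alpha``:
        rank r is accepted when its residual p-value exceeds alpha, and
        implies r + 1 streams."""
        for r in self.ranks:
            if r.p_value > alpha:
                return r.rank + 1
        return len(self.ranks) + 1

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "rank": r.rank,
            "chisq": r.chisq,
            "dof": r.dof,
            "p_value": r.p_value,
            "neglog10_p": r.neglog10_p,
        } for r in self.ranks])

    def __str__(self):
        lines = [f"qpWave: left={self.model.left} right={self.model.right}",
                 self.summary().to_string(index=False)]
        return "\n".join(lines)
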