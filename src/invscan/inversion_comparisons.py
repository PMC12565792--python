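"""Pairwise dependence tests between called inversions.

Every unordered pair of retained inversions is tested for association of
their per-sample karyotypes (coded 0/1/2 under each inversion's own
orientation): a Spearman rank correlation with Benjamini–Hochberg FDR
control across all pairs, plus a chi-square test on the genotype
contingency table as a model-free companion statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .karyotyping import InversionCall

logger = logging.getLogger(__name__)


@dataclass
class InversionPairResult:
    inversion_a: str
    inversion_b: str
    n_shared: int
    rho: float
    p_raw: float
    p_fdr: float
    chi2: float
    chi2_p: float
    significant: bool
    low_n: bool = False


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, q_i = p_i * m / i, enforce monotone non-decreasing from
    the largest down, cap at 1; returned in the original order.
    """
    p = np.asarray(pvals, dtype=np.float64)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def genotype_chi2(codes_a: np.ndarray, codes_b: np.ndarray
                  ) -> tuple[float, float]:
    """Chi-square test of the up-to-3x3 genotype contingency table.

    Asymptotic test without continuity correction; rows/columns with zero
    margin are dropped.  Returns (statistic, p); (0, 1) for a degenerate
    (single-row or single-column) table.
    """
    table = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(codes_a, codes_b):
        table[a, b] += 1
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def pairwise_inversion_tests(inversions: list[InversionCall],
                             alpha: float = 0.05, min_shared: int = 10,
                             ) -> list[InversionPairResult]:
    """All-pairs karyotype dependence tests with one BH adjustment.

    Pairs with fewer than ``min_shared`` samples called in both inversions
    are flagged ``low_n`` and excluded from the FDR family (their p_fdr is
    nan and they are never significant).
    """
    if len(inversions) < 2:
        raise ValueError("need >= 2 inversions to compare")
    code_maps = [inv.genotype_codes() for inv in inversions]
    results: list[InversionPairResult] = []
    family_idx: list[int] = []
    for i in range(len(inversions)):
        for j in range(i + 1, len(inversions)):
            shared = sorted(set(code_maps[i]) & set(code_maps[j]))
            a = np.array([code_maps[i][s] for s in shared])
            b = np.array([code_maps[j][s] for s in shared])
            low_n = len(shared) < min_shared
            if low_n or np.ptp(a) == 0 or np.ptp(b) == 0:
                rho, p_raw = float("nan"), float("nan")
                chi2, chi2_p = float("nan"), float("nan")
                low_n = True
            else:
                rho, p_raw = stats.spearmanr(a, b)
                chi2, chi2_p = genotype_chi2(a, b)
            res = InversionPairResult(
                inversion_a=inversions[i].inversion_id,
                inversion_b=inversions[j].inversion_id,
                n_shared=len(shared), rho=float(rho), p_raw=float(p_raw),
                p_fdr=float("nan"), chi2=chi2, chi2_p=chi2_p,
                significant=False, low_n=low_n)
            if not low_n:
                family_idx.append(len(results))
            results.append(res)
    if family_idx:
        adj = bh_adjust(np.array([results[k].p_raw for k in family_idx]))
        for k, q in zip(family_idx, adj):
            results[k].p_fdr = float(q)
            results[k].significant = bool(q <= alpha)
    return results
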