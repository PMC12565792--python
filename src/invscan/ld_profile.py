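"""Short-range linkage disequilibrium profile and its PCA corroboration.

Recombination suppression between inversion arrangements elevates genotypic
r² between nearby SNPs inside the inverted interval.  This module computes
all pair r² within a bp distance cap, summarises them as a windowed median
along the chromosome (window length a fraction of the chromosome length),
and correlates that profile with the mean absolute SNP loading of a PCA
component over the same window grid — a significant positive Spearman rho
ties the LD landscape to the loading-variance signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._corr import lagged_r2
from .genotype_io import MISSING, GenotypeMatrix
from .inversion_scan import PCAResult, WindowStat

logger = logging.getLogger(__name__)


@dataclass
class LDPair:
    chrom: str
    pos_a: int
    pos_b: int
    r2: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.pos_a + self.pos_b)


@dataclass
class LDCorrelation:
    chrom: str
    component: int
    rho: float
    p_value: float
    n_windows: int


def pair_r2(d_a: np.ndarray, d_b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors.

    Pairwise-complete over MISSING; None (undefined) when fewer than 3
    shared samples or either vector is constant on the shared set.
    """
    d_a = np.asarray(d_a)
    d_b = np.asarray(d_b)
    shared = (d_a != MISSING) & (d_b != MISSING)
    if shared.sum() < 3:
        return None
    a = d_a[shared].astype(np.float64)
    b = d_b[shared].astype(np.float64)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def collect_pair_arrays(gm: GenotypeMatrix, chrom: str,
                        max_dist: int = 12_000, min_dist: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array form of :func:`collect_pairs`: ``(pos_a, pos_b, r2)``.

    Enumerates lag-by-lag across the sorted position vector — exactly the
    pairs a brute-force double loop would visit, with undefined r² pairs
    skipped (count logged).  When the chromosome has no missing entries the
    r² for every lag collapses to one dot product of pre-standardised
    columns.
    """
    cols = np.where(gm.chrom == chrom)[0]
    pos = gm.pos[cols]
    d = gm.dosage[:, cols]
    m = len(cols)
    if m < 2:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    # largest lag that can still be within max_dist anywhere
    reach = np.searchsorted(pos, pos + max_dist, side="right") - np.arange(m) - 1
    max_lag = int(reach.max())

    complete = not (d == MISSING).any()
    if complete:
        z = d.astype(np.float64)
        z -= z.mean(axis=0)
        norm = np.linalg.norm(z, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z /= norm
        z[:, norm == 0] = np.nan

    pos_a: list[np.ndarray] = []
    pos_b: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    n_undefined = 0
    for lag in range(1, max_lag + 1):
        dist = pos[lag:] - pos[:-lag]
        sel = (dist > min_dist) & (dist <= max_dist)
        if not sel.any():
            continue
        if complete:
            r = np.einsum("ij,ij->j", z[:, :-lag], z[:, lag:])
            r2 = r * r
        else:
            r2 = lagged_r2(d, lag)
        idx = np.where(sel)[0]
        defined = ~np.isnan(r2[idx])
        n_undefined += int((~defined).sum())
        idx = idx[defined]
        pos_a.append(pos[idx])
        pos_b.append(pos[idx + lag])
        r2s.append(r2[idx])
    if n_undefined:
        logger.info("collect_pairs %s: skipped %d undefined pairs",
                    chrom, n_undefined)
    if not pos_a:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0),)
    pa = np.concatenate(pos_a)
    pb = np.concatenate(pos_b)
    rr = np.concatenate(r2s)
    order = np.lexsort((pb, pa))
    return pa[order], pb[order], rr[order]


def collect_pairs(gm: GenotypeMatrix, chrom: str,
                  max_dist: int = 12_000, min_dist: int = 0,
                  ) -> list[LDPair]:
    """All SNP pairs on ``chrom`` with ``min_dist < pos_b - pos_a <= max_dist``
    as :class:`LDPair` records (see :func:`collect_pair_arrays`)."""
    pa, pb, rr = collect_pair_arrays(gm, chrom, max_dist, min_dist)
    return [LDPair(chrom=chrom, pos_a=int(a), pos_b=int(b), r2=float(r))
            for a, b, r in zip(pa, pb, rr)]


def ld_window_grid(chrom_length: int, window_frac: float = 0.005,
                   step_frac: float = 0.0025) -> list[tuple[int, int]]:
    """Half-open bp windows covering [1, chrom_length], sized as a fraction
    of the chromosome length."""
    window = max(int(round(window_frac * chrom_length)), 1)
    step = max(int(round(step_frac * chrom_length)), 1)
    grid = []
    start = 1
    while start <= chrom_length:
        grid.append((start, start + window))
        start += step
    return grid


def windowed_median_r2(pairs, chrom: str, chrom_length: int,
                       window_frac: float = 0.005, step_frac: float = 0.0025,
                       min_pairs: int = 5) -> list[WindowStat]:
    """Median pair r² in sliding windows along the chromosome.

    ``pairs`` is a list of :class:`LDPair` or a ``(pos_a, pos_b, r2)``
    array triple.  A pair belongs to a window iff its midpoint lies
    inside; windows with fewer than ``min_pairs`` pairs carry no value.
    """
    if chrom_length is None or chrom_length <= 0:
        raise ValueError(f"chromosome length unknown for {chrom}")
    grid = ld_window_grid(chrom_length, window_frac, step_frac)
    if isinstance(pairs, tuple):
        pa, pb, r2s = pairs
        mids = 0.5 * (pa + pb)
    else:
        mids = np.array([p.midpoint for p in pairs])
        r2s = np.array([p.r2 for p in pairs])
    order = np.argsort(mids)
    mids, r2s = mids[order], r2s[order]
    out = []
    for start, end in grid:
        lo = np.searchsorted(mids, start, side="left")
        hi = np.searchsorted(mids, end, side="left")
        n = hi - lo
        value = float(np.median(r2s[lo:hi])) if n >= min_pairs else None
        out.append(WindowStat(chrom=chrom, component=0, start=start, end=end,
                              value=value, n_snps=int(n)))
    return out


def mean_abs_weight_per_window(pca: PCAResult, component: int,
                               grid: list[tuple[int, int]],
                               min_snps: int = 1) -> list[float | None]:
    """Mean absolute SNP loading of a component over each grid window."""
    w = np.abs(pca.weights[:, component - 1])
    out: list[float | None] = []
    for start, end in grid:
        lo = np.searchsorted(pca.pos, start, side="left")
        hi = np.searchsorted(pca.pos, end, side="left")
        out.append(float(w[lo:hi].mean()) if hi - lo >= min_snps else None)
    return out


def weight_ld_correlation(windows: list[WindowStat], pca: PCAResult,
                          component: int) -> LDCorrelation | None:
    """Spearman correlation between windowed median r² and mean |loading|.

    Both statistics are evaluated on the LD window grid; windows missing
    either value are dropped.  Average ranks handle ties.  None (with a
    warning) when fewer than 5 complete windows remain.
    """
    grid = [(w.start, w.end) for w in windows]
    mean_w = mean_abs_weight_per_window(pca, component, grid)
    xs, ys = [], []
    for w, mw in zip(windows, mean_w):
        if w.value is not None and mw is not None:
            xs.append(w.value)
            ys.append(mw)
    if len(xs) < 5:
        logger.warning("weight_ld_correlation: only %d complete windows",
                       len(xs))
        return None
    rho, p = stats.spearmanr(xs, ys)
    return LDCorrelation(chrom=pca.chrom, component=component,
                         rho=float(rho), p_value=float(p), n_windows=len(xs))
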