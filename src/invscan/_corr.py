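"""Pairwise-complete dosage correlation primitives shared by LD code paths.

Dosage matrices may contain MISSING entries; every correlation here is
computed over the samples non-missing in *both* columns of a pair
("pairwise complete"), which keeps r² well defined under scattered
missingness without imputing.
"""

from __future__ import annotations

import numpy as np

from .genotype_io import MISSING


def r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """All-pairs squared Pearson correlation of dosage columns.

    Pairwise-complete over MISSING entries.  Pairs with a constant column
    (zero variance on the shared samples) or fewer than 2 shared samples
    get ``nan``.  Returns an ``(m, m)`` symmetric matrix with unit diagonal
    where defined.
    """
    d = dosage.astype(np.float64)
    mask = dosage != MISSING
    d[~mask] = 0.0
    m = mask.astype(np.float64)

    n = m.T @ m                      # shared sample counts
    sx = d.T @ m                     # sum of x over samples shared with y
    sy = sx.T
    sxy = d.T @ d
    sxx = (d * d).T @ m
    syy = sxx.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(varx <= 0) | (vary <= 0) | (n < 2)] = np.nan
    return r2


def lagged_r2(dosage: np.ndarray, lag: int) -> np.ndarray:
    """r² between column ``j`` and column ``j + lag`` for every ``j``.

    Vectorised across columns; pairwise-complete over MISSING.  Entries are
    ``nan`` where undefined (constant column or < 2 shared samples).
    """
    a = dosage[:, :-lag].astype(np.float64)
    b = dosage[:, lag:].astype(np.float64)
    va = dosage[:, :-lag] != MISSING
    vb = dosage[:, lag:] != MISSING
    v = (va & vb).astype(np.float64)
    a = np.where(v > 0, a, 0.0)
    b = np.where(v > 0, b, 0.0)

    n = v.sum(axis=0)
    sx = a.sum(axis=0)
    sy = b.sum(axis=0)
    sxy = (a * b).sum(axis=0)
    sxx = (a * a).sum(axis=0)
    syy = (b * b).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(varx <= 0) | (vary <= 0) | (n < 2)] = np.nan
    return r2
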