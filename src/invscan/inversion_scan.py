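"""Per-chromosome PCA and the sliding-window loading-variance scan.

A polymorphic inversion suppresses recombination between arrangements, so
the SNPs inside it behave as one long haplotype block: a principal
component of the genotype matrix aligns with inversion karyotype, and the
SNP loadings (eigenvector entries) of that component are large inside the
inverted interval and near zero elsewhere.  Scanning the variance of those
loadings in bp windows therefore localises the inversion: a contiguous run
of windows with variance far above the chromosome background is the
candidate-region signal this module extracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .variant_filtering import allele_frequency

logger = logging.getLogger(__name__)


class InsufficientResolutionError(ValueError):
    """Too few valued windows on a chromosome for region detection."""


@dataclass
class PCAResult:
    """Per-chromosome PCA decomposition.

    ``scores`` are sample coordinates (left singular vectors times singular
    values); ``weights`` are unit-norm SNP loadings (right singular
    vectors); ``eigenvalues`` are squared singular values over
    ``n_samples - 1``, so the sample variance of scores column k equals
    eigenvalue k.  ``snp_index`` maps weight rows back to columns of the
    genotype matrix the PCA was run on; ``pos`` carries their positions.
    """

    chrom: str
    scores: np.ndarray
    weights: np.ndarray
    eigenvalues: np.ndarray
    snp_index: np.ndarray
    pos: np.ndarray

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class WindowStat:
    """One sliding-window statistic (loading variance here; median r² in
    the LD profile).  ``value`` is None when the window held fewer than the
    minimum number of observations."""

    chrom: str
    component: int
    start: int
    end: int
    value: float | None
    n_snps: int


@dataclass
class CandidateRegion:
    """A run of flagged high-variance windows merged into one interval."""

    chrom: str
    component: int
    start: int
    end: int
    peak_value: float
    n_windows: int


def standardize(gm: GenotypeMatrix, chrom: str
                ) -> tuple[np.ndarray, np.ndarray]:
    """Centre and scale one chromosome's dosages for PCA.

    Column j becomes ``(d - 2 p_j) / sqrt(2 p_j (1 - p_j))`` with ``p_j``
    the alt-allele frequency — the usual genotype standardisation under
    which every marker contributes unit variance under Hardy–Weinberg.
    MISSING entries become 0 after centring (mean imputation).  Monomorphic
    or zero-variance columns are dropped (count logged).

    Returns ``(matrix, kept)`` where ``kept`` holds the gm column indices
    of the surviving SNPs.
    """
    sub = gm.subset_chrom(chrom)
    cols = np.where(gm.chrom == chrom)[0]
    if sub.n_snps < 2 or sub.n_samples < 3:
        raise ValueError(f"chromosome {chrom}: need >= 2 SNPs and >= 3 samples")
    freq, _ = allele_frequency(sub)
    observed = sub.dosage != MISSING
    d = sub.dosage.astype(np.float64)
    ok = ~np.isnan(freq) & (freq > 0) & (freq < 1)
    # a column can have 0 < p < 1 yet zero variance (all heterozygous);
    # nonzero variance <=> at least two distinct observed genotype values
    n_distinct = sum(((sub.dosage == g) & observed).any(axis=0).astype(np.int8)
                     for g in (0, 1, 2))
    polymorphic = ok & (n_distinct >= 2)
    n_dropped = int((~polymorphic).sum())
    if n_dropped:
        logger.info("standardize %s: dropped %d degenerate columns",
                    chrom, n_dropped)
    if not polymorphic.any():
        raise ValueError(f"chromosome {chrom}: all columns degenerate")

    p = freq[polymorphic]
    z = (d[:, polymorphic] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[~observed[:, polymorphic]] = 0.0
    return z, cols[polymorphic]


def chromosome_pca(gm: GenotypeMatrix, chrom: str,
                   n_components: int = 5) -> PCAResult:
    """PCA of one chromosome's standardised genotype matrix.

    Computed from the eigendecomposition of the small samples x samples
    Gram matrix (equivalent to the SVD of the standardised matrix, but
    O(n² m) instead of O(n m²) for the typical n << m).  Sign convention:
    each component is flipped so its largest-|loading| SNP has a positive
    loading.
    """
    z, kept = standardize(gm, chrom)
    n, m = z.shape
    k_req = min(n_components, n - 1, m)
    if k_req < n_components:
        logger.warning("chromosome %s: truncating to %d components", chrom, k_req)

    gram = z @ z.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:k_req]
    sv2 = np.clip(evals[order], 0.0, None)          # squared singular values
    u = evecs[:, order]
    s = np.sqrt(sv2)

    nonzero = s > 1e-12 * max(s[0], 1.0)
    k = int(nonzero.sum())
    if k < k_req:
        logger.warning("chromosome %s: rank %d < requested %d", chrom, k, k_req)
    u, s, sv2 = u[:, :k], s[:k], sv2[:k]

    weights = (z.T @ u) / s                         # right singular vectors
    weights /= np.linalg.norm(weights, axis=0)      # guard rounding drift
    scores = u * s
    # deterministic sign: largest-|weight| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(weights[:, j])))
        if weights[i, j] < 0:
            weights[:, j] = -weights[:, j]
            scores[:, j] = -scores[:, j]
    eigenvalues = sv2 / (n - 1)
    return PCAResult(chrom=chrom, scores=scores, weights=weights,
                     eigenvalues=eigenvalues, snp_index=kept,
                     pos=gm.pos[kept])


def windowed_weight_variance(pca: PCAResult, component: int,
                             window_bp: int = 10_000, step_bp: int = 7_500,
                             min_snps: int = 3) -> list[WindowStat]:
    """Sliding-window variance of one component's SNP loadings.

    Windows of ``window_bp`` advance by ``step_bp``, anchored at the
    chromosome's first SNP; the value is the unbiased (n-1) sample variance
    of the loadings whose positions fall in the half-open window.  Windows
    with fewer than ``min_snps`` loadings carry no value (variance over a
    couple of points is too unstable to flag on).
    """
    if not (1 <= component <= pca.n_components):
        raise ValueError(f"component {component} out of range")
    w = pca.weights[:, component - 1]
    pos = pca.pos
    out: list[WindowStat] = []
    w_start = int(pos[0])
    last = int(pos[-1])
    while w_start <= last:
        lo = np.searchsorted(pos, w_start, side="left")
        hi = np.searchsorted(pos, w_start + window_bp, side="left")
        n = hi - lo
        value = float(np.var(w[lo:hi], ddof=1)) if n >= min_snps else None
        out.append(WindowStat(chrom=pca.chrom, component=component,
                              start=w_start, end=w_start + window_bp,
                              value=value, n_snps=int(n)))
        w_start += step_bp
    return out


def detect_candidate_regions(windows: list[WindowStat],
                             flag_quantile: float = 0.75,
                             flag_fold: float = 5.0,
                             min_run: int = 10,
                             max_gap: int = 2) -> list[CandidateRegion]:
    """Merge runs of high-variance windows into candidate regions.

    A window is flagged when its value reaches both the ``flag_quantile``
    quantile of all valued windows and ``flag_fold`` times their median
    (``value >= threshold``, so blocks tied exactly at the quantile count).
    Flagged windows are chained along the chromosome, tolerating up to
    ``max_gap`` consecutive unflagged windows; chains with at least
    ``min_run`` flagged windows become regions spanning the first to last
    flagged window.  Regions are returned sorted by peak value, descending.

    Under a structureless chromosome the fold-over-median bar is far in the
    tail of the window-variance distribution, so no chain forms; the
    quantile bar only matters when a large fraction of the chromosome is
    shifted, and must therefore stay below the plausible inverted fraction.
    """
    values = np.array([w.value for w in windows if w.value is not None])
    if len(values) < 20:
        raise InsufficientResolutionError(
            f"only {len(values)} valued windows; need >= 20")
    threshold = max(float(np.quantile(values, flag_quantile)),
                    flag_fold * float(np.median(values)))

    regions: list[CandidateRegion] = []
    chain: list[WindowStat] = []
    gap = 0

    def close() -> None:
        nonlocal chain
        if len(chain) >= min_run:
            regions.append(CandidateRegion(
                chrom=chain[0].chrom, component=chain[0].component,
                start=chain[0].start, end=chain[-1].end,
                peak_value=max(w.value for w in chain),
                n_windows=len(chain)))
        chain = []

    for w in sorted(windows, key=lambda w: w.start):
        flagged = w.value is not None and w.value >= threshold
        if flagged:
            chain.append(w)
            gap = 0
        elif chain:
            gap += 1
            if gap > max_gap:
                close()
                gap = 0
    close()
    regions.sort(key=lambda r: r.peak_value, reverse=True)
    return regions
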