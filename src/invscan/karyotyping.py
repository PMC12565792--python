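"""Inversion karyotyping: from a candidate component to AA/AB/BB calls.

The SNPs with the largest absolute loadings on a candidate component are
dominated by sites near-fixed between the standard and inverted
arrangements.  Identity-by-state similarity over that subset separates
samples into three groups — the two arrangement homozygotes at the ends
and heterokaryotypes midway — which a one-dimensional classical MDS
embedding followed by fuzzy c-means turns into per-sample genotype calls
with membership probabilities.  Components whose clustering is not
"three well-defined groups" are returned unretained, with the reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix
from .inversion_scan import CandidateRegion, PCAResult

logger = logging.getLogger(__name__)

GENOTYPE_LABELS = ("AA", "AB", "BB")
GENOTYPE_CODE = {"AA": 0, "AB": 1, "BB": 2}


@dataclass
class KaryotypeCall:
    sample_id: str
    inversion_id: str
    genotype: str                      # AA / AB / BB
    memberships: np.ndarray            # 3-vector, sums to 1
    mds1: float


@dataclass
class InversionCall:
    """One candidate chromosome-component with its per-sample calls and
    population summaries (minor-arrangement frequency and fixation index)."""

    inversion_id: str
    chrom: str
    component: int
    region: CandidateRegion | None
    calls: list[KaryotypeCall]
    inv_maf: float
    f_index: float
    retained: bool
    reason: str = ""
    centers: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def counts(self) -> tuple[int, int, int]:
        n = [0, 0, 0]
        for c in self.calls:
            n[GENOTYPE_CODE[c.genotype]] += 1
        return tuple(n)

    def genotype_codes(self) -> dict[str, int]:
        """sample_id -> 0/1/2 coding under this inversion's orientation."""
        return {c.sample_id: GENOTYPE_CODE[c.genotype] for c in self.calls}


def select_top_weight_snps(pca: PCAResult, component: int,
                           fraction: float = 0.01) -> np.ndarray:
    """Indices (into the gm the PCA was run on) of the top-|loading| SNPs.

    Takes ``ceil(fraction * n_snps)`` SNPs with the largest absolute
    loading on the component; ties at the cut go to the lower position.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    w = np.abs(pca.weights[:, component - 1])
    k = int(np.ceil(fraction * len(w)))
    if k < 1:
        raise ValueError("top-weight selection is empty")
    if k < 10:
        logger.warning("top-weight selection yields only %d SNPs", k)
    order = np.lexsort((pca.pos, -w))   # primary: |w| desc; tie: pos asc
    chosen = order[:k]
    return pca.snp_index[np.sort(chosen)]


def ibs_matrix(gm: GenotypeMatrix, snp_subset: np.ndarray) -> np.ndarray:
    """Samples x samples identity-by-state similarity over a SNP subset.

    IBS(i, j) is the mean over pairwise-complete subset SNPs of
    ``(2 - |d_i - d_j|) / 2``: 1 for identical genotypes, 1/2 for one
    shared allele, 0 for opposite homozygotes.
    """
    if gm.n_samples < 2:
        raise ValueError("IBS needs >= 2 samples")
    if len(snp_subset) == 0:
        raise ValueError("empty SNP subset")
    d = gm.dosage[:, snp_subset]
    obs = (d != MISSING)
    a0 = (d == 0) & obs
    a1 = (d == 1) & obs
    a2 = (d == 2) & obs
    f0, f1, f2, fm = (x.astype(np.float64) for x in (a0, a1, a2, obs))
    count = fm @ fm.T
    agree = f0 @ f0.T + f1 @ f1.T + f2 @ f2.T
    diff2 = f0 @ f2.T + f2 @ f0.T
    diff1 = count - agree - diff2
    if (count[~np.eye(len(count), dtype=bool)] == 0).any():
        raise ValueError("a sample pair shares zero non-missing subset SNPs")
    ibs = 1.0 - (diff1 + 2.0 * diff2) / (2.0 * count)
    np.fill_diagonal(ibs, 1.0)
    return ibs


def classical_mds(similarity: np.ndarray, k: int = 1) -> np.ndarray:
    """Classical (Torgerson) MDS of the distance ``D = 1 - similarity``.

    Double-centres ``-D²/2`` and embeds on the top-k eigenpairs; negative
    eigenvalues are clamped to zero.  Axis signs are fixed by making the
    sample with the largest |coordinate| positive on each axis.
    """
    d = 1.0 - similarity
    n = d.shape[0]
    d2 = d * d
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12 * max(abs(evals[0]), 1.0)).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        logger.warning("MDS: only %d positive eigenvalues; truncating from %d",
                       n_pos, k)
        if k_eff == 0:
            return np.zeros((n, 1))
    coords = evecs[:, :k_eff] * np.sqrt(np.clip(evals[:k_eff], 0.0, None))
    for a in range(k_eff):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float
                     ) -> np.ndarray:
    dist = np.abs(x[:, None] - centers[None, :])
    zero = dist < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dist ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        u[hit, np.argmax(zero[hit], axis=1)] = 1.0
    return u


def _fcm_run(x: np.ndarray, centers: np.ndarray, m: float, tol: float,
             max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    for _ in range(max_iter):
        u = _fcm_memberships(x, centers, m)
        um = u ** m
        new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break
    else:
        logger.warning("fuzzy_cmeans: no convergence in %d iterations",
                       max_iter)
    u = _fcm_memberships(x, centers, m)
    objective = float((u ** m * (x[:, None] - centers[None, :]) ** 2).sum())
    return u, centers, objective


def fuzzy_cmeans(coords: np.ndarray, c: int = 3, m: float = 2.0,
                 tol: float = 1e-6, max_iter: int = 500,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on a 1-D embedding.

    Two deterministic starts are run — centers at the interior quantiles
    (1/6, 3/6, 5/6 for c = 3) and centers at (min, median, max) — and the
    solution with the lower fuzzy objective is kept.  The second start
    rescues skewed cluster-size configurations where all quantile centers
    fall inside one large cluster and the iteration cannot escape it.
    Seed-controlled jitter is applied only if a start's centers collide.
    Memberships use the standard inverse-distance ``2/(m-1)`` weighting; a
    point coinciding with a center gets crisp membership there.  Returns
    ``(memberships, centers)`` with centers sorted ascending and membership
    columns in that order.
    """
    x = np.asarray(coords, dtype=np.float64).reshape(-1)
    if len(np.unique(x)) < c:
        raise ValueError(f"need >= {c} distinct coordinate values")
    q_interior = (2.0 * np.arange(c) + 1.0) / (2.0 * c)
    q_extreme = np.linspace(0.0, 1.0, c)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for quantiles in (q_interior, q_extreme):
        centers = np.quantile(x, quantiles)
        if len(np.unique(centers)) < c:
            rng = np.random.default_rng(seed)
            span = max(x.max() - x.min(), 1.0)
            centers = centers + rng.uniform(-1e-3, 1e-3, size=c) * span
            centers.sort()
        run = _fcm_run(x, centers, m, tol, max_iter)
        if best is None or run[2] < best[2]:
            best = run
    u, centers, _ = best
    order = np.argsort(centers)
    return u[:, order], centers[order]


def call_karyotypes(sample_ids: list[str], inversion_id: str,
                    memberships: np.ndarray, centers: np.ndarray,
                    coords: np.ndarray,
                    min_cluster_size: int = 3,
                    min_mean_membership: float = 0.8,
                    spacing_window: tuple[float, float] = (0.3, 0.7),
                    ) -> tuple[list[KaryotypeCall], bool, str]:
    """Assign AA/AB/BB by maximal membership and judge cluster quality.

    Orientation: of the two flanking (homozygote) clusters, the larger is
    AA — the major arrangement — so the minor-arrangement frequency is at
    most 0.5 by construction.  The middle cluster is AB.  Retention
    requires every cluster to have at least ``min_cluster_size`` samples,
    mean maximal membership at least ``min_mean_membership``, and the
    middle center's relative position between the flanking centers inside
    ``spacing_window`` (a Hardy–Weinberg inversion gives ~0.5).
    """
    hard = np.argmax(memberships, axis=1)       # 0 = low center, 2 = high
    sizes = np.bincount(hard, minlength=3)

    retained, reason = True, ""
    if sizes.min() < min_cluster_size:
        retained, reason = False, "cluster size"
    else:
        mean_max = float(memberships.max(axis=1).mean())
        span = centers[2] - centers[0]
        rel = (centers[1] - centers[0]) / span if span > 0 else np.nan
        if mean_max < min_mean_membership:
            retained, reason = False, "mean membership"
        elif not (spacing_window[0] <= rel <= spacing_window[1]):
            retained, reason = False, "center spacing"

    # orientation: larger flanking cluster is AA
    if sizes[0] >= sizes[2]:
        label_of = {0: "AA", 1: "AB", 2: "BB"}
        col_order = (0, 1, 2)
    else:
        label_of = {0: "BB", 1: "AB", 2: "AA"}
        col_order = (2, 1, 0)

    x = np.asarray(coords).reshape(-1)
    calls = [
        KaryotypeCall(
            sample_id=s,
            inversion_id=inversion_id,
            genotype=label_of[int(hard[i])],
            memberships=memberships[i, list(col_order)],
            mds1=float(x[i]),
        )
        for i, s in enumerate(sample_ids)
    ]
    return calls, retained, reason


def inversion_summary(calls: list[KaryotypeCall]) -> tuple[float, float]:
    """Minor-arrangement frequency and fixation index of a call set.

    With counts (n_AA, n_AB, n_BB): q = (2 n_BB + n_AB) / 2n,
    H_obs = n_AB / n, H_exp = 2 q (1 - q), F = 1 - H_obs / H_exp
    (0 when H_exp = 0).
    """
    n = len(calls)
    n_ab = sum(1 for c in calls if c.genotype == "AB")
    n_bb = sum(1 for c in calls if c.genotype == "BB")
    q = (2 * n_bb + n_ab) / (2 * n)
    h_obs = n_ab / n
    h_exp = 2.0 * q * (1.0 - q)
    f = 1.0 - h_obs / h_exp if h_exp > 0 else 0.0
    return q, f


def karyotype_component(gm: GenotypeMatrix, pca: PCAResult, component: int,
                        region: CandidateRegion | None = None,
                        top_fraction: float = 0.01, seed: int = 0,
                        min_cluster_size: int = 3,
                        min_mean_membership: float = 0.8,
                        spacing_window: tuple[float, float] = (0.3, 0.7),
                        ) -> InversionCall:
    """Full karyotyping of one chromosome-component.

    Chains top-weight SNP selection (chromosome-wide, per the component),
    IBS, 1-D classical MDS and fuzzy c-means with c = 3 into an
    :class:`InversionCall`.
    """
    inversion_id = f"{pca.chrom}:C{component}"
    subset = select_top_weight_snps(pca, component, top_fraction)
    ibs = ibs_matrix(gm, subset)
    coords = classical_mds(ibs, k=1)[:, 0]
    try:
        memberships, centers = fuzzy_cmeans(coords, c=3, seed=seed)
    except ValueError as exc:
        return InversionCall(
            inversion_id=inversion_id, chrom=pca.chrom, component=component,
            region=region, calls=[], inv_maf=float("nan"),
            f_index=float("nan"), retained=False, reason=str(exc))
    calls, retained, reason = call_karyotypes(
        gm.sample_ids, inversion_id, memberships, centers, coords,
        min_cluster_size=min_cluster_size,
        min_mean_membership=min_mean_membership,
        spacing_window=spacing_window)
    inv_maf, f_index = inversion_summary(calls)
    return InversionCall(
        inversion_id=inversion_id, chrom=pca.chrom, component=component,
        region=region, calls=calls, inv_maf=inv_maf, f_index=f_index,
        retained=retained, reason=reason, centers=centers)
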