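"""Recovery metrics against simulation truth.

Karyotype calls and simulated truth are compared up to arrangement
orientation (the pipeline's AA/BB labelling is frequency-based, so the
truth coding may be flipped); interval estimates are compared by Jaccard
overlap.
"""

from __future__ import annotations

import numpy as np

from .karyotyping import GENOTYPE_CODE, InversionCall


def karyotype_concordance(inv: InversionCall, truth_karyotypes: np.ndarray,
                          sample_ids: list[str]) -> float:
    """Fraction of samples whose call matches truth, orientation-aligned.

    ``truth_karyotypes`` is the per-sample inverted-haplotype count (0/1/2)
    indexed like ``sample_ids`` (the simulator's sample order).  The better
    of the direct and flipped (0<->2) codings is scored, since arrangement
    labels are arbitrary.
    """
    index = {sid: i for i, sid in enumerate(sample_ids)}
    called = np.array([GENOTYPE_CODE[c.genotype] for c in inv.calls])
    true = np.array([truth_karyotypes[index[c.sample_id]] for c in inv.calls])
    direct = float((called == true).mean())
    flipped = float((called == 2 - true).mean())
    return max(direct, flipped)


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two closed bp intervals."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0, hi - lo)
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0
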