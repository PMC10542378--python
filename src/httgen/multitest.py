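"""Holm (family-wise) and Benjamini-Hochberg (FDR) p-value adjustment.

Thin validated wrappers over ``statsmodels.stats.multitest``; adjusted
p-values are returned (not accept/reject flags) so thresholds stay
caller-side. Used by the LVM path search (BH across candidate edges) and the
seven-region prediction family (Holm across regions).
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["holm_adjust", "bh_adjust"]


def _validate(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d family of p-values")
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    return p


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    adjusted_(i) = min(1, max_{j<=i} (m - j + 1) p_(j)) on the sorted family.
    """
    p = _validate(pvalues)
    return multipletests(p, method="holm")[1]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j>=i} min(1, m p_(j) / j) on the sorted family.
    """
    p = _validate(pvalues)
    return multipletests(p, method="fdr_bh")[1]
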