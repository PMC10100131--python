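"""Small shared statistics helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, 1 df, no continuity correction.

    The uncorrected form is used throughout for baseline-characteristics count
    comparisons (Yates' correction would change the reported p-values).

    Parameters
    ----------
    table : array-like, shape (2, 2)
        Nonnegative integer counts.

    Returns
    -------
    (statistic, p_value)
        The Pearson statistic and its chi-square(1) upper-tail p-value.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square test undefined: a marginal total is zero")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
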