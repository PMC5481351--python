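"""Heaps-law and Zipf-law fitting of FSF vocabulary scaling.

Across proteomes, vocabulary size V (FSF use) grows as a sublinear power of
database size N (FSF reuse): V ~ N^beta with beta < 1 ("economies of
scale").  Each supergroup follows its own regime: exponents decrease from
viruses (near-kernel vocabularies, beta toward 1) through Archaea and
Bacteria to Eukarya (beta toward 0).  Fits are ordinary least squares of
log10 V on log10 N; within a proteome, the rank-frequency distribution of
FSF abundances follows a Zipf law P(k) ~ k^-gamma, related to Heaps
scaling by beta = 1/gamma under asymptotic conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HeapsFit", "ZipfFit", "heaps_fit", "fit_regimes", "zipf_fit"]

REGIME_ORDER = ("V", "A", "B", "E")


@dataclass
class HeapsFit:
    group: Optional[str]
    beta: float
    intercept: float
    r_squared: float
    f_statistic: float  # F(1, n-2); inf when the fit is exact
    p_value: float
    n: int
    stderr: float
    n_excluded_zero_use: int = 0


@dataclass
class ZipfFit:
    gamma: float
    r_squared: float
    n: int
    fit_range: tuple


def _ols_loglog(x: np.ndarray, y: np.ndarray):
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    n = len(x)
    r2 = res.rvalue**2
    if r2 >= 1.0 - 1e-14:
        f = np.inf
        r2 = 1.0
    else:
        f = r2 * (n - 2) / (1.0 - r2)
    return res, r2, f, n


def heaps_fit(use_reuse_table: pd.DataFrame, group: Optional[str] = None) -> HeapsFit:
    """OLS of log10(use) on log10(reuse), optionally within one supergroup."""
    table = use_reuse_table
    if group is not None:
        table = table[table["group"] == group]
    positive = (table["use"] >= 1) & (table["reuse"] >= 1)
    excluded = int((~positive).sum())
    table = table[positive]
    if len(table) < 3:
        raise ValueError(
            f"need >= 3 taxa with use >= 1 and reuse >= 1 (group {group!r}, "
            f"have {len(table)})"
        )
    res, r2, f, n = _ols_loglog(
        table["reuse"].to_numpy(float), table["use"].to_numpy(float)
    )
    return HeapsFit(
        group=group,
        beta=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        f_statistic=float(f),
        p_value=float(res.pvalue),
        n=n,
        stderr=float(res.stderr),
        n_excluded_zero_use=excluded,
    )


def fit_regimes(
    use_reuse_table: pd.DataFrame, order: Sequence[str] = REGIME_ORDER
) -> dict:
    """Per-group Heaps fits plus a report on the exponent ordering.

    The biological expectation is a monotone decrease of beta along the
    regime order viruses > Archaea > Bacteria > Eukarya.
    """
    present = [g for g in order if (use_reuse_table["group"] == g).any()]
    if len(present) < 1:
        raise ValueError("no recognized group present in table")
    fits = {g: heaps_fit(use_reuse_table, group=g) for g in present}
    betas = [fits[g].beta for g in present]
    monotone = all(b1 > b2 for b1, b2 in zip(betas, betas[1:]))
    return {
        "fits": fits,
        "order": present,
        "betas": dict(zip(present, betas)),
        "monotone_decreasing": monotone,
    }


def zipf_fit(abundances: Sequence[float], min_nonzero: int = 10) -> ZipfFit:
    """Rank-frequency power-law exponent of one abundance vector.

    OLS of log10(frequency) on log10(rank) over nonzero entries;
    gamma = -slope.
    """
    a = np.asarray(abundances, dtype=float)
    a = np.sort(a[a > 0])[::-1]
    if len(a) < min_nonzero:
        raise ValueError(f"need at least {min_nonzero} nonzero abundances, have {len(a)}")
    ranks = np.arange(1, len(a) + 1, dtype=float)
    res, r2, _, n = _ols_loglog(ranks, a)
    return ZipfFit(
        gamma=float(-res.slope),
        r_squared=float(r2),
        n=n,
        fit_range=(1, len(a)),
    )
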