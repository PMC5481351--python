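"""Evolutionary principal coordinates (evoPCO) of proteomes in FSF-age space.

An FSF occurrence (use) matrix is weighted by domain age: entry (taxon,
FSF) becomes occurrence * (1 - nd), where nd in [0, 1] is the fold
superfamily's node-distance age from a tree of domains (0 = most ancient).
Ancient FSFs therefore contribute close to 1 when present, recent ones close
to 0, and absences exactly 0.  Classical PCoA (Euclidean distances, Gower
double-centering, eigendecomposition) then lays the proteomes out in a few
axes; an optional reconstructed-ancestor row gives the plot its direction of
evolutionary change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["EvoPCOResult", "age_weight", "evo_pcoa", "trace_evopco_vs_reuse"]


@dataclass
class EvoPCOResult:
    coordinates: pd.DataFrame  # taxa x axes ("PCo1", ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    explained: np.ndarray  # variance fractions of returned axes (over positive eigenvalues)
    metadata: dict = field(default_factory=dict)


def age_weight(
    occurrence: pd.DataFrame,
    fsf_ages: "pd.Series | dict",
    abundance_weighted: bool = False,
) -> pd.DataFrame:
    """Transform an occurrence matrix into occurrence * (1 - nd).

    `occurrence` is taxa x FSF; nonzero entries count as presence unless
    `abundance_weighted` is set, in which case raw abundances are used
    (off by default: the ordination is defined on occurrence).
    """
    ages = pd.Series(fsf_ages, dtype=float)
    missing = [c for c in occurrence.columns if c not in ages.index]
    if missing:
        raise KeyError(f"FSFs without an age: {missing}")
    bad = ages[(ages < 0) | (ages > 1)]
    if len(bad):
        raise ValueError(f"nd ages outside [0, 1]: {list(bad.index)}")
    base = occurrence if abundance_weighted else (occurrence > 0).astype(float)
    weights = (1.0 - ages[occurrence.columns]).to_numpy()
    return base.astype(float) * weights[None, :]


def evo_pcoa(X: pd.DataFrame, k: int = 3) -> EvoPCOResult:
    """Classical (metric) PCoA of the rows of X under Euclidean distance.

    B = -1/2 * J D^2 J (Gower double-centering) is eigendecomposed;
    coordinates are eigenvectors scaled by sqrt(eigenvalue), ordered by
    decreasing eigenvalue.  Sign convention: the largest-magnitude
    coordinate on each axis is positive.  Explained-variance fractions are
    taken over the positive eigenvalues only.
    """
    if X.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 rows")
    if not 1 <= k <= X.shape[0] - 1:
        raise ValueError(f"k must be in [1, {X.shape[0] - 1}]")
    D = squareform(pdist(X.to_numpy(dtype=float), metric="euclidean"))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-12
    coords = np.zeros((n, k))
    for j in range(k):
        if eigvals[j] > 0:
            axis = eigvecs[:, j] * np.sqrt(eigvals[j])
            if axis[np.argmax(np.abs(axis))] < 0:
                axis = -axis
            coords[:, j] = axis
    total_pos = eigvals[pos].sum()
    explained = np.where(eigvals[:k] > 0, eigvals[:k] / total_pos, 0.0)
    return EvoPCOResult(
        coordinates=pd.DataFrame(
            coords, index=X.index, columns=[f"PCo{j + 1}" for j in range(k)]
        ),
        eigenvalues=eigvals,
        explained=explained,
        metadata={"n": n, "metric": "euclidean",
                  "negative_eigenvalues_excluded": int((~pos & (eigvals < 0)).sum())},
    )


def trace_evopco_vs_reuse(
    result: EvoPCOResult,
    use_reuse_table: pd.DataFrame,
    ancestor_label: Optional[str] = None,
) -> pd.DataFrame:
    """Per-taxon (PCo1, log10 reuse, group); the ancestor row is flagged."""
    if "PCo1" not in result.coordinates.columns:
        raise ValueError("result has no first principal coordinate")
    table = use_reuse_table.set_index("taxon")
    if ancestor_label is not None and ancestor_label not in result.coordinates.index:
        raise KeyError(f"ancestor label {ancestor_label!r} not among coordinates")
    rows = []
    for taxon in result.coordinates.index:
        is_anc = taxon == ancestor_label
        if taxon not in table.index and not is_anc:
            continue
        reuse = float(table.loc[taxon, "reuse"]) if taxon in table.index else np.nan
        rows.append(
            {
                "taxon": taxon,
                "pco1": float(result.coordinates.loc[taxon, "PCo1"]),
                "log10_reuse": np.log10(reuse) if reuse and reuse > 0 else np.nan,
                "group": table.loc[taxon, "group"] if taxon in table.index else "ancestor",
                "is_ancestor": is_anc,
            }
        )
    return pd.DataFrame(rows)
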