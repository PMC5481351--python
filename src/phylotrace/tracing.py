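"""Node-distance timelines and size-vs-time tracing.

The node distance (nd) of a node in a rooted tree is the number of internal
nodes on the path from the root (root counted), min-max normalized over the
target nodes to [0, 1]: 0 = most basal, 1 = most derived.  Applied to the
leaves of a tree of life it orders proteomes on a relative evolutionary
time axis; applied to a tree of domains it dates fold superfamilies.
Size-vs-nd tracing joins the timeline with per-taxon FSF use/reuse and
smooths the relationship with robust LOWESS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from phylotrace.trees import Phylogeny

__all__ = ["Timeline", "LowessParams", "node_distances", "trace_size_vs_nd"]


@dataclass
class Timeline:
    nd: pd.Series  # node label -> nd in [0, 1]
    raw: pd.Series  # node label -> internal-node count from the root
    constant_depth: bool = False  # all depths equal; nd set to 0 and flagged


@dataclass
class LowessParams:
    """Smoothing window fraction q and robustifying iterations i."""

    q: float = 0.1
    i: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if self.i < 0:
            raise ValueError("i must be >= 0")


def node_distances(tree: Phylogeny, target: str = "leaves") -> Timeline:
    """Normalized root-to-node internal-node counts for leaves or internals."""
    if not tree.rooted:
        raise ValueError("node distances require a rooted tree")
    if target not in ("leaves", "internal"):
        raise ValueError("target must be 'leaves' or 'internal'")
    raw: dict[str, int] = {}
    depth: dict[int, int] = {}
    internal_counter = 0
    for node in tree.preorder():
        if node.parent is None:
            depth[id(node)] = 1  # the root is an internal node and is counted
        else:
            inc = 0 if node.is_leaf else 1
            depth[id(node)] = depth[id(node.parent)] + inc
        if node.is_leaf:
            if target == "leaves":
                raw[node.label] = depth[id(node)]
        else:
            if target == "internal":
                label = node.label or f"n{internal_counter}"
                raw[label] = depth[id(node)]
            internal_counter += 1
    raw_s = pd.Series(raw, dtype=float).sort_index()
    lo, hi = raw_s.min(), raw_s.max()
    if hi == lo:
        return Timeline(nd=raw_s * 0.0, raw=raw_s, constant_depth=True)
    return Timeline(nd=(raw_s - lo) / (hi - lo), raw=raw_s, constant_depth=False)


def trace_size_vs_nd(
    timeline: Timeline,
    use_reuse_table: pd.DataFrame,
    params: Optional[LowessParams] = None,
) -> dict:
    """Join a leaf timeline with FSF use/reuse and smooth both with LOWESS.

    Returns ``{"table": per-taxon (nd, use, reuse, group),
    "smoothed": {"use": ..., "reuse": ...}}`` where each smoothed frame holds
    the LOWESS curve (tricube-weighted local linear fits with bisquare
    robustifying reweights) evaluated at the observed nd values.
    """
    params = params or LowessParams()
    tl_leaves = set(timeline.nd.index)
    tab_leaves = set(use_reuse_table["taxon"])
    if tl_leaves != tab_leaves:
        raise ValueError(
            "timeline/table leaf mismatch; only in timeline: "
            f"{sorted(tl_leaves - tab_leaves)}, only in table: "
            f"{sorted(tab_leaves - tl_leaves)}"
        )
    table = use_reuse_table.copy()
    table["nd"] = table["taxon"].map(timeline.nd)
    table = table.sort_values(["nd", "taxon"]).reset_index(drop=True)
    smoothed = {}
    for col in ("use", "reuse"):
        fitted = _sm_lowess(
            table[col].to_numpy(dtype=float),
            table["nd"].to_numpy(dtype=float),
            frac=params.q,
            it=params.i,
            return_sorted=False,
        )
        smoothed[col] = pd.DataFrame({"nd": table["nd"], col: fitted})
    return {"table": table, "smoothed": smoothed}
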