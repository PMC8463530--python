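"""Signed -log10(p) evidence matrices and their hierarchical clustering.

Each cell combines effect direction and strength as
sign(effect) * -log10(p), with p from a two-sided normal test of
effect/se and floored at a configurable truncation (1e-16 for heatmap
exports, 1e-60 for the clustering matrix, where the deeper floor preserves
contrast among extremely significant lipid effects).  For a p-value of 0.05
the magnitude is -log10(0.05) ~= 1.3, corresponding to |z| = 1.96.
Clustering operates on sign(v) * sqrt(|v|), compressing the dynamic range
before agglomeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

#: p-value floors used for the two export styles
HEATMAP_FLOOR = 1e-16
CLUSTER_FLOOR = 1e-60


def signed_logp(effect: float, se: float, floor: float = CLUSTER_FLOOR) -> float:
    """Direction-signed evidence score sign(effect) * -log10(p).

    p is the two-sided normal tail of z = effect/se, truncated below at
    ``floor``; a zero effect maps to exactly 0.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0 < floor < 1):
        raise ValueError("floor must be in (0, 1)")
    if effect == 0:
        return 0.0
    z = effect / se
    p = 2 * stats.norm.sf(abs(z))
    p = max(p, floor)
    return math.copysign(-math.log10(p), effect)


@dataclass
class EvidenceMatrix:
    """Outcomes x evidence-sources grid of signed -log10(p) values.

    ``values`` is a DataFrame (rows = outcome labels, columns = source
    labels); ``mask`` marks missing cells.  Rows with any missing cell are
    excluded from clustering but retained for heatmap export.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    floor: float
    dropped_rows: list[str] = field(default_factory=list)

    @property
    def clusterable(self) -> pd.DataFrame:
        return self.values.loc[~self.mask.any(axis=1)]


def build_evidence_matrix(
    sources: dict[str, dict[str, tuple[float, float]]],
    outcome_whitelist: list[str] | None = None,
    floor: float = CLUSTER_FLOOR,
) -> EvidenceMatrix:
    """Assemble the evidence grid from oriented (effect, se) pairs.

    ``sources`` maps a source label (an MR target estimate or a compound's
    pooled trial estimate) to {outcome: (effect, se)}; all effects must
    already be oriented to the canonical drug-target direction.  Rows are
    the union of outcomes across sources (optionally restricted to a
    whitelist); an outcome absent from some source is masked there and the
    row is dropped from the clusterable submatrix.
    """
    if not sources:
        raise ValueError("no evidence sources supplied")
    cols = list(sources)
    outcomes: list[str] = []
    for s in cols:
        for o in sources[s]:
            if o not in outcomes:
                outcomes.append(o)
    if outcome_whitelist is not None:
        outcomes = [o for o in outcomes if o in outcome_whitelist]
    if not outcomes:
        raise ValueError("no outcomes shared with the whitelist")

    vals = pd.DataFrame(np.nan, index=outcomes, columns=cols, dtype=float)
    for s in cols:
        for o, (effect, se) in sources[s].items():
            if o in vals.index:
                vals.loc[o, s] = signed_logp(effect, se, floor)
    mask = vals.isna()
    dropped = list(vals.index[mask.any(axis=1)])
    return EvidenceMatrix(values=vals, mask=mask, floor=floor, dropped_rows=dropped)


def sqrt_signed(v: np.ndarray) -> np.ndarray:
    """Signed square root sign(v) * sqrt(|v|)."""
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.sqrt(np.abs(v))


@dataclass
class ClusterResult:
    """Row/column merge trees (scipy linkage form) and leaf orders."""

    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]
    col_order: list[str]
    transformed: pd.DataFrame

    def row_newick(self) -> str:
        return _to_newick(self.row_linkage, self.row_order_input)

    def col_newick(self) -> str:
        return _to_newick(self.col_linkage, self.col_order_input)

    row_order_input: list[str] = field(default_factory=list)
    col_order_input: list[str] = field(default_factory=list)


def cluster_matrix(
    m: EvidenceMatrix,
    transform: str = "sqrt_signed",
    metric: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of the evidence matrix, rows and columns.

    ``transform`` is ``sqrt_signed`` (the default; compresses the signed
    log-p range) or ``none``.  A single row or column yields a degenerate
    (empty) tree rather than an error.
    """
    if transform not in ("sqrt_signed", "none"):
        raise ValueError("transform must be sqrt_signed or none")
    sub = m.clusterable
    if sub.empty:
        raise ValueError("no fully observed rows to cluster")
    data = sub.to_numpy(dtype=float)
    if transform == "sqrt_signed":
        data = sqrt_signed(data)
    tdf = pd.DataFrame(data, index=sub.index, columns=sub.columns)

    def _link(x: np.ndarray, labels: list[str]):
        if x.shape[0] < 2:
            return None, list(labels)
        Z = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
        order = [labels[i] for i in hierarchy.leaves_list(Z)]
        return Z, order

    row_Z, row_order = _link(data, list(sub.index))
    col_Z, col_order = _link(data.T, list(sub.columns))
    return ClusterResult(
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=row_order,
        col_order=col_order,
        transformed=tdf,
        row_order_input=list(sub.index),
        col_order_input=list(sub.columns),
    )


def _to_newick(Z: np.ndarray | None, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    if Z is None:
        return (labels[0] + ";") if labels else ";"
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return rec(tree, tree.dist) + ";"


def write_matrix(m: EvidenceMatrix, path) -> None:
    """Tab-delimited export of the full matrix (masked cells empty)."""
    m.values.to_csv(path, sep="\t", na_rep="")
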