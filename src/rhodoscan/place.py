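"""Nearest-leaf assignment of recruited PR reads and cluster aggregation.

A recruited read carries its aligned residue per profile match column.  It is
compared against every reference leaf over the match columns both cover; the
best leaf by identity wins when enough columns were compared and the identity
margin to the runner-up is positive.  Ambiguous reads (margin below
threshold — the analogue of reads that would land on internal tree nodes)
are left unplaced and excluded from cluster fractions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recruit import RecruitedRead
from .refdata import OTHER_CLUSTER, CladeTree, ReferenceAlignment, match_columns


@dataclass
class LeafAssignment:
    read_id: str
    leaf_id: str | None  # None = UNPLACED
    identity: float
    margin: float
    n_compared: int
    reason: str = ""  # set when unplaced

    @property
    def placed(self) -> bool:
        return self.leaf_id is not None


class LeafMatrix:
    """Reference rows restricted to profile match columns, integer-coded."""

    def __init__(
        self,
        aln: ReferenceAlignment,
        leaf_ids: list[str] | None = None,
        max_gap_fraction: float = 0.5,
    ):
        cols = match_columns(aln, max_gap_fraction)
        full = aln.to_matrix()[:, cols]
        if leaf_ids is None:
            leaf_ids = list(aln.ids)
        missing = [l for l in leaf_ids if l not in aln.ids]
        if missing:
            raise ValueError(f"leaves {missing} not found in the reference alignment")
        rows = [aln.ids.index(l) for l in leaf_ids]
        self.leaf_ids = list(leaf_ids)
        self.mat = np.ascontiguousarray(full[rows])  # (n_leaves, L), gap = -1


def assign_leaf(
    read: RecruitedRead,
    aln: ReferenceAlignment | LeafMatrix,
    min_cols: int = 20,
    min_margin: float = 0.01,
    leaf_ids: list[str] | None = None,
) -> LeafAssignment:
    """Assign one recruited read to its nearest reference leaf.

    Identity is matches / compared over match columns inside the read's
    aligned span where at least one of read and leaf holds a residue; a read
    gap against a leaf residue (or vice versa) counts as a mismatch, columns
    gapped in both are skipped.  The read is UNPLACED when fewer than
    ``min_cols`` columns were compared for every leaf, or when the identity
    margin to the second-best leaf is below ``min_margin``.
    """
    lm = aln if isinstance(aln, LeafMatrix) else LeafMatrix(aln, leaf_ids)
    r = read.res_codes
    in_span = r > -2
    if not in_span.any():
        return LeafAssignment(read.read_id, None, 0.0, 0.0, 0, reason="no_overlap")
    leaf = lm.mat[:, : r.shape[0]]
    both_gap = (r == -1) & (leaf == -1)
    compared = (in_span & ~both_gap).sum(axis=1)
    matches = (in_span & (r >= 0) & (r == leaf)).sum(axis=1)
    eligible = compared >= min_cols
    if not eligible.any():
        return LeafAssignment(
            read.read_id, None, 0.0, 0.0, int(compared.max()), reason="few_columns"
        )
    identity = np.where(eligible, matches / np.maximum(compared, 1), -1.0)
    best = int(identity.argmax())
    best_id = float(identity[best])
    if eligible.sum() > 1:
        second = np.partition(identity[eligible], -2)[-2]
        margin = best_id - float(second)
    else:
        margin = 1.0
    if margin < min_margin:
        return LeafAssignment(
            read.read_id, None, best_id, margin, int(compared[best]), reason="low_margin"
        )
    return LeafAssignment(
        read.read_id, lm.leaf_ids[best], best_id, margin, int(compared[best])
    )


def assign_reads(
    reads: list[RecruitedRead],
    aln: ReferenceAlignment,
    min_cols: int = 20,
    min_margin: float = 0.01,
    leaf_ids: list[str] | None = None,
) -> list[LeafAssignment]:
    """Vectorized :func:`assign_leaf` over a read set (one shared LeafMatrix)."""
    lm = LeafMatrix(aln, leaf_ids)
    return [assign_leaf(r, lm, min_cols, min_margin) for r in reads]


@dataclass
class ClusterTable:
    """Per-cluster counts and fractions over placed reads."""

    table: pd.DataFrame  # columns: cluster, count, fraction
    n_placed: int
    n_unplaced: int

    @property
    def all_unplaced(self) -> bool:
        return self.n_placed == 0

    def fraction(self, cluster: str) -> float:
        sub = self.table[self.table["cluster"] == cluster]
        return float(sub["fraction"].iloc[0]) if len(sub) else 0.0


def aggregate_clusters(
    assignments: list[LeafAssignment], tree: CladeTree
) -> ClusterTable:
    """Aggregate leaf assignments to cluster counts and fractions.

    Unplaced reads are excluded; leaves missing from the cluster map are
    counted under ``other`` with a warning.  An empty (all-unplaced) table is
    returned with the ``all_unplaced`` flag set rather than raising.
    """
    counts: dict[str, int] = {}
    n_placed = 0
    n_unplaced = 0
    known = set(tree.cluster_map)
    for a in assignments:
        if not a.placed:
            n_unplaced += 1
            continue
        n_placed += 1
        if a.leaf_id not in known:
            warnings.warn(
                f"leaf '{a.leaf_id}' absent from cluster map, counted as "
                f"'{OTHER_CLUSTER}'",
                stacklevel=2,
            )
            cluster = OTHER_CLUSTER
        else:
            cluster = tree.cluster_map[a.leaf_id]
        counts[cluster] = counts.get(cluster, 0) + 1
    rows = sorted(counts.items())
    table = pd.DataFrame(rows, columns=["cluster", "count"])
    table["fraction"] = table["count"] / n_placed if n_placed else np.nan
    return ClusterTable(table=table, n_placed=n_placed, n_unplaced=n_unplaced)


def leaf_counts(assignments: list[LeafAssignment]) -> dict[str, int]:
    """Placed-read counts per leaf (the tree-tip resolution of aggregation)."""
    out: dict[str, int] = {}
    for a in assignments:
        if a.placed:
            out[a.leaf_id] = out.get(a.leaf_id, 0) + 1
    return dict(sorted(out.items()))
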