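"""16S rRNA pairwise similarity and neighbor-joining distance trees.

The marker similarity is a semi-global alignment (terminal gaps free,
match +1 / mismatch -1 / gap -2).  Terminal gap columns are excluded from
the compared length; internal gap columns count toward the compared length
but toward neither matches nor differences, so

    similarity% = 100 * matches / aligned_len
    aligned_len = matches + n_differences + internal_gap_columns.

Neighbor joining is the classical agglomeration; it reproduces additive
matrices exactly.  Trees are scikit-bio ``TreeNode`` objects, so Newick
serialization and Robinson-Foulds comparison come for free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from skbio import TreeNode

from .genome_io import AMBIGUOUS_NT

logger = logging.getLogger("taxg")


@dataclass
class MarkerSimilarity:
    similarity_percent: float
    n_differences: int
    aligned_len: int
    internal_gap_columns: int

    @property
    def n_matches(self) -> int:
        return self.aligned_len - self.n_differences - self.internal_gap_columns


def _marker_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    try:  # biopython >= 1.86 naming
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # pragma: no cover - older biopython
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def pairwise_global_identity(a: str, b: str) -> MarkerSimilarity:
    """Marker similarity from a semi-global pairwise alignment.

    Symmetric in its arguments.  Warns when either sequence carries more
    than 5% ambiguous bases (ambiguity columns are scored as differences).
    """
    a = a.upper()
    b = b.upper()
    if not a or not b:
        raise ValueError("empty marker sequence")
    if len(a) < 100 or len(b) < 100:
        warnings.warn("marker sequences shorter than 100 bp", stacklevel=2)
    for name, seq in (("first", a), ("second", b)):
        n_amb = sum(seq.count(c) for c in AMBIGUOUS_NT)
        if n_amb > 0.05 * len(seq):
            warnings.warn(
                f"{name} sequence has {n_amb}/{len(seq)} ambiguous bases",
                stacklevel=2,
            )
    alignment = _marker_aligner().align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    # strip terminal gap columns (gap runs touching either end)
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    matches = diffs = gaps = 0
    for ca, cb in zip(row_a[start:end], row_b[start:end]):
        if ca == "-" or cb == "-":
            gaps += 1
        elif ca == cb and ca not in AMBIGUOUS_NT:
            matches += 1
        else:
            diffs += 1
    aligned_len = end - start
    if aligned_len == 0:
        raise ValueError("alignment has no compared columns")
    return MarkerSimilarity(
        similarity_percent=100.0 * matches / aligned_len,
        n_differences=diffs,
        aligned_len=aligned_len,
        internal_gap_columns=gaps,
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: pd.DataFrame | np.ndarray, labels=None) -> TreeNode:
    """Classical neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch (the joined pair's total is preserved); ties in the
    Q criterion break on the smallest row index, so the result is
    deterministic.  On an additive matrix the tree's patristic distances
    reproduce the input exactly.
    """
    if isinstance(dm, pd.DataFrame):
        labels = list(dm.index)
        d = dm.to_numpy(dtype=float)
    else:
        d = np.asarray(dm, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(d))]
    n = len(d)
    if n < 3:
        raise ValueError(">= 3 taxa required")
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if np.abs(d - d.T).max() > 1e-9:
        raise ValueError("distance matrix not symmetric (tolerance 1e-9)")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest-row-index tie-break: argmin on the flattened row-major array
        flat = int(np.argmin(q))
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        i_g, j_g = active[i_loc], active[j_loc]
        child_i, child_j = nodes[i_g], nodes[j_g]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k_loc, k_g in enumerate(active):
            if k_loc in (i_loc, j_loc):
                continue
            duk = 0.5 * (sub[i_loc, k_loc] + sub[j_loc, k_loc] - dij)
            d[u, k_g] = d[k_g, u] = duk
        nodes.append(parent)
        active = [g for g in active if g not in (i_g, j_g)] + [u]
    # connect the last three nodes to a central (unrooted) vertex
    x, y, z = active
    dxy, dxz, dyz = d[x, y], d[x, z], d[y, z]
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    lengths = [max(v, 0.0) for v in (lx, ly, lz)]
    for node, length in zip((nodes[x], nodes[y], nodes[z]), lengths):
        node.length = float(length)
    root = TreeNode(children=[nodes[x], nodes[y], nodes[z]])
    return root


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> float:
    """Unrooted Robinson-Foulds distance between two trees."""
    return t1.compare_rfd(t2, rooted=False)


def write_newick(tree: TreeNode, path: str | Path, decimals: int = 6) -> None:
    """Serialize to Newick with branch lengths rounded to *decimals*."""
    tree = tree.copy()
    for node in tree.traverse():
        if node.length is not None:
            node.length = round(node.length, decimals)
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
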