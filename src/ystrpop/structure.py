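"""Population-structure summaries of an Rst matrix: classical MDS and NJ.

Classical (Torgerson) metric MDS double-centers the squared-distance matrix,
eigendecomposes it, and uses the top-k eigenpairs as coordinates; it is exact
on Euclidean-realizable inputs and fully deterministic, which is why it is
used here rather than an iterative stress-majorization variant.  A normalized
residual stress is reported so goodness of fit can be judged.

Neighbor-Joining uses the canonical Q-matrix agglomeration with deterministic
tie-breaking (lowest label-index pair) and the usual handling of negative
branch lengths (clamped to zero, the deficit moved to the sibling edge).  On
an additive matrix it recovers the generating topology and branch lengths
exactly.  Trees are skbio ``TreeNode`` objects and serialize to Newick.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .distance import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "classical_mds",
    "neighbor_joining",
    "to_newick",
    "from_newick",
]


@dataclass(frozen=True)
class OrdinationResult:
    """MDS embedding: centered coordinates, eigenvalues (descending), stress."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n_labels, k)
    eigenvalues: np.ndarray  # all n eigenvalues, non-increasing
    stress: float


def classical_mds(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson metric MDS of a distance matrix into ``k`` dimensions.

    Negative eigenvalues (non-Euclidean part of the input) are truncated to
    zero for coordinates.  Eigenvector signs are fixed by making the first
    nonzero component of each used axis positive, so runs are reproducible.
    Stress is ``sqrt(sum (d - d_hat)^2 / sum d^2)`` over off-diagonal pairs.
    """
    m = len(d.labels)
    if k >= m:
        raise ValueError(f"k={k} must be smaller than the number of labels ({m})")
    sq = d.values**2
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ sq @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    coords = np.zeros((m, k))
    for axis in range(k):
        lam = eigval[axis]
        if lam <= 0:
            continue
        v = eigvec[:, axis]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            v = -v
        coords[:, axis] = v * np.sqrt(lam)
    coords = coords - coords.mean(axis=0, keepdims=True)

    recon = np.sqrt(
        np.maximum(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2), 0.0
        )
    )
    denom = (d.values**2).sum()
    stress = float(np.sqrt(((d.values - recon) ** 2).sum() / denom)) if denom > 0 else 0.0
    return OrdinationResult(
        labels=d.labels, coordinates=coords, eigenvalues=eigval, stress=stress
    )


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: zero it and move the deficit to the sibling edge
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    elif lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Neighbor-Joining tree from a distance matrix (>= 3 labels).

    Ties in the Q matrix are broken by the lowest (row, column) index pair in
    current label order, so the build is deterministic.  The returned tree is
    unrooted, represented with a trifurcating root.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 labels")
    dist = d.values.astype(float).copy()
    nodes = [TreeNode(name=label) for label in d.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        q = (m - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = (np.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] < best[0] - 1e-15:
                    best = (q[i, j], i, j)
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        new = TreeNode(children=[child_i, child_j])

        new_dist = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        reduced = np.empty((m - 1, m - 1))
        reduced[:-1, :-1] = dist[np.ix_(keep, keep)]
        reduced[-1, :-1] = reduced[:-1, -1] = new_dist[keep]
        reduced[-1, -1] = 0.0
        dist = reduced
        nodes = [nodes[x] for x in keep] + [new]

    # final three-point join
    a, b, c = nodes
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    la = max(0.0, 0.5 * (dab + dac - dbc))
    lb = max(0.0, 0.5 * (dab + dbc - dac))
    lc = max(0.0, 0.5 * (dac + dbc - dab))
    for node, length in zip((a, b, c), (la, lb, lc)):
        node.length = float(length)
    root = TreeNode(children=[a, b, c])
    return root


def to_newick(tree: TreeNode) -> str:
    """Serialize to a Newick string with branch lengths."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")
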