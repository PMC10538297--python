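"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's computational shortcuts:
grouping is by pairwise equality instead of hashing, AMOVA sums of squares
are enumerated over every individual pair instead of the centered-sum
identity, and additive matrices are generated from explicit random trees.
"""

from __future__ import annotations

import numpy as np

from ystrpop.model import Haplotype


def brute_group_counts(haplotypes, loci) -> list[int]:
    """Group haplotypes by pairwise equality over ``loci``; return state counts."""
    complete = [h for h in haplotypes if h.is_complete(loci)]
    groups: list[list[Haplotype]] = []
    for h in complete:
        for group in groups:
            rep = group[0]
            if all(h.calls[l] == rep.calls[l] for l in loci):
                group.append(h)
                break
        else:
            groups.append([h])
    return sorted((len(g) for g in groups), reverse=True)


def brute_match_probability(haplotypes, loci) -> float:
    """Fraction of identical ordered pairs (self-pairs included) == sum Pi^2."""
    complete = [h for h in haplotypes if h.is_complete(loci)]
    n = len(complete)
    hits = 0
    for a in complete:
        for b in complete:
            if all(a.calls[l] == b.calls[l] for l in loci):
                hits += 1
    return hits / (n * n)


def brute_amova(mats: list[np.ndarray]) -> dict:
    """Haploid AMOVA components from explicit all-pairs squared distances."""

    def sq(a, b):
        return float(((a - b) ** 2).sum())

    pooled = np.vstack(mats)
    n_total = pooled.shape[0]
    n_pops = len(mats)
    ssd_total = sum(
        sq(pooled[i], pooled[j]) for i in range(n_total) for j in range(i + 1, n_total)
    ) / n_total
    ssd_within = 0.0
    for m in mats:
        n_p = m.shape[0]
        ssd_within += sum(
            sq(m[i], m[j]) for i in range(n_p) for j in range(i + 1, n_p)
        ) / n_p
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = n_total - n_pops
    msd_within = ssd_within / df_within
    msd_among = ssd_among / df_among
    sizes = np.array([m.shape[0] for m in mats], dtype=float)
    n0 = (n_total - (sizes**2).sum() / n_total) / df_among
    sigma2_within = msd_within
    sigma2_among = (msd_among - msd_within) / n0
    denom = sigma2_among + sigma2_within
    rst = sigma2_among / denom if denom > 0 else (1.0 if sigma2_among > 0 else 0.0)
    return {
        "ssd_total": ssd_total,
        "ssd_within": ssd_within,
        "ssd_among": ssd_among,
        "n0": n0,
        "sigma2_among": sigma2_among,
        "sigma2_within": sigma2_within,
        "rst": rst,
    }


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with positive branch lengths and its leaf distance matrix.

    Returns (labels, matrix, newick).  Pairwise distances are accumulated
    during the agglomerative construction, so the matrix is additive by
    construction and Neighbor-Joining must recover topology and branch
    lengths exactly.
    """
    labels = [f"T{i}" for i in range(n_leaves)]
    index = {label: i for i, label in enumerate(labels)}
    dist = np.zeros((n_leaves, n_leaves))
    # each active node: (newick fragment, {leaf: distance from leaf to node})
    nodes: list[tuple[str, dict[str, float]]] = [
        (label, {label: 0.0}) for label in labels
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (ni, di), (nj, dj) = nodes[i], nodes[j]
        li = round(float(rng.uniform(0.5, 2.0)), 3)
        lj = round(float(rng.uniform(0.5, 2.0)), 3)
        for leaf_a, da in di.items():
            for leaf_b, db in dj.items():
                d = da + li + db + lj
                dist[index[leaf_a], index[leaf_b]] = d
                dist[index[leaf_b], index[leaf_a]] = d
        merged = {leaf: d + li for leaf, d in di.items()}
        merged.update({leaf: d + lj for leaf, d in dj.items()})
        fragment = f"({ni}:{li},{nj}:{lj})"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((fragment, merged))
    newick = nodes[0][0] + ";"
    return labels, dist, newick
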