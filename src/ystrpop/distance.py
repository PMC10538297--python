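"""Pairwise Rst between populations via haploid AMOVA.

Rst is the microsatellite analogue of Fst: molecular variance is partitioned
within and among populations using squared repeat-count differences as the
distance kernel, and Rst = sigma2_among / (sigma2_among + sigma2_within).
Sums of squared deviations follow the standard haploid AMOVA layout:

    SSD_total  = (1/N)  * sum over all pairs of d_ij
    SSD_within = sum over populations p of (1/n_p) * sum of within-p pairs
    SSD_among  = SSD_total - SSD_within

with MSD = SSD/df, sigma2_within = MSD_within, and
sigma2_among = (MSD_among - MSD_within)/n0 where
n0 = (N - sum n_p^2 / N)/(P - 1).

Only single-copy STR loci enter the kernel: a repeat difference is undefined
for the unordered allele multiset of a multi-copy locus, and InDels are not
repeats.  Microvariant fractions are used numerically (14.1 vs 14 differs by
0.1).  Individuals with a missing or multi-allele call at any included locus
are dropped listwise for that comparison.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Haplotype, PopulationSample

__all__ = [
    "VarianceComponents",
    "DistanceMatrix",
    "haplotype_sq_distance",
    "repeat_matrix",
    "amova_rst",
    "pairwise_rst",
    "rst_permutation_p",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Haploid AMOVA decomposition and the derived Rst."""

    ssd_total: float
    ssd_within: float
    ssd_among: float
    df_among: int
    df_within: int
    n0: float
    sigma2_among: float
    sigma2_within: float
    rst: float

    @property
    def rst_clamped(self) -> float:
        """Rst floored at zero, for use as a dissimilarity."""
        return max(0.0, self.rst)


def _call_repeat(h: Haplotype, locus: str) -> float:
    call = h.calls.get(locus)
    if call is None:
        raise ValueError(f"{h.sample_id}: locus {locus} is missing")
    if call.n_alleles != 1:
        raise ValueError(
            f"{h.sample_id}: multi-allele call {call} at {locus}; exclude this "
            "locus or individual from repeat-difference distances"
        )
    allele = call.alleles[0]
    if allele.value is None:
        raise ValueError(
            f"{h.sample_id}: categorical (InDel) allele at {locus}; "
            "exclude InDel loci from repeat-difference distances"
        )
    return allele.value


def haplotype_sq_distance(h1: Haplotype, h2: Haplotype, loci: Sequence[str]) -> float:
    """Sum over loci of squared repeat differences (microvariants numeric)."""
    return float(
        sum((_call_repeat(h1, l) - _call_repeat(h2, l)) ** 2 for l in loci)
    )


def repeat_matrix(
    sample: PopulationSample, loci: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """(n_usable, n_loci) repeat values, dropping individuals listwise.

    An individual is usable only if it carries a single numeric allele at
    every requested locus.  Returns the matrix and the retained sample ids.
    """
    rows, ids = [], []
    for h in sample.haplotypes:
        try:
            rows.append([_call_repeat(h, l) for l in loci])
        except ValueError:
            continue
        ids.append(h.sample_id)
    return np.asarray(rows, dtype=float).reshape(len(ids), len(loci)), ids


def _ssd_from_centered(x: np.ndarray) -> float:
    # sum_{i<j} d_ij / n  ==  sum_i |x_i - mean|^2, summed over loci
    centered = x - x.mean(axis=0, keepdims=True)
    return float((centered**2).sum())


def amova_rst(
    samples: Sequence[PopulationSample], loci: Sequence[str]
) -> VarianceComponents:
    """Haploid AMOVA over two or more populations at single-copy STR loci.

    Negative Rst (less variance among than within, sampling noise around
    zero differentiation) is reported as computed; use ``rst_clamped`` when a
    non-negative distance is required.
    """
    if len(samples) < 2:
        raise ValueError("AMOVA needs at least two populations")
    if not loci:
        raise ValueError("AMOVA needs at least one locus")
    mats = []
    for s in samples:
        x, _ = repeat_matrix(s, loci)
        if x.shape[0] < 2:
            raise ValueError(
                f"population {s.name}: fewer than 2 usable individuals at "
                f"the requested loci"
            )
        mats.append(x)
    return _amova_from_matrices(mats)


def _amova_from_matrices(mats: Sequence[np.ndarray]) -> VarianceComponents:
    sizes = np.array([m.shape[0] for m in mats], dtype=float)
    n_total = float(sizes.sum())
    n_pops = len(mats)
    pooled = np.vstack(mats)

    ssd_total = _ssd_from_centered(pooled)
    ssd_within = float(sum(_ssd_from_centered(m) for m in mats))
    ssd_among = ssd_total - ssd_within

    df_among = n_pops - 1
    df_within = int(n_total) - n_pops
    msd_among = ssd_among / df_among
    msd_within = ssd_within / df_within if df_within > 0 else float("nan")
    n0 = (n_total - float((sizes**2).sum()) / n_total) / df_among

    sigma2_within = msd_within
    sigma2_among = (msd_among - msd_within) / n0
    denom = sigma2_among + sigma2_within
    rst = sigma2_among / denom if denom > 0 else (1.0 if sigma2_among > 0 else 0.0)

    return VarianceComponents(
        ssd_total=ssd_total,
        ssd_within=ssd_within,
        ssd_among=ssd_among,
        df_among=df_among,
        df_within=df_within,
        n0=n0,
        sigma2_among=sigma2_among,
        sigma2_within=sigma2_within,
        rst=rst,
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled dissimilarity matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.labels)

    # -- square labelled TSV (supplementary-table layout) -------------------
    def to_tsv(self) -> str:
        lines = ["\t".join(["", *self.labels])]
        for label, row in zip(self.labels, self.values):
            lines.append("\t".join([label, *(format(x, ".6g") for x in row)]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        lines = [l for l in text.splitlines() if l.strip()]
        labels = tuple(lines[0].split("\t")[1:])
        values = np.array(
            [[float(x) for x in line.split("\t")[1:]] for line in lines[1:]]
        )
        return cls(labels=labels, values=values)

    # -- PHYLIP square dialect ----------------------------------------------
    def to_phylip(self) -> str:
        buf = io.StringIO()
        buf.write(f"{len(self.labels)}\n")
        for label, row in zip(self.labels, self.values):
            name = label.replace(" ", "_")[:10].ljust(10)
            buf.write(name + "  " + "  ".join(format(x, ".6f") for x in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [l for l in text.splitlines() if l.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels=tuple(labels), values=np.array(rows))


def pairwise_rst(
    samples: Sequence[PopulationSample], loci: Sequence[str]
) -> DistanceMatrix:
    """Matrix of pairwise clamped Rst values between all population pairs."""
    if len(samples) < 2:
        raise ValueError("need at least two populations")
    labels = tuple(s.name for s in samples)
    k = len(samples)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vc = amova_rst([samples[i], samples[j]], loci)
            values[i, j] = values[j, i] = vc.rst_clamped
    return DistanceMatrix(labels=labels, values=values)


def rst_permutation_p(
    sample_a: PopulationSample,
    sample_b: PopulationSample,
    loci: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Permutation p-value for Rst > 0 between two populations.

    Individuals are shuffled across the two labels (sizes preserved) and the
    fraction of permutations with Rst >= observed is returned with the usual
    +1 correction: ``(1 + #{Rst* >= Rst}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    xa, _ = repeat_matrix(sample_a, loci)
    xb, _ = repeat_matrix(sample_b, loci)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("each population needs >= 2 usable individuals")
    observed = _amova_from_matrices([xa, xb]).rst
    pooled = np.vstack([xa, xb])
    na = xa.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        rst = _amova_from_matrices([pooled[perm[:na]], pooled[perm[na:]]]).rst
        if rst >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
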