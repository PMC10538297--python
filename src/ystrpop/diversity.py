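"""Direct-count frequency spectra and forensic diversity statistics.

The statistics are the standard forensic summaries of a haploid marker set:

* gene / haplotype diversity  ``GD = n (1 - sum Pi^2) / (n - 1)`` (Nei's
  unbiased estimator; the same formula serves per-locus alleles and whole
  haplotypes),
* haplotype match probability  ``HMP = sum Pi^2``,
* discrimination capacity  ``DC = Ndiff / N``,

with ``Pi`` the direct-count frequency of the i-th allele or haplotype and
``n`` the number of typed individuals.  At a multi-copy locus the allelic
state is the entire canonical call (the unordered DYS385 pair counts as one
state), which is what makes per-locus diversities like 0.94 reachable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

import pandas as pd

from .model import PanelDefinition, PopulationSample, subset_panel

__all__ = [
    "FrequencySpectrum",
    "DiversityStats",
    "allele_spectrum",
    "haplotype_spectrum",
    "gene_diversity",
    "match_probability",
    "discrimination_capacity",
    "diversity_stats",
    "panel_report",
]


@dataclass(frozen=True)
class FrequencySpectrum:
    """Distinct states with their counts over ``n`` observations."""

    states: tuple[tuple[Hashable, int], ...]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("spectrum needs n >= 1")
        counts = [c for _, c in self.states]
        if any(c < 1 for c in counts):
            raise ValueError("all state counts must be >= 1")
        if sum(counts) != self.n:
            raise ValueError(f"counts sum to {sum(counts)}, expected n={self.n}")

    @classmethod
    def from_observations(cls, observations: Sequence[Hashable]) -> "FrequencySpectrum":
        counter = Counter(observations)
        states = tuple(sorted(counter.items(), key=lambda kv: (-kv[1], str(kv[0]))))
        return cls(states=states, n=len(observations))

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "FrequencySpectrum":
        """Anonymous spectrum from multiplicities alone (state identity immaterial)."""
        states = tuple((f"state_{i}", int(c)) for i, c in enumerate(counts))
        return cls(states=states, n=int(sum(counts)))

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(c / self.n for _, c in self.states)

    @property
    def n_distinct(self) -> int:
        return len(self.states)

    @property
    def n_unique(self) -> int:
        return sum(1 for _, c in self.states if c == 1)

    def sum_pi_squared(self) -> float:
        # exact integer arithmetic before the single division
        return sum(c * c for _, c in self.states) / (self.n * self.n)


@dataclass(frozen=True)
class DiversityStats:
    """Bundle of the forensic summaries for one spectrum."""

    gd_or_hd: float
    hmp: float
    dc: float
    n_distinct: int
    n_unique: int
    n: int


def gene_diversity(spec: FrequencySpectrum) -> float:
    """Nei's unbiased diversity ``n (1 - sum Pi^2)/(n - 1)``; needs n >= 2."""
    if spec.n < 2:
        raise ValueError("gene diversity undefined for n < 2")
    return spec.n * (1.0 - spec.sum_pi_squared()) / (spec.n - 1)


def match_probability(spec: FrequencySpectrum) -> float:
    """``sum Pi^2`` — the chance two random males share the state."""
    return spec.sum_pi_squared()


def discrimination_capacity(spec: FrequencySpectrum) -> float:
    """Number of distinct states over sample size."""
    return spec.n_distinct / spec.n


def diversity_stats(spec: FrequencySpectrum) -> DiversityStats:
    return DiversityStats(
        gd_or_hd=gene_diversity(spec),
        hmp=match_probability(spec),
        dc=discrimination_capacity(spec),
        n_distinct=spec.n_distinct,
        n_unique=spec.n_unique,
        n=spec.n,
    )


def allele_spectrum(sample: PopulationSample, locus: str) -> FrequencySpectrum:
    """Direct-count allele spectrum at one marker.

    The state is the whole canonical call, so the unordered allele pair at a
    multi-copy locus (and an anomalous bi-allele at a single-copy locus)
    counts as one combined state.  ``n`` is the number of individuals typed
    at the locus.
    """
    observations = []
    for h in sample.haplotypes:
        call = h.calls.get(locus)
        if call is not None:
            observations.append(str(call))
    if not observations:
        raise ValueError(f"locus {locus} is not typed in sample {sample.name}")
    return FrequencySpectrum.from_observations(observations)


def haplotype_spectrum(
    sample: PopulationSample, panel: PanelDefinition
) -> FrequencySpectrum:
    """Whole-haplotype spectrum under panel equality.

    Individuals missing any panel locus are excluded (direct-counting
    semantics); raises if nobody is fully typed.
    """
    observations = []
    for h in sample.haplotypes:
        key = h.state_key(panel.loci)
        if key is not None:
            observations.append(key)
    if not observations:
        raise ValueError(
            f"no haplotype in sample {sample.name} is complete for panel {panel.name}"
        )
    return FrequencySpectrum.from_observations(observations)


def panel_report(
    sample: PopulationSample, panels: Sequence[PanelDefinition]
) -> pd.DataFrame:
    """Forensic-efficiency comparison of marker sets on one sample.

    One row per panel, in input order: marker count, haplotype counts, DC,
    HD and HMP — the layout of the usual kit-comparison table.
    """
    rows = []
    for panel in panels:
        sub = subset_panel(sample, panel)
        spec = haplotype_spectrum(sub, panel)
        stats = diversity_stats(spec)
        rows.append(
            {
                "panel": panel.name,
                "n_markers": panel.marker_count,
                "n": stats.n,
                "n_haplotypes": stats.n_distinct,
                "n_unique": stats.n_unique,
                "DC": stats.dc,
                "HD": stats.gd_or_hd,
                "HMP": stats.hmp,
            }
        )
    return pd.DataFrame(rows)
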