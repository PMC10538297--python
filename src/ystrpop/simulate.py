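"""Synthetic Y-marker data emulating a forensic population study.

Three generators cover the pipeline's input shapes:

* :func:`sample_from_spectrum` — a sample whose haplotype frequency spectrum
  is exactly prescribed (e.g. 296 singletons + 8 doubletons = 312 males),
  for testing spectrum-derived statistics against closed-form counts.
* :func:`simulate_population` — forward stepwise-mutation simulation: every
  lineage descends from a common founder and each single-copy STR mutates
  with probability ``mu`` per generation by +/-1 repeat (symmetric
  single-step model, the model under which Rst is the natural estimator).
  Multi-copy loci evolve each copy independently; Y-InDel states are drawn
  from a two-state frequency; microvariant lineages carry an inherited
  fractional offset.
* :func:`simulate_divergent_pair` — two populations from a common founder
  with population B's founder shifted by ``delta`` repeats at every STR
  locus, giving tunable differentiation for the Rst stage.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import AlleleLabel, Haplotype, LocusCall, PanelDefinition, PopulationSample
from .panels import YPLUS44

__all__ = [
    "SimulationConfig",
    "sample_from_spectrum",
    "simulate_population",
    "simulate_divergent_pair",
]

_FOUNDER_RANGE = (10, 25)  # realistic Y-STR repeat-count range


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 312 males, the 44-marker panel, mu = 3.35e-3.

    ``generations`` sets how much drift accumulates (mu * g expected
    mutations per lineage per locus); 200 generations with the default mu
    gives the moderate per-locus diversity typical of a single population.
    ``delta`` is the founder repeat shift between the two populations of
    :func:`simulate_divergent_pair`.  ``microvariants`` maps locus ->
    (fractional offset, lineage frequency); defaults mirror loci where
    microvariant alleles are seen in real casework panels.
    """

    n_individuals: int = 312
    panel: PanelDefinition = YPLUS44
    mu: float = 3.35e-3
    generations: int = 200
    founder: Mapping[str, float] | None = None
    delta: float = 0.0
    indel_major_freq: float = 0.9
    microvariants: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"DYS458": (0.1, 0.03), "DYS557": (0.3, 0.02)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.n_individuals < 1:
            raise ValueError("need n_individuals >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not 0.0 <= self.indel_major_freq <= 1.0:
            raise ValueError("indel_major_freq must be in [0, 1]")


def _num_label(value: float) -> AlleleLabel:
    # canonical text: integer repeats print bare, microvariants with 1 digit
    raw = str(int(round(value))) if abs(value - round(value)) < 1e-9 else f"{value:.1f}"
    return AlleleLabel(raw=raw, value=float(raw))


def _copies(panel: PanelDefinition, locus: str) -> int:
    return 2 if locus in panel.multi_copy else 1


def _draw_founder(panel: PanelDefinition, rng: np.random.Generator) -> dict[str, list[int]]:
    lo, hi = _FOUNDER_RANGE
    founder: dict[str, list[int]] = {}
    for locus in panel.loci:
        if locus in panel.indel_loci:
            continue
        founder[locus] = [int(rng.integers(lo, hi + 1)) for _ in range(_copies(panel, locus))]
    return founder


def sample_from_spectrum(
    spectrum_spec: Sequence[tuple[int, int]],
    panel: PanelDefinition | None = None,
    seed: int = 0,
    name: str = "synthetic",
) -> PopulationSample:
    """Sample whose haplotype spectrum has exactly the requested multiplicities.

    ``spectrum_spec`` is a list of ``(multiplicity, number_of_states)`` pairs:
    ``[(1, 296), (2, 8)]`` yields n = 312 with 304 distinct haplotypes of
    which 296 are unique.  Distinct states are guaranteed to differ at >= 1
    locus; raises if the panel's state space cannot host that many states.
    """
    panel = panel or YPLUS44
    if not spectrum_spec:
        raise ValueError("empty spectrum specification")
    for mult, count in spectrum_spec:
        if mult < 1 or count < 1:
            raise ValueError("multiplicities and state counts must be >= 1")
    n_states = sum(count for _, count in spectrum_spec)

    lo, hi = _FOUNDER_RANGE
    per_locus = []
    for locus in panel.loci:
        if locus in panel.indel_loci:
            per_locus.append(2.0)
        else:
            r = float(hi - lo + 1)
            per_locus.append(r * (r + 1) / 2 if locus in panel.multi_copy else r)
    if np.log(per_locus).sum() < np.log(n_states):
        raise ValueError(
            f"panel state space too small for {n_states} distinct haplotypes"
        )

    rng = np.random.default_rng(seed)

    def random_haplotype(idx: int) -> Haplotype:
        calls = {}
        for locus in panel.loci:
            if locus in panel.indel_loci:
                raw = "I" if rng.random() < 0.5 else "D"
                calls[locus] = LocusCall(locus, (AlleleLabel(raw=raw, value=None),))
            else:
                alleles = tuple(
                    _num_label(int(rng.integers(lo, hi + 1)))
                    for _ in range(_copies(panel, locus))
                )
                calls[locus] = LocusCall(locus, alleles)
        return Haplotype(sample_id=f"S{idx:04d}", calls=calls)

    distinct: list[Haplotype] = []
    seen: set[tuple] = set()
    attempts = 0
    while len(distinct) < n_states:
        attempts += 1
        if attempts > 200 * n_states + 1000:
            raise ValueError("could not realize the requested spectrum")
        h = random_haplotype(len(distinct))
        key = h.state_key(panel.loci)
        if key in seen:
            continue
        seen.add(key)
        distinct.append(h)

    haplotypes: list[Haplotype] = []
    idx = 0
    state_iter = iter(distinct)
    for mult, count in spectrum_spec:
        for _ in range(count):
            proto = next(state_iter)
            for _ in range(mult):
                haplotypes.append(Haplotype(sample_id=f"S{idx:04d}", calls=proto.calls))
                idx += 1
    return PopulationSample(name=name, haplotypes=tuple(haplotypes))


def _evolve_repeats(
    founder_values: np.ndarray,
    n: int,
    mu: float,
    g: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, n_copies) repeat values after g generations of +/-1 stepping."""
    k = rng.binomial(g, mu, size=(n, founder_values.size))
    up = rng.binomial(k, 0.5)
    return founder_values[None, :] + (2 * up - k)


def simulate_population(cfg: SimulationConfig, name: str = "pop") -> PopulationSample:
    """Forward stepwise-mutation sample; deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    founder = dict(cfg.founder) if cfg.founder is not None else None
    drawn = _draw_founder(panel, rng)
    if founder is None:
        founder_copies = drawn
    else:
        founder_copies = {
            locus: [founder[locus]] * _copies(panel, locus)
            if locus in founder
            else drawn[locus]
            for locus in drawn
        }
    return _population_from_founder(cfg, founder_copies, rng, name)


def _population_from_founder(
    cfg: SimulationConfig,
    founder_copies: Mapping[str, Sequence[float]],
    rng: np.random.Generator,
    name: str,
) -> PopulationSample:
    panel, n = cfg.panel, cfg.n_individuals
    locus_values: dict[str, np.ndarray] = {}
    for locus in panel.loci:
        if locus in panel.indel_loci:
            continue
        base = np.asarray(founder_copies[locus], dtype=float)
        values = _evolve_repeats(np.floor(base), n, cfg.mu, cfg.generations, rng)
        frac = base - np.floor(base)
        values = values + frac[None, :]
        if locus in cfg.microvariants:
            offset, freq = cfg.microvariants[locus]
            carriers = rng.random(n) < freq
            values[carriers, :] += offset
        locus_values[locus] = np.maximum(values, 1.0)

    indel_states: dict[str, np.ndarray] = {
        locus: np.where(rng.random(n) < cfg.indel_major_freq, "I", "D")
        for locus in panel.loci
        if locus in panel.indel_loci
    }

    haplotypes = []
    for i in range(n):
        calls = {}
        for locus in panel.loci:
            if locus in panel.indel_loci:
                raw = str(indel_states[locus][i])
                calls[locus] = LocusCall(locus, (AlleleLabel(raw=raw, value=None),))
            else:
                alleles = tuple(_num_label(v) for v in locus_values[locus][i])
                calls[locus] = LocusCall(locus, alleles)
        haplotypes.append(Haplotype(sample_id=f"{name}_{i:04d}", calls=calls))
    return PopulationSample(name=name, haplotypes=tuple(haplotypes))


def simulate_divergent_pair(
    cfg: SimulationConfig,
) -> tuple[PopulationSample, PopulationSample]:
    """Two populations from one founder, B shifted +delta repeats per STR locus.

    ``delta = 0`` reduces to two independent draws from the same population.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    founder_a = _draw_founder(panel, rng)
    if cfg.founder is not None:
        founder_a = {
            locus: [cfg.founder[locus]] * _copies(panel, locus)
            if locus in cfg.founder
            else vals
            for locus, vals in founder_a.items()
        }
    founder_b = {
        locus: [v + cfg.delta for v in vals] for locus, vals in founder_a.items()
    }
    pop_a = _population_from_founder(cfg, founder_a, rng, "popA")
    pop_b = _population_from_founder(cfg, founder_b, rng, "popB")
    return pop_a, pop_b
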