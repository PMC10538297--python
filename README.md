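# ystrpop

Forensic Y-STR population genetics in Python: per-locus and per-panel
diversity statistics, pairwise Rst by haploid AMOVA, and population-structure
summaries (classical MDS, Neighbor-Joining trees).

Y-chromosome STR haplotypes are the standard tool for distinguishing
unrelated males and tracing paternal lineages. A population study types a
few hundred males at a commercial marker panel and reports, per locus, the
allele frequencies and gene diversity `GD = n(1 - Σpᵢ²)/(n-1)`, and, per
panel, the haplotype diversity HD (same estimator on whole-haplotype
frequencies), the haplotype match probability `HMP = Σpᵢ²` and the
discrimination capacity `DC = N_distinct/N`; genetic distances between
populations are Rst values from an analysis of molecular variance with
squared repeat-difference distances, visualized by multidimensional scaling
and a Neighbor-Joining tree. `ystrpop` implements that entire flow on plain
delimited haplotype tables, with the forensic naming edge cases handled
properly: microvariant alleles (`14.1`), multi-copy loci whose unordered
allele pair is one state (DYS385), copy-number anomalies (`13,14` at a
single-copy locus, `19,21,22` at a double-copy locus) and binary Y-InDels.

It ships panel definitions for the common kits (minimal 9, PowerPlex Y 12,
Yfiler 17, PowerPlex Y23, Yfiler Plus 27, and a 41 Y-STR + 3 Y-InDel
44-marker megaplex), a stepwise-mutation forward simulator for generating
test populations with tunable divergence, a library API, and a `ystrpop`
command-line tool.

## Worked example

```python
from ystrpop import (
    sample_from_spectrum, haplotype_spectrum, diversity_stats,
    SimulationConfig, simulate_divergent_pair, amova_rst,
)
from ystrpop.panels import YPLUS44

# a 312-male sample whose haplotype spectrum is 296 singletons + 8 doubletons
sample = sample_from_spectrum([(1, 296), (2, 8)], YPLUS44, seed=0)
stats = diversity_stats(haplotype_spectrum(sample, YPLUS44))
print(f"HD={stats.gd_or_hd:.5f} HMP={stats.hmp:.5f} DC={stats.dc:.4f}")
# HD=0.99984 HMP=0.00337 DC=0.9744

# two populations diverged by 4 repeats at every STR locus
a, b = simulate_divergent_pair(SimulationConfig(n_individuals=50, delta=4.0, seed=2))
vc = amova_rst([a, b], YPLUS44.str_single_copy)
print(f"Rst={vc.rst:.4f}")
# Rst=0.9219
```

`HD` near 1 and `HMP` near `1/n` say almost every male carries a haplotype
seen once; `DC = 304/312` counts distinct haplotypes per sampled male. The
`Rst` of 0.92 reflects near-complete differentiation: with a founder shift
of 4 repeats per locus, almost all molecular variance lies between the two
populations.

The numbered scripts under `analysis/` run the full flow on synthetic data
and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py      # haplotype tables
python analysis/02_forensic_diversity.py   # locus GD, HD/HMP/DC, kit comparison
python analysis/03_population_structure.py # Rst matrix, MDS, NJ tree
```

The same stages are available from the shell, e.g.:

```bash
ystrpop simulate --n 312 --seed 7 --out cohort.tsv
ystrpop diversity -i dong=cohort.tsv --out results/
ystrpop rst -i a=popA.tsv -i b=popB.tsv -i c=popC.tsv --out results/
ystrpop njtree -m results/rst_matrix.tsv --out results/
```

## Layout

- `src/ystrpop/` — library: `model` (types, parsing, table I/O), `panels`,
  `diversity`, `distance` (AMOVA/Rst), `structure` (MDS/NJ), `simulate`,
  `pipeline`, `cli`
- `analysis/` — numbered analysis drivers
- `tests/` — pytest suite with brute-force oracles (`tests/oracles.py`)
- `docs/methods.md` — models, defaults, numerical choices, limitations
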