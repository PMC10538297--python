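#!/usr/bin/env python
"""Population structure across the simulated populations.

Reads results/data/pop*.tsv (run 01_simulate_cohort.py first), computes the
pairwise Rst matrix over single-copy STR loci, a permutation p-value for the
least-diverged pair, classical MDS coordinates, and the Neighbor-Joining
tree.  Outputs under results/structure/.
"""

from pathlib import Path

from ystrpop import RunConfig, load_population, rst_permutation_p, run_structure
from ystrpop.panels import YPLUS44

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 2023


def main() -> None:
    tables = sorted((BASE / "data").glob("pop*.tsv"))
    if len(tables) < 3:
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    inputs = tuple((p.stem, p) for p in tables)
    cfg = RunConfig(inputs=inputs, out_dir=BASE / "structure", panel=YPLUS44,
                    seed=SEED)
    summary = run_structure(cfg)

    print(f"Rst over {len(summary['rst_loci'])} single-copy STR loci:")
    for pair, value in summary["rst"].items():
        print(f"  {pair}: {value:.4f}")
    print(f"MDS stress: {summary['mds_stress']:.4g}")
    print(f"NJ tree: {summary['newick']}")

    a = load_population(tables[0], YPLUS44, tables[0].stem)
    b = load_population(tables[1], YPLUS44, tables[1].stem)
    p = rst_permutation_p(a, b, YPLUS44.str_single_copy, n_perm=999, seed=SEED)
    print(f"permutation p ({a.name} vs {b.name}, 999 perms): {p:.4f}")


if __name__ == "__main__":
    main()
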