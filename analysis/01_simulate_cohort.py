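#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes three kinds of haplotype tables under results/data/:

* ``dong_like.tsv`` — a 312-male sample on the 44-marker panel whose
  haplotype spectrum is exactly the published one (296 unique haplotypes,
  8 seen twice), used by the diversity stage;
* ``cohort_smm.tsv`` — a 312-male forward stepwise-mutation cohort (mu =
  3.35e-3, 200 generations), a structurally realistic stand-in for raw
  genotypes;
* ``pop0..pop4.tsv`` — five populations at founder divergence 0/1/2/4/6
  repeats from a common ancestor, inputs for the Rst/MDS/NJ stage.
"""

from pathlib import Path

from ystrpop import SimulationConfig, sample_from_spectrum, simulate_population, write_haplotype_table
from ystrpop.panels import YPLUS44

SEED = 2023
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    dong_like = sample_from_spectrum([(1, 296), (2, 8)], YPLUS44, seed=SEED,
                                     name="dong_like")
    (OUT / "dong_like.tsv").write_text(write_haplotype_table(dong_like, YPLUS44))
    print(f"dong_like.tsv: n={dong_like.n}, spectrum 296x1 + 8x2")

    cohort = simulate_population(SimulationConfig(seed=SEED), name="cohort")
    (OUT / "cohort_smm.tsv").write_text(write_haplotype_table(cohort, YPLUS44))
    print(f"cohort_smm.tsv: n={cohort.n}, stepwise-mutation model")

    founder = {locus: 16 for locus in YPLUS44.loci if locus not in YPLUS44.indel_loci}
    for i, delta in enumerate((0, 1, 2, 4, 6)):
        shifted = {l: 16 + delta for l in YPLUS44.str_single_copy}
        cfg = SimulationConfig(
            n_individuals=60, generations=150,
            founder={**founder, **shifted}, seed=SEED + i,
        )
        pop = simulate_population(cfg, name=f"pop{i}")
        (OUT / f"pop{i}.tsv").write_text(write_haplotype_table(pop, YPLUS44))
        print(f"pop{i}.tsv: n=60, founder shift +{delta} repeats")


if __name__ == "__main__":
    main()
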