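#!/usr/bin/env python
"""Forensic diversity of the 44-marker panel and kit comparison.

Reads results/data/dong_like.tsv (run 01_simulate_cohort.py first), computes
per-locus allelic states and GD, the whole-panel HD/HMP/DC, and the
efficiency comparison across the shipped marker sets, mirroring the usual
allele-frequency and kit-comparison report tables.  Outputs under
results/diversity/.
"""

from pathlib import Path

from ystrpop import RunConfig, run_diversity
from ystrpop.panels import BUILTIN_PANELS, YPLUS44

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dong_like = BASE / "data" / "dong_like.tsv"
    cohort = BASE / "data" / "cohort_smm.tsv"
    if not (dong_like.exists() and cohort.exists()):
        raise SystemExit("run analysis/01_simulate_cohort.py first")

    # headline statistics on the spectrum-matched sample
    cfg = RunConfig(
        inputs=(("dong_like", dong_like),),
        out_dir=BASE / "diversity",
        panel=YPLUS44,
    )
    summary = run_diversity(cfg)
    print(
        f"panel={summary['panel']} ({summary['n_markers']} markers), "
        f"n={summary['n']}: {summary['n_haplotypes']} haplotypes "
        f"({summary['n_unique']} unique)"
    )
    print(f"HD={summary['HD']}, HMP={summary['HMP']}, DC={summary['DC']}")

    # kit comparison on the drift cohort, whose per-locus diversity is
    # realistic (the spectrum-matched sample is already resolved by any panel)
    cfg2 = RunConfig(
        inputs=(("cohort", cohort),),
        out_dir=BASE / "diversity" / "cohort",
        panel=YPLUS44,
        compare_panels=tuple(BUILTIN_PANELS.values()),
    )
    summary2 = run_diversity(cfg2)
    print("kit comparison on the stepwise-mutation cohort:")
    for row in summary2["panels"]:
        print(
            f"  {row['panel']:>14} ({row['n_markers']:>2} markers): "
            f"DC={row['DC']:.5f} HD={row['HD']:.5f} HMP={row['HMP']:.5f}"
        )


if __name__ == "__main__":
    main()
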