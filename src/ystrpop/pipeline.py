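"""End-to-end orchestration: diversity reports and population-structure outputs.

``run_diversity`` turns one haplotype table into the three standard report
tables (per-locus allele spectra + GD, haplotype list with frequencies, and a
panel-comparison table) plus a JSON summary.  ``run_structure`` takes two or
more population tables and emits the pairwise Rst matrix (labelled TSV and
PHYLIP), classical MDS coordinates, and — with three or more populations — a
Neighbor-Joining tree in Newick.  Outputs are deterministic given inputs and
re-parse with the package's own readers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .diversity import (
    allele_spectrum,
    diversity_stats,
    gene_diversity,
    haplotype_spectrum,
    panel_report,
)
from .distance import pairwise_rst
from .model import PanelDefinition, PopulationSample, read_haplotype_table
from .panels import BUILTIN_PANELS
from .structure import classical_mds, neighbor_joining, to_newick

logger = logging.getLogger("ystrpop")

__all__ = ["RunConfig", "run_diversity", "run_structure", "load_population"]


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for one pipeline run."""

    inputs: tuple[tuple[str, Path], ...]  # (population label, table path)
    out_dir: Path
    panel: PanelDefinition
    compare_panels: tuple[PanelDefinition, ...] = ()
    rst_loci: tuple[str, ...] = ()  # empty -> panel.str_single_copy
    dims: int = 2
    seed: int = 0
    table_format: str = "tsv"

    @property
    def sep(self) -> str:
        return "," if self.table_format == "csv" else "\t"


def load_population(path: Path, panel: PanelDefinition, name: str) -> PopulationSample:
    return read_haplotype_table(Path(path).read_text(), panel, name=name)


def _write_table(df: pd.DataFrame, path: Path, sep: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def locus_report(sample: PopulationSample, panel: PanelDefinition) -> pd.DataFrame:
    """Per-locus table: allelic states, counts and GD (allele-frequency layout)."""
    rows = []
    for locus in panel.loci:
        spec = allele_spectrum(sample, locus)
        rows.append(
            {
                "locus": locus,
                "n": spec.n,
                "n_states": spec.n_distinct,
                "min_freq": min(spec.frequencies),
                "max_freq": max(spec.frequencies),
                "GD": gene_diversity(spec),
            }
        )
    return pd.DataFrame(rows)


def haplotype_report(sample: PopulationSample, panel: PanelDefinition) -> pd.DataFrame:
    """Distinct haplotypes with counts and frequencies (haplotype-list layout)."""
    spec = haplotype_spectrum(sample, panel)
    rows = []
    for state, count in spec.states:
        cells = {locus: ",".join(alleles) for locus, alleles in zip(panel.loci, state)}
        rows.append({**cells, "count": count, "frequency": count / spec.n})
    return pd.DataFrame(rows)


def run_diversity(config: RunConfig) -> dict:
    """Diversity stage on the first input table; returns the JSON summary dict."""
    if not config.inputs:
        raise ValueError("run_diversity needs at least one input table")
    label, path = config.inputs[0]
    sample = load_population(path, config.panel, label)
    out = Path(config.out_dir)
    sep = config.sep

    _write_table(locus_report(sample, config.panel), out / "locus_gd.tsv", sep)
    _write_table(haplotype_report(sample, config.panel), out / "haplotypes.tsv", sep)
    panels = config.compare_panels or (config.panel,)
    report = panel_report(sample, panels)
    _write_table(report, out / "panel_comparison.tsv", sep)

    stats = diversity_stats(haplotype_spectrum(sample, config.panel))
    summary = {
        "population": sample.name,
        "n": stats.n,
        "panel": config.panel.name,
        "n_markers": config.panel.marker_count,
        "n_haplotypes": stats.n_distinct,
        "n_unique": stats.n_unique,
        "HD": round(stats.gd_or_hd, 5),
        "HMP": round(stats.hmp, 5),
        "DC": round(stats.dc, 4),
        "panels": report.to_dict(orient="records"),
    }
    (out / "diversity_summary.json").write_text(json.dumps(summary, indent=2))
    logger.info(
        "%s: n=%d HD=%.5f HMP=%.5f DC=%.4f (%d haplotypes, %d unique)",
        sample.name, stats.n, stats.gd_or_hd, stats.hmp, stats.dc,
        stats.n_distinct, stats.n_unique,
    )
    return summary


def run_structure(config: RunConfig) -> dict:
    """Structure stage: Rst matrix, MDS coordinates, NJ tree (if >= 3 inputs)."""
    if len(config.inputs) < 2:
        raise ValueError("run_structure needs at least two input tables")
    samples = [
        load_population(path, config.panel, label) for label, path in config.inputs
    ]
    loci = config.rst_loci or config.panel.str_single_copy
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dm = pairwise_rst(samples, loci)
    (out / "rst_matrix.tsv").write_text(dm.to_tsv())
    (out / "rst_matrix.phy").write_text(dm.to_phylip())

    dims = min(config.dims, len(dm.labels) - 1)
    ord_res = classical_mds(dm, k=dims)
    coords = pd.DataFrame(
        ord_res.coordinates,
        columns=[f"dim{i+1}" for i in range(dims)],
    )
    coords.insert(0, "population", list(ord_res.labels))
    _write_table(coords, out / "mds_coordinates.tsv", config.sep)

    newick = None
    if len(samples) >= 3:
        newick = to_newick(neighbor_joining(dm))
        (out / "nj_tree.nwk").write_text(newick + "\n")
    else:
        logger.warning("fewer than 3 populations: NJ tree skipped")

    summary = {
        "populations": list(dm.labels),
        "rst_loci": list(loci),
        "rst": {
            f"{dm.labels[i]}|{dm.labels[j]}": float(dm.values[i, j])
            for i in range(len(dm.labels))
            for j in range(i + 1, len(dm.labels))
        },
        "mds_stress": ord_res.stress,
        "newick": newick,
    }
    (out / "structure_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
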