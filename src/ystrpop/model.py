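"""Domain model for forensic Y-marker haplotype data.

Y-STR alleles are named by repeat count; microvariants carry one fractional
digit (``14.1`` = 14 full repeats plus 1 bp).  Multi-copy loci (e.g. DYS385)
return an unordered multiset of alleles per male that is treated as a single
allelic state.  Y-InDel markers are two-state categorical loci.  Copy-number
anomalies (a bi-allelic call at a single-copy locus, a tri-allelic call at a
double-copy locus) are representable and survive table round-trips.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlleleLabel",
    "LocusCall",
    "Haplotype",
    "PanelDefinition",
    "PopulationSample",
    "AlleleParseError",
    "TableSchemaError",
    "parse_allele",
    "read_haplotype_table",
    "write_haplotype_table",
    "subset_panel",
    "read_panel_config",
    "write_panel_config",
]


class AlleleParseError(ValueError):
    """Malformed allele token (non-numeric STR label, bad fraction, empty item)."""


class TableSchemaError(ValueError):
    """Haplotype table does not match the governing panel's schema."""


_STR_ALLELE_RE = re.compile(r"^\d+(\.\d)?$")


@dataclass(frozen=True)
class AlleleLabel:
    """One allele as printed: numeric repeat count for STRs, categorical for InDels.

    ``value`` is the numeric repeat count (fractional part = microvariant) or
    ``None`` for categorical InDel states.  ``raw`` preserves the printed
    token so that ``14.1`` stays ``"14.1"`` and ``13`` stays ``"13"``.
    """

    raw: str
    value: float | None

    @property
    def is_numeric(self) -> bool:
        return self.value is not None

    def _sort_key(self) -> tuple:
        if self.value is not None:
            return (0, self.value, self.raw)
        return (1, self.raw)

    def __str__(self) -> str:  # round-trip: text out == text in
        return self.raw


def _parse_one_allele(item: str, locus: str, kind: str) -> AlleleLabel:
    item = item.strip()
    if not item:
        raise AlleleParseError(f"{locus}: empty allele item")
    if kind == "indel":
        return AlleleLabel(raw=item, value=None)
    if not _STR_ALLELE_RE.match(item):
        raise AlleleParseError(
            f"{locus}: malformed STR allele token {item!r} "
            "(expected integer repeats with at most one fractional digit)"
        )
    value = float(item)
    if value <= 0:
        raise AlleleParseError(f"{locus}: non-positive STR allele {item!r}")
    return AlleleLabel(raw=item, value=value)


@dataclass(frozen=True)
class LocusCall:
    """The allelic state of one individual at one marker.

    ``alleles`` is stored canonically sorted (ascending repeat count), so two
    calls are equal iff their unordered multisets are equal; ``"22,19,21"``
    and ``"19,21,22"`` parse to the same call.
    """

    locus: str
    alleles: tuple[AlleleLabel, ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"{self.locus}: a call needs at least one allele")
        object.__setattr__(
            self, "alleles", tuple(sorted(self.alleles, key=AlleleLabel._sort_key))
        )

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def state_key(self) -> tuple[str, ...]:
        """Hashable canonical identity of the whole state."""
        return tuple(a.raw for a in self.alleles)

    def __str__(self) -> str:
        return ",".join(a.raw for a in self.alleles)


def parse_allele(
    token: str,
    locus: str = "?",
    kind: str = "str",
    delimiter: str = ",",
) -> LocusCall:
    """Parse a table cell into a canonical :class:`LocusCall`.

    Multi-allele cells are ``delimiter``-separated (default comma, as printed
    in forensic tables: ``"19,21,22"``); a hyphen-joined token such as
    ``"13-17"`` is accepted as an input alternative when no comma is present.

    Parameters
    ----------
    token : str
        Cell text, e.g. ``"14.1"`` or ``"19,21,22"``.
    locus : str
        Marker name, used in error messages and the returned call.
    kind : {"str", "indel"}
        STR alleles must be numeric; InDel states are categorical.
    """
    if kind not in ("str", "indel"):
        raise ValueError(f"unknown locus kind {kind!r}")
    token = token.strip()
    if not token:
        raise AlleleParseError(f"{locus}: empty allele token")
    items = token.split(delimiter)
    if len(items) == 1 and "-" in token and kind == "str":
        items = token.split("-")
    alleles = tuple(_parse_one_allele(item, locus, kind) for item in items)
    return LocusCall(locus=locus, alleles=alleles)


@dataclass(frozen=True)
class Haplotype:
    """One male's calls across markers; loci absent from ``calls`` are missing."""

    sample_id: str
    calls: Mapping[str, LocusCall]

    def call(self, locus: str) -> LocusCall | None:
        return self.calls.get(locus)

    def is_complete(self, loci: Sequence[str]) -> bool:
        return all(locus in self.calls for locus in loci)

    def state_key(self, loci: Sequence[str]) -> tuple | None:
        """Canonical haplotype identity over ``loci``; None if any locus missing."""
        keys = []
        for locus in loci:
            call = self.calls.get(locus)
            if call is None:
                return None
            keys.append(call.state_key())
        return tuple(keys)

    def restrict(self, loci: Sequence[str]) -> "Haplotype":
        return Haplotype(
            sample_id=self.sample_id,
            calls={l: self.calls[l] for l in loci if l in self.calls},
        )


@dataclass(frozen=True)
class PanelDefinition:
    """A named marker set: ordered loci plus copy-number and InDel annotation.

    ``multi_copy`` loci are duplicated on the Y and nominally yield two
    alleles per male; for marker counting each contributes two markers
    (DYS385a/b convention), so ``marker_count = len(loci) + len(multi_copy)``.
    """

    name: str
    loci: tuple[str, ...]
    multi_copy: frozenset[str] = field(default_factory=frozenset)
    indel_loci: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"panel {self.name}: duplicate loci")
        extra = (self.multi_copy | self.indel_loci) - set(self.loci)
        if extra:
            raise ValueError(f"panel {self.name}: annotated loci not in panel: {sorted(extra)}")
        if self.multi_copy & self.indel_loci:
            raise ValueError(f"panel {self.name}: multi_copy and indel_loci overlap")

    @property
    def marker_count(self) -> int:
        return len(self.loci) + len(self.multi_copy)

    def locus_kind(self, locus: str) -> str:
        return "indel" if locus in self.indel_loci else "str"

    @property
    def str_single_copy(self) -> tuple[str, ...]:
        """Single-copy STR loci — the loci usable for repeat-difference distances."""
        return tuple(
            l for l in self.loci if l not in self.multi_copy and l not in self.indel_loci
        )


@dataclass(frozen=True)
class PopulationSample:
    """Named collection of haplotypes from one population."""

    name: str
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if len(self.haplotypes) < 1:
            raise ValueError(f"population {self.name}: needs at least one haplotype")
        ids = [h.sample_id for h in self.haplotypes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"population {self.name}: duplicate sample ids {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    @property
    def typed_loci(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for h in self.haplotypes:
            for locus in h.calls:
                seen.setdefault(locus, None)
        return tuple(seen)


# ---------------------------------------------------------------------------
# Table I/O.  TSV is the native dialect (comma stays free for multi-allele
# cells); CSV is accepted, with multi-allele cells quoted by the csv module.

ID_COLUMN = "sample_id"
_ID_ALIASES = {"sample_id", "sample", "id", "sampleid"}


def _detect_delimiter(header_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if "\t" in header_line else ","


def read_haplotype_table(
    source: str | io.TextIOBase,
    panel: PanelDefinition,
    name: str = "sample",
    delimiter: str | None = None,
) -> PopulationSample:
    """Read a haplotype table (one row per individual, one column per marker).

    The header must contain a sample-identifier column and every panel locus.
    Empty cells become missing markers.  Raises :class:`TableSchemaError` when
    a panel column is absent and :class:`ValueError` on duplicate sample ids.
    """
    if isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = text.splitlines()
    if not lines:
        raise TableSchemaError("empty table: no header row")
    sep = _detect_delimiter(lines[0], delimiter)
    reader = csv.reader(lines, delimiter=sep)
    header = next(reader)
    id_col = None
    for i, col in enumerate(header):
        if col.strip().lower() in _ID_ALIASES:
            id_col = i
            break
    if id_col is None:
        raise TableSchemaError(
            f"no sample-identifier column (expected one of {sorted(_ID_ALIASES)})"
        )
    col_index = {col: i for i, col in enumerate(header)}
    missing_cols = [l for l in panel.loci if l not in col_index]
    if missing_cols:
        raise TableSchemaError(
            f"table is missing panel column(s): {', '.join(missing_cols)}"
        )

    haplotypes = []
    for row in reader:
        if not row or all(not c.strip() for c in row):
            continue
        sample_id = row[id_col].strip()
        calls: dict[str, LocusCall] = {}
        for locus in panel.loci:
            idx = col_index[locus]
            cell = row[idx].strip() if idx < len(row) else ""
            if not cell:
                continue  # missing marker
            calls[locus] = parse_allele(cell, locus=locus, kind=panel.locus_kind(locus))
        haplotypes.append(Haplotype(sample_id=sample_id, calls=calls))
    if not haplotypes:
        raise TableSchemaError("table has a header but no data rows")
    return PopulationSample(name=name, haplotypes=tuple(haplotypes))


def write_haplotype_table(
    sample: PopulationSample,
    panel: PanelDefinition,
    delimiter: str = "\t",
) -> str:
    """Serialize a sample to delimited text; inverse of :func:`read_haplotype_table`."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow([ID_COLUMN, *panel.loci])
    for h in sample.haplotypes:
        row = [h.sample_id]
        for locus in panel.loci:
            call = h.calls.get(locus)
            row.append(str(call) if call is not None else "")
        writer.writerow(row)
    return buf.getvalue()


def subset_panel(sample: PopulationSample, panel: PanelDefinition) -> PopulationSample:
    """Restrict every haplotype to the panel's loci (sample size unchanged).

    Every panel locus must be typed somewhere in the sample; otherwise an
    error lists the absent loci.
    """
    typed = set(sample.typed_loci)
    absent = [l for l in panel.loci if l not in typed]
    if absent:
        raise ValueError(
            f"panel {panel.name}: loci not typed in sample {sample.name}: "
            f"{', '.join(absent)}"
        )
    return PopulationSample(
        name=sample.name,
        haplotypes=tuple(h.restrict(panel.loci) for h in sample.haplotypes),
    )


# ---------------------------------------------------------------------------
# Panel configuration files (YAML; one section per panel).

def read_panel_config(text: str) -> list[PanelDefinition]:
    """Parse a panel config: ``panels: [{name, loci, multi_copy, indel_loci}]``."""
    import yaml

    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "panels" not in doc:
        raise ValueError("panel config must be a mapping with a 'panels' list")
    panels = []
    for entry in doc["panels"]:
        panels.append(
            PanelDefinition(
                name=str(entry["name"]),
                loci=tuple(str(l) for l in entry["loci"]),
                multi_copy=frozenset(str(l) for l in entry.get("multi_copy", [])),
                indel_loci=frozenset(str(l) for l in entry.get("indel_loci", [])),
            )
        )
    return panels


def write_panel_config(panels: Iterable[PanelDefinition]) -> str:
    import yaml

    doc = {
        "panels": [
            {
                "name": p.name,
                "loci": list(p.loci),
                "multi_copy": sorted(p.multi_copy),
                "indel_loci": sorted(p.indel_loci),
            }
            for p in panels
        ]
    }
    return yaml.safe_dump(doc, sort_keys=False)
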