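"""Readers and writers for abundance matrices, annotation catalogs and result tables.

Supported inputs are plain tab-separated text: an entity-by-sample abundance
matrix, MapMan ontology mapping files (BINCODE/NAME/IDENTIFIER/DESCRIPTION/TYPE,
fields optionally wrapped in single quotes) and standard GMT gene-set files.
Biological replicates are aggregated to one column per condition before
surprisal analysis.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MAPMAN_COLUMNS = ("BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION", "TYPE")


@dataclass
class AbundanceMatrix:
    """Entity-by-condition table of nonnegative abundances X_i(t).

    Rows are measured entities (transcripts, proteins, metabolites), columns
    are conditions in experimental time order.
    """

    entity_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.condition_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.condition_labels)} conditions"
            )
        seen: set[str] = set()
        for eid in self.entity_ids:
            if not eid:
                raise ValueError("empty entity ID")
            if eid in seen:
                raise ValueError(f"duplicate entity ID {eid!r}")
            seen.add(eid)
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance for entity {self.entity_ids[i]!r} "
                f"in condition {self.condition_labels[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AnnotationCatalog:
    """Mapping from FAS identifier to its member entity IDs.

    A FAS (functionally annotated set) is the unit of enrichment testing,
    e.g. one MapMan bin name path or one GMT gene set. Sets may overlap.
    ``skipped_lines`` counts malformed lines dropped during parsing.
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    skipped_lines: int = 0

    def __post_init__(self) -> None:
        for fas_id, members in self.sets.items():
            if not fas_id:
                raise ValueError("empty FAS identifier")
            for m in members:
                if not m:
                    raise ValueError(f"empty member ID in FAS {fas_id!r}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ReplicateDesign:
    """Maps each sample column label to the condition (time point) it replicates."""

    sample_to_condition: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sample_to_condition:
            raise ValueError("empty replicate design")

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        out: list[str] = []
        for cond in self.sample_to_condition.values():
            if cond not in out:
                out.append(cond)
        return out


def read_abundance_matrix(path: str | Path, delimiter: str = "\t") -> AbundanceMatrix:
    """Read an entity-by-sample abundance matrix from delimited text.

    First row: header of condition/sample labels; first column: entity IDs.
    Duplicate IDs, non-numeric cells and ragged rows are hard errors.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        # Header may or may not carry a leading label for the ID column; infer
        # from the first data row's width.
        rows = [row for row in reader if row and any(f.strip() for f in row)]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = len(rows[0]) - 1
    if len(header) == ncol + 1:
        condition_labels = [h.strip() for h in header[1:]]
    elif len(header) == ncol:
        condition_labels = [h.strip() for h in header]
    else:
        raise ValueError(
            f"{path}: header has {len(header)} fields but data rows have {ncol + 1}"
        )
    entity_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(rows), ncol), dtype=float)
    for r, row in enumerate(rows):
        if len(row) != ncol + 1:
            raise ValueError(f"{path}: ragged row {r + 2} ({len(row)} fields, expected {ncol + 1})")
        eid = row[0].strip().strip("'\"")
        if eid in seen:
            raise ValueError(f"{path}: duplicate entity ID {eid!r}")
        seen.add(eid)
        entity_ids.append(eid)
        for c, cell in enumerate(row[1:]):
            try:
                values[r, c] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {r + 2}, "
                    f"column {condition_labels[c]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-finite cell at row {r + 2}, column {condition_labels[c]!r}"
        )
    return AbundanceMatrix(entity_ids, condition_labels, values)


def _strip_quotes(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in "'\"":
        s = s[1:-1]
    return s.strip()


def normalize_identifier(identifier: str) -> str:
    """Canonical entity ID: surrounding quotes/whitespace stripped, uppercased.

    MapMan mapping files ship lowercase AGI codes while expression matrices
    are typically uppercase; matching is therefore case-insensitive.
    """
    return _strip_quotes(identifier).upper()


def read_mapman_mapping(
    path: str | Path, propagate_to_ancestors: bool = False
) -> AnnotationCatalog:
    """Read a MapMan ontology mapping file into an annotation catalog.

    One FAS per distinct NAME path. By default an identifier annotated to a
    child bin (e.g. ``a.b.c``) is a member of that bin only; set
    ``propagate_to_ancestors`` to additionally add it to ``a.b`` and ``a``.
    Bins listed only at deeper levels still appear (possibly empty) so that
    every ontology depth is a distinct test unit.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = [_strip_quotes(h).upper() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty MapMan mapping file") from None
        missing = [c for c in MAPMAN_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in MAPMAN_COLUMNS}
        sets: dict[str, set[str]] = {}
        descriptions: dict[str, str] = {}
        n_rows = 0
        for row in reader:
            if not row or not any(f.strip() for f in row):
                continue
            n_rows += 1
            name = _strip_quotes(row[idx["NAME"]])
            identifier = normalize_identifier(row[idx["IDENTIFIER"]])
            desc = _strip_quotes(row[idx["DESCRIPTION"]]) if idx["DESCRIPTION"] < len(row) else ""
            if not name:
                continue
            sets.setdefault(name, set())
            if desc and name not in descriptions:
                descriptions[name] = desc
            if identifier:
                sets[name].add(identifier)
                if propagate_to_ancestors:
                    parts = name.split(".")
                    for depth in range(1, len(parts)):
                        ancestor = ".".join(parts[:depth])
                        sets.setdefault(ancestor, set()).add(identifier)
    if n_rows == 0:
        raise ValueError(f"{path}: MapMan mapping file has no data rows")
    return AnnotationCatalog(sets, descriptions)


def read_gmt(path: str | Path) -> AnnotationCatalog:
    """Read a GMT gene-set file (set-name TAB description TAB member...).

    Lines with fewer than three fields are skipped with a warning and counted
    in the returned catalog's ``skipped_lines``. Duplicate members within a
    line are deduplicated; a repeated set name is a hard error.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    skipped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            fields = line.split("\t")
            if len(fields) < 3 or not fields[0].strip():
                skipped += 1
                logger.warning("%s: skipping malformed GMT line %d", path, lineno)
                continue
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = {m.strip() for m in fields[2:] if m.strip()}
            sets[name] = members
            if fields[1].strip():
                descriptions[name] = fields[1].strip()
    return AnnotationCatalog(sets, descriptions, skipped_lines=skipped)


def aggregate_replicates(
    matrix: AbundanceMatrix,
    design: ReplicateDesign,
    method: Literal["mean", "median"] = "mean",
) -> AbundanceMatrix:
    """Collapse replicate sample columns to one column per condition.

    Aggregation acts on the raw abundance scale, before any log transform.
    Output condition order is the design's first-appearance order.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    missing = [c for c in matrix.condition_labels if c not in design.sample_to_condition]
    if missing:
        raise ValueError(f"sample column(s) absent from replicate design: {missing}")
    conditions = design.conditions
    agg = np.mean if method == "mean" else np.median
    out = np.empty((len(matrix.entity_ids), len(conditions)))
    for j, cond in enumerate(conditions):
        cols = [
            k
            for k, sample in enumerate(matrix.condition_labels)
            if design.sample_to_condition[sample] == cond
        ]
        if not cols:
            raise ValueError(f"condition {cond!r} has no sample column in the matrix")
        out[:, j] = agg(matrix.values[:, cols], axis=1)
    return AbundanceMatrix(list(matrix.entity_ids), conditions, out)


ENRICHMENT_COLUMNS = (
    "fas_id",
    "constraint",
    "direction",
    "set_size",
    "subset_size",
    "weight_sum",
    "p_empirical",
    "q_bh",
)


def _format_float(x: float) -> str:
    # scientific below 1e-4 for p/q readability, fixed otherwise; >=6 sig digits
    if x != 0 and abs(x) < 1e-4:
        return f"{x:.6e}"
    return f"{x:.8g}"


def write_enrichment_table(records: Sequence, path: str | Path) -> None:
    """Write enrichment records to TSV, sorted by (constraint, direction, q, fas_id)."""
    path = Path(path)
    ordered = sorted(records, key=lambda r: (r.constraint, r.direction, r.q_bh, r.fas_id))
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ENRICHMENT_COLUMNS)
        for r in ordered:
            writer.writerow(
                [
                    r.fas_id,
                    r.constraint,
                    r.direction,
                    r.set_size,
                    r.subset_size,
                    _format_float(r.weight_sum),
                    _format_float(r.p_empirical),
                    _format_float(r.q_bh),
                ]
            )


def read_enrichment_table(path: str | Path) -> list:
    """Read back a TSV written by :func:`write_enrichment_table`."""
    from tmea.enrichment import EnrichmentRecord

    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != ENRICHMENT_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for row in reader:
            records.append(
                EnrichmentRecord(
                    fas_id=row[0],
                    constraint=int(row[1]),
                    direction=row[2],
                    set_size=int(row[3]),
                    subset_size=int(row[4]),
                    weight_sum=float(row[5]),
                    p_empirical=float(row[6]),
                    q_bh=float(row[7]),
                )
            )
    return records
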