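"""Readers and writers for the pipeline's tabular and graph text formats.

All inputs and outputs are plain UTF-8, TAB-delimited, LF-terminated text:

* prediction tables (TSV): one compound->protein docking prediction per row,
  with a dimensionless fit score;
* gene sets (GMT): the standard ``name<TAB>description<TAB>member...`` format,
  used both for the disease->target database and for pathway collections;
* interaction edge lists (two-column TSV, or SIF with an interaction-type
  middle column);
* herb membership tables (TSV): which compound belongs to which herb.

Writers are deterministic: identical in-memory input produces byte-identical
files, so reports can be diffed across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FormatError",
    "PredictionRecord",
    "DiseaseTargetDB",
    "PPIEdgeList",
    "check_target_id",
    "read_prediction_table",
    "write_prediction_table",
    "read_herb_membership",
    "write_herb_membership",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "format_pvalue",
    "write_report",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def check_target_id(value: str) -> str:
    """Validate an accession-like protein identifier (e.g. ``"P42574"``).

    Identifiers must be non-empty and contain no whitespace; comparison is
    case-sensitive exact match throughout the package.
    """
    if not value or any(c.isspace() for c in value):
        raise FormatError(f"invalid target identifier: {value!r}")
    return value


@dataclass(frozen=True)
class PredictionRecord:
    """One compound->protein target prediction with its docking fit score."""

    compound_id: str
    herb_id: str
    target: str
    fit_score: float

    def __post_init__(self) -> None:
        check_target_id(self.target)
        if not (self.fit_score >= 0):
            raise ValueError(
                f"fit_score must be non-negative, got {self.fit_score!r} "
                f"for {self.compound_id}->{self.target}"
            )


@dataclass(frozen=True)
class DiseaseTargetDB:
    """Named disease -> target-set mapping plus its target universe.

    ``entries`` preserves insertion order; ``universe`` is the union of all
    entries and its size is the population size N used in enrichment.
    """

    entries: dict[str, frozenset[str]]
    universe: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        for name, members in self.entries.items():
            if not members:
                raise ValueError(f"disease set {name!r} is empty")
        union: set[str] = set()
        for members in self.entries.values():
            union |= members
        object.__setattr__(self, "universe", frozenset(union))

    @property
    def n_universe(self) -> int:
        return len(self.universe)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PPIEdgeList:
    """Undirected protein-protein interactions as normalized unordered pairs.

    Pairs are stored lexicographically ordered; self-loops are dropped at
    parse time (their count is kept in ``n_self_loops_dropped``).
    """

    edges: frozenset[tuple[str, str]]
    n_self_loops_dropped: int = 0

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop in edge list: {a!r}")
            if a > b:
                raise ValueError(f"unnormalized pair: ({a!r}, {b!r})")

    def __len__(self) -> int:
        return len(self.edges)


def _normalize_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


_DEFAULT_DIALECT = {
    "herb": "herb",
    "compound": "compound",
    "target": "target",
    "fit_score": "fit_score",
}


def read_prediction_table(
    path: str, dialect: Mapping[str, str] | None = None
) -> list[PredictionRecord]:
    """Read a TSV of compound->target predictions, one record per data row.

    ``dialect`` maps the logical column names (``herb``, ``compound``,
    ``target``, ``fit_score``) to the header names used in the file.
    Row order is preserved. Malformed rows raise :class:`FormatError`
    citing the 1-based line number.
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        try:
            idx = {logical: header.index(name) for logical, name in cols.items()}
        except ValueError as exc:
            missing = [n for n in cols.values() if n not in header]
            raise FormatError(
                f"{path}: missing column(s) {missing} in header {header}"
            ) from exc
        records: list[PredictionRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) <= max(idx.values()):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            raw_score = fields[idx["fit_score"]]
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric fit score {raw_score!r}"
                ) from exc
            if not math.isfinite(score):
                raise FormatError(f"{path}:{lineno}: non-finite fit score {raw_score!r}")
            records.append(
                PredictionRecord(
                    compound_id=fields[idx["compound"]],
                    herb_id=fields[idx["herb"]],
                    target=check_target_id(fields[idx["target"]]),
                    fit_score=score,
                )
            )
    return records


def write_prediction_table(records: Iterable[PredictionRecord], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("herb\tcompound\ttarget\tfit_score\n")
        for r in records:
            fh.write(f"{r.herb_id}\t{r.compound_id}\t{r.target}\t{r.fit_score!r}\n")


def read_herb_membership(path: str) -> dict[str, tuple[str, ...]]:
    """Read a two-column ``herb<TAB>compound`` table into herb -> compounds.

    Insertion order of herbs and of compounds within a herb is preserved;
    duplicate (herb, compound) rows collapse.
    """
    membership: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: expected 2 columns, got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            herb, compound = fields[0], fields[1]
            bucket = membership.setdefault(herb, [])
            if compound not in bucket:
                bucket.append(compound)
    return {h: tuple(cs) for h, cs in membership.items()}


def write_herb_membership(membership: Mapping[str, Sequence[str]], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("herb\tcompound\n")
        for herb, compounds in membership.items():
            for c in compounds:
                fh.write(f"{herb}\t{c}\n")


def read_gmt(path: str) -> DiseaseTargetDB:
    """Read a GMT gene-set file into a :class:`DiseaseTargetDB`.

    Duplicate members within a set collapse; duplicate set names are an
    error; insertion order is preserved. Lines with fewer than three fields
    raise :class:`FormatError` with the line number.
    """
    entries: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member, got {len(fields)} field(s)"
                )
            name = fields[0]
            if name in entries:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(check_target_id(m) for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            entries[name] = members
    return DiseaseTargetDB(entries=entries)


def write_gmt(db: DiseaseTargetDB, path: str, descriptions: Mapping[str, str] | None = None) -> None:
    """Write a :class:`DiseaseTargetDB` as GMT; members sorted for stability."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in db.entries.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(members)) + "\n")


def read_edge_list(path: str, format: str = "tsv") -> PPIEdgeList:
    """Read an undirected interaction edge list (``tsv`` or ``sif``).

    Pairs are normalized (lexicographically smaller id first), duplicates
    collapse and self-loops are dropped; the number dropped is recorded on
    the returned :class:`PPIEdgeList`.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "sif":
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: SIF line needs source, type, target"
                    )
                a, b = fields[0], fields[2]
            else:
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 columns")
                a, b = fields[0], fields[1]
            check_target_id(a)
            check_target_id(b)
            if a == b:
                self_loops += 1
                continue
            edges.add(_normalize_edge(a, b))
    return PPIEdgeList(edges=frozenset(edges), n_self_loops_dropped=self_loops)


def write_edge_list(ppi: PPIEdgeList, path: str, format: str = "tsv") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in sorted(ppi.edges):
            if format == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def format_pvalue(p: float) -> str:
    """Render a probability the way the disease report prints it.

    Six decimal places with trailing zeros stripped (``0.006421``,
    ``0.1554``, ``1``), which keeps reports diffable against published
    enrichment tables.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability out of range: {p!r}")
    text = f"{p:.6f}".rstrip("0").rstrip(".")
    return text or "0"


def write_report(
    rows: Iterable[Mapping[str, object]],
    path: str,
    columns: Sequence[str],
) -> None:
    """Write a result table as TSV with a fixed column order.

    Columns whose name ends in ``p_value`` are rendered with
    :func:`format_pvalue`; other floats use ``repr`` (shortest round-trip
    form, locale-independent). Byte-identical across runs on equal input.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for col in columns:
                value = row[col]
                if col.endswith("p_value") and isinstance(value, float):
                    cells.append(format_pvalue(value))
                elif isinstance(value, float):
                    cells.append(repr(value))
                elif isinstance(value, bool):
                    cells.append("true" if value else "false")
                else:
                    cells.append(str(value))
            fh.write("\t".join(cells) + "\n")
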