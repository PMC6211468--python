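"""Reading, normalising and merging the pipeline's tabular inputs.

All identifiers are treated as opaque strings: they are stripped of
surrounding whitespace and upper-cased, nothing more.  An optional
two-column mapping table (``read_id_map`` / ``apply_id_map``) lets the
caller translate between namespaces (e.g. gene symbol -> UniProt) before
merging; no live identifier-mapping service is ever queried.

Supported formats: TSV/CSV with a header row, single-sheet XLSX,
GMT gene sets, GraphML and SIF network export.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TargetRecord",
    "TargetSet",
    "EdgeTable",
    "PathwayAnnotation",
    "SchemaError",
    "normalize_id",
    "read_target_table",
    "merge_target_sets",
    "intersect_target_sets",
    "read_edge_list",
    "merge_ppi_sources",
    "read_gene_sets",
    "write_gene_sets",
    "read_id_map",
    "apply_id_map",
    "write_network",
    "read_network",
]


class SchemaError(ValueError):
    """Raised when an input file does not match the declared schema."""


def normalize_id(raw: str) -> str:
    """Canonicalise an identifier: strip surrounding whitespace, upper-case."""
    return str(raw).strip().upper()


@dataclass(frozen=True)
class TargetRecord:
    """One target: canonical id, display symbol, provenance labels and tag."""

    id: str
    symbol: str = ""
    sources: tuple[str, ...] = ()
    tag: str = ""


@dataclass
class TargetSet:
    """A deduplicated set of targets keyed by canonical identifier."""

    records: dict[str, TargetRecord] = field(default_factory=dict)

    @property
    def ids(self) -> set[str]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, target_id: str) -> bool:
        return target_id in self.records

    def __iter__(self):
        return iter(self.records.values())

    def add(self, record: TargetRecord) -> bool:
        """Insert a record; first-seen wins for non-key fields.

        Provenance labels are always accumulated.  Returns True if the id
        was new.
        """
        if not record.id:
            raise ValueError("empty target id")
        existing = self.records.get(record.id)
        if existing is None:
            self.records[record.id] = record
            return True
        merged_sources = existing.sources + tuple(
            s for s in record.sources if s not in existing.sources
        )
        self.records[record.id] = TargetRecord(
            id=existing.id,
            symbol=existing.symbol or record.symbol,
            sources=merged_sources,
            tag=existing.tag or record.tag,
        )
        return False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": r.id, "symbol": r.symbol, "source_label": ";".join(r.sources), "tag": r.tag}
            for r in sorted(self.records.values(), key=lambda r: r.id)
        ]
        return pd.DataFrame(rows, columns=["id", "symbol", "source_label", "tag"])


@dataclass
class EdgeTable:
    """Undirected simple edge set with per-edge provenance.

    Each unordered pair is stored once under its sorted orientation;
    self-pairs are rejected at insertion.
    """

    edges: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.key(*pair) in self.edges

    def add(self, a: str, b: str, sources: Sequence[str] = ()) -> bool:
        """Insert one edge; returns True if the pair was new, False if merged."""
        if not a or not b:
            raise ValueError("empty edge endpoint id")
        if a == b:
            raise ValueError(f"self-loop {a!r}")
        k = self.key(a, b)
        existing = self.edges.get(k)
        if existing is None:
            self.edges[k] = tuple(sources)
            return True
        self.edges[k] = existing + tuple(s for s in sources if s not in existing)
        return False

    @property
    def node_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_a": a, "protein_b": b, "source_label": ";".join(src)}
            for (a, b), src in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "source_label"])


@dataclass
class PathwayAnnotation:
    """Named gene sets over a universe of identifiers."""

    pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.pathways)

    def restricted(self, universe: Iterable[str]) -> "PathwayAnnotation":
        """Restrict every pathway to the given universe of ids."""
        uni = frozenset(universe)
        return PathwayAnnotation(
            pathways={name: members & uni for name, members in self.pathways.items()},
            universe=uni,
        )


# ---------------------------------------------------------------------------
# table readers


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xlsm"}:
        return pd.read_excel(path, dtype=str)
    sep = "," if suffix == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_target_table(
    path: str | Path,
    source_label: str,
    id_column: str = "id",
    symbol_column: str | None = "symbol",
    source_column: str | None = "source_label",
    tag: str = "",
) -> TargetSet:
    """Read one target table into a deduplicated :class:`TargetSet`.

    Ids are trimmed and upper-cased; duplicate ids collapse to the first
    record seen (the number dropped is logged).  Provenance is taken from
    ``source_column`` when the file carries one (``;``-separated labels),
    otherwise every record is labelled ``source_label``.  An empty file
    yields an empty set with a warning; a missing id column is a
    :class:`SchemaError`.
    """
    frame = _read_table(path)
    out = TargetSet()
    if frame.empty:
        logger.warning("target table %s is empty (source %s)", path, source_label)
        return out
    if id_column not in frame.columns:
        raise SchemaError(f"{path}: missing id column {id_column!r} (has {list(frame.columns)})")
    has_symbol = symbol_column is not None and symbol_column in frame.columns
    has_source = source_column is not None and source_column in frame.columns
    has_tag = "tag" in frame.columns
    dropped = 0
    for _, row in frame.iterrows():
        raw = row[id_column]
        if pd.isna(raw) or not str(raw).strip():
            dropped += 1
            continue
        if has_source and pd.notna(row[source_column]) and str(row[source_column]).strip():
            sources = tuple(s for s in str(row[source_column]).split(";") if s)
        else:
            sources = (source_label,)
        record = TargetRecord(
            id=normalize_id(raw),
            symbol=str(row[symbol_column]).strip() if has_symbol and pd.notna(row[symbol_column]) else "",
            sources=sources,
            tag=str(row["tag"]).strip() if has_tag and pd.notna(row["tag"]) else tag,
        )
        if not out.add(record):
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d duplicate/empty rows (%d kept)", path, dropped, len(out))
    return out


def merge_target_sets(sets: Sequence[TargetSet]) -> TargetSet:
    """Union by id; provenance labels accumulate per id."""
    if not sets:
        raise ValueError("merge_target_sets requires at least one set")
    out = TargetSet()
    for ts in sets:
        for record in ts:
            out.add(record)
    return out


def intersect_target_sets(a: TargetSet, b: TargetSet) -> TargetSet:
    """Records of ``a`` whose ids also occur in ``b`` (labels from both)."""
    out = TargetSet()
    for record in a:
        if record.id in b:
            out.add(record)
            out.add(b.records[record.id])
    return out


def read_edge_list(
    path: str | Path,
    source_label: str = "",
    columns: tuple[str, str] | None = None,
    max_skip_fraction: float = 0.1,
) -> EdgeTable:
    """Read a two-column interaction table into an :class:`EdgeTable`.

    Self-loops are dropped (count logged), orientation is normalised and
    duplicate pairs collapse.  Unparseable rows are skipped with a warning,
    but the read fails if more than ``max_skip_fraction`` of rows skip.
    """
    frame = _read_table(path)
    out = EdgeTable()
    if frame.empty:
        logger.warning("edge list %s is empty", path)
        return out
    if columns is None:
        if frame.shape[1] < 2:
            raise SchemaError(f"{path}: need at least two columns for an edge list")
        col_a, col_b = frame.columns[:2]
    else:
        col_a, col_b = columns
        for col in (col_a, col_b):
            if col not in frame.columns:
                raise SchemaError(f"{path}: missing edge column {col!r}")
    skipped = loops = 0
    sources = (source_label,) if source_label else ()
    for _, row in frame.iterrows():
        raw_a, raw_b = row[col_a], row[col_b]
        if pd.isna(raw_a) or pd.isna(raw_b) or not str(raw_a).strip() or not str(raw_b).strip():
            skipped += 1
            continue
        a, b = normalize_id(raw_a), normalize_id(raw_b)
        if a == b:
            loops += 1
            continue
        out.add(a, b, sources)
    if loops:
        logger.info("%s: dropped %d self-loops", path, loops)
    if skipped:
        logger.warning("%s: skipped %d unparseable rows", path, skipped)
        if skipped > max_skip_fraction * len(frame):
            raise SchemaError(
                f"{path}: {skipped}/{len(frame)} rows unparseable "
                f"(> {max_skip_fraction:.0%} threshold)"
            )
    return out


def merge_ppi_sources(tables: Sequence[EdgeTable]) -> EdgeTable:
    """Union of unordered pairs across sources; provenance lists concatenate."""
    out = EdgeTable()
    for table in tables:
        for (a, b), sources in table.edges.items():
            out.add(a, b, sources)
    return out


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> PathwayAnnotation:
    """Parse a GMT file (name, description, tab-separated member ids)."""
    annotation = PathwayAnnotation()
    pathways: dict[str, frozenset[str]] = {}
    universe: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name = fields[0].strip()
            if not name:
                raise SchemaError(f"{path}:{lineno}: empty pathway name")
            if name in pathways:
                raise SchemaError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            members = frozenset(normalize_id(m) for m in fields[2:] if m.strip())
            pathways[name] = members
            universe |= members
    annotation.pathways = pathways
    annotation.universe = frozenset(universe)
    return annotation


def write_gene_sets(annotation: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name in sorted(annotation):
            members = sorted(annotation[name])
            handle.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# identifier mapping


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping (from_id -> to_id), normalised."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                continue
            mapping[normalize_id(row[0])] = normalize_id(row[1])
    return mapping


def apply_id_map(targets: TargetSet, mapping: Mapping[str, str]) -> TargetSet:
    """Translate target ids through a mapping; unmapped ids pass through."""
    out = TargetSet()
    for record in targets:
        new_id = mapping.get(record.id, record.id)
        out.add(TargetRecord(new_id, record.symbol, record.sources, record.tag))
    return out


# ---------------------------------------------------------------------------
# network export / import


def write_network(network: "InteractionNetwork", path: str | Path, format: str = "graphml") -> None:
    """Export a network as GraphML (class labels kept) or SIF (labels dropped)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "sif":
        with open(path, "w") as handle:
            for a, b in sorted(EdgeTable.key(a, b) for a, b in network.graph.edges):
                handle.write(f"{a}\tpp\t{b}\n")
            for node in sorted(nx.isolates(network.graph)):
                handle.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format {format!r} (expected graphml or sif)")


def read_network(path: str | Path) -> "InteractionNetwork":
    """Re-import a GraphML export; inverse of :func:`write_network`."""
    from .network import InteractionNetwork

    graph = nx.read_graphml(path)
    for _, data in graph.nodes(data=True):
        data.setdefault("node_class", "linker")
    return InteractionNetwork(graph=graph)
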