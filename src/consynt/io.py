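"""Domain types and readers/writers for the tabular and genomic formats the pipeline touches.

Coordinates are stored 1-based inclusive throughout the package; BED input
(0-based half-open) is converted on read and converted back on write.  Strand
is retained but no downstream analysis is strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """A malformed row in an input file; message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene placed on a genome: 1-based inclusive coordinates.

    ``(species, gene_id)`` is the unique key within any dataset.
    """

    gene_id: str
    symbol: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RiskGeneSet:
    """An ordered, de-duplicated list of risk-gene symbols."""

    label: str
    members: list[str]
    source_refs: list[str] = field(default_factory=list)
    variant_ids: list[str] | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"risk set {self.label!r} has duplicate members")


@dataclass
class PhenotypeAnnotation:
    """Free-text phenotype terms for one gene plus derived category flags.

    ``essential`` is always derived as ``lethal or sterile`` and never stored
    independently.
    """

    gene_id: str
    terms: list[str] = field(default_factory=list)
    lethal: bool = False
    sterile: bool = False
    lifespan_affected: bool = False
    stage_category: str = "none"

    @property
    def essential(self) -> bool:
        return self.lethal or self.sterile


class InteractionGraph:
    """An undirected gene-gene interaction graph without self-loops or duplicates.

    Internally edges are kept as two parallel integer index arrays so that
    within-set edge counting stays vectorized for resampling nulls; the
    ``edges`` property materializes the conventional set-of-pairs view.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = (), nodes: Iterable[str] = ()):
        seen: set[tuple[str, str]] = set()
        node_list: list[str] = []
        index: dict[str, int] = {}

        def idx(g: str) -> int:
            i = index.get(g)
            if i is None:
                i = len(node_list)
                index[g] = i
                node_list.append(g)
            return i

        n_self = n_dup = 0
        pairs: list[tuple[int, int]] = []
        for a, b in edges:
            if a == b:
                n_self += 1
                idx(a)
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            pairs.append((idx(key[0]), idx(key[1])))
        for g in nodes:
            idx(g)
        if n_self or n_dup:
            logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
        self._nodes = node_list
        self._index = index
        if pairs:
            arr = np.asarray(pairs, dtype=np.int64)
            self._u, self._v = arr[:, 0].copy(), arr[:, 1].copy()
        else:
            self._u = np.empty(0, dtype=np.int64)
            self._v = np.empty(0, dtype=np.int64)

    @classmethod
    def from_arrays(
        cls, node_names: Sequence[str], edge_u: np.ndarray, edge_v: np.ndarray
    ) -> "InteractionGraph":
        """Fast constructor from pre-validated index arrays (no self-loops/dups)."""
        g = cls.__new__(cls)
        g._nodes = list(node_names)
        g._index = {name: i for i, name in enumerate(g._nodes)}
        g._u = np.asarray(edge_u, dtype=np.int64)
        g._v = np.asarray(edge_v, dtype=np.int64)
        if np.any(g._u == g._v):
            raise ValidationError("self-loop in edge arrays")
        return g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def node_list(self) -> list[str]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return int(self._u.size)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {
            frozenset((self._nodes[int(a)], self._nodes[int(b)]))
            for a, b in zip(self._u, self._v)
        }

    def node_index(self, gene_id: str) -> int | None:
        return self._index.get(gene_id)

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._u, self._v

    def membership_mask(self, genes: Iterable[str]) -> np.ndarray:
        """Boolean mask over internal node order for the given gene ids."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        for g in genes:
            i = self._index.get(g)
            if i is not None:
                mask[i] = True
        return mask

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(
            (self._nodes[int(a)], self._nodes[int(b)]) for a, b in zip(self._u, self._v)
        )
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"InteractionGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# coordinate files


def _iter_data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_gene_coordinates(path: str | Path, format: str) -> list[GeneRecord]:
    """Read gene coordinates from BED6 or GFF3 into 1-based inclusive records.

    BED intervals (0-based half-open) are converted on read; GFF3 rows are
    restricted to feature type ``gene``.  The species tag is taken from the
    file stem unless a ``species=`` attribute (GFF3) is present.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt not in {"BED6", "GFF3"}:
        raise ValueError(f"unknown coordinate format {format!r}")
    records: list[GeneRecord] = []
    species_default = path.stem
    seen_keys: set[tuple[str, str]] = set()
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if fmt == "BED6":
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 row has {len(fields)} columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start0, end0 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            start, end = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
            if end < start:
                raise ValidationError(
                    f"{path}:{lineno}: inverted interval after conversion"
                )
            rec = GeneRecord(
                gene_id=name,
                symbol=name,
                species=species_default,
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand if strand in VALID_STRANDS else ".",
            )
        else:  # GFF3
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 row has {len(fields)} columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ValidationError(f"{path}:{lineno}: end < start")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID", attr_map.get("gene_id", f"line{lineno}"))
            rec = GeneRecord(
                gene_id=gene_id,
                symbol=attr_map.get("Name", gene_id),
                species=attr_map.get("species", species_default),
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand if strand in VALID_STRANDS else ".",
            )
        key = (rec.species, rec.gene_id)
        if key in seen_keys:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {rec.gene_id!r}")
        seen_keys.add(key)
        records.append(rec)
    if not records:
        logger.warning("no gene records read from %s", path)
    return records


def write_gene_coordinates(
    records: Sequence[GeneRecord], path: str | Path, format: str
) -> None:
    """Write records as BED6 (converting back to 0-based half-open) or GFF3."""
    path = Path(path)
    fmt = format.upper()
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            if fmt == "BED6":
                fh.write(
                    f"{rec.chromosome}\t{rec.start - 1}\t{rec.end}\t"
                    f"{rec.gene_id}\t0\t{rec.strand}\n"
                )
            elif fmt == "GFF3":
                attrs = f"ID={rec.gene_id};Name={rec.symbol};species={rec.species}"
                fh.write(
                    f"{rec.chromosome}\tconsynt\tgene\t{rec.start}\t{rec.end}\t."
                    f"\t{rec.strand}\t.\t{attrs}\n"
                )
            else:
                raise ValueError(f"unknown coordinate format {format!r}")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path) -> InteractionGraph:
    """Read a two-column TSV of gene-id pairs into an undirected graph.

    Duplicate edges (in either orientation) and self-loops are dropped with
    counts logged; a header row ``gene_a<TAB>gene_b`` is tolerated.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        if lineno == 1 and fields[0].lower() in {"gene_a", "source", "gene1"}:
            continue
        pairs.append((fields[0], fields[1]))
    return InteractionGraph(pairs)


def write_edge_list(graph: InteractionGraph, path: str | Path) -> None:
    path = Path(path)
    names = graph.node_list
    u, v = graph.edge_index_arrays()
    rows = sorted(
        tuple(sorted((names[int(a)], names[int(b)]))) for a, b in zip(u, v)
    )
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# risk sets and simple tables


def read_risk_set(
    path: str | Path, label: str | None = None, case_fold: bool = True
) -> RiskGeneSet:
    """Read a risk-gene TSV (header required, ``symbol`` column) into a set.

    Duplicates are removed preserving first occurrence.  With ``case_fold``
    (default) symbols differing only in case are treated as the same gene and
    reported under their first-seen spelling.
    """
    path = Path(path)
    header: list[str] | None = None
    members: list[str] = []
    variant_ids: list[str] = []
    seen: set[str] = set()
    n_rows = 0
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            if "symbol" not in header:
                raise ParseError(f"{path}:1: header lacks a 'symbol' column")
            continue
        row = dict(zip(header, fields))
        symbol = row.get("symbol", "").strip()
        if not symbol:
            raise ValidationError(f"{path}:{lineno}: empty symbol cell")
        n_rows += 1
        key = symbol.casefold() if case_fold else symbol
        if key in seen:
            continue
        seen.add(key)
        members.append(symbol)
        variant_ids.append(row.get("variant_ids", ""))
    logger.info("risk set %s: %d rows -> %d unique symbols", path, n_rows, len(members))
    return RiskGeneSet(
        label=label or path.stem,
        members=members,
        variant_ids=variant_ids if any(variant_ids) else None,
    )


def read_phenotype_table(path: str | Path) -> list[PhenotypeAnnotation]:
    """Read a phenotype TSV (``gene_id``, semicolon-joined ``terms``)."""
    path = Path(path)
    header: list[str] | None = None
    out: list[PhenotypeAnnotation] = []
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = [h.strip().lower() for h in fields]
            if "gene_id" not in header or "terms" not in header:
                raise ParseError(f"{path}:1: header needs gene_id and terms columns")
            continue
        row = dict(zip(header, fields))
        terms = [t.strip() for t in row.get("terms", "").split(";") if t.strip()]
        out.append(PhenotypeAnnotation(gene_id=row["gene_id"], terms=terms))
    return out


def write_phenotype_table(
    annotations: Sequence[PhenotypeAnnotation], path: str | Path
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\tterms\n")
        for ann in annotations:
            fh.write(f"{ann.gene_id}\t{';'.join(ann.terms)}\n")


def read_lookup_table(
    path: str | Path, key_col: str = "human_gene", value_col: str = "target_gene"
) -> dict[str, str]:
    """Read a two-column curated ortholog lookup TSV into a dict.

    Rows whose value cell is empty or the literal ``None`` are skipped (the
    convention used to record 'no counterpart' explicitly).
    """
    path = Path(path)
    header: list[str] | None = None
    out: dict[str, str] = {}
    for lineno, line in _iter_data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = [h.strip() for h in fields]
            for col in (key_col, value_col):
                if col not in header:
                    raise ParseError(f"{path}:1: header lacks column {col!r}")
            continue
        row = dict(zip(header, fields))
        value = row.get(value_col, "").strip()
        if not value or value.lower() == "none":
            continue
        out[row[key_col].strip()] = value
    return out
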