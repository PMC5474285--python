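"""Domain types and readers/writers for the tabular and graph formats.

All tabular inputs are tab-separated with a mandatory header; comma-separated
input is rejected rather than sniffed so parsing stays deterministic. Gene
symbols are uppercased at ingest and matched by exact string equality
thereafter.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError

# Standard UniProt accession pattern (old 6-char and new 10-char forms).
_UNIPROT_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)

EDGE_SOURCES = frozenset({"TCMSP", "SEA", "BINDINGDB", "SYNTHETIC", "FIXTURE"})


@dataclass(frozen=True)
class CompoundRecord:
    """One herb compound with its predicted ADME profile.

    ob_percent is oral bioavailability in percent; caco2 the predicted
    Caco-2 permeability score; dl the drug-likeness index. dl may be
    negative (the compound table contains -2.18), so no [0, 1] bound is
    imposed.
    """

    compound_id: str
    name: str
    ob_percent: float
    caco2: float
    dl: float


@dataclass(frozen=True)
class DescriptorVector:
    """Ordered molecular-descriptor vector, fixed length per dataset."""

    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValidationError("descriptor vector must be non-empty")
        if not all(math.isfinite(v) for v in self.values):
            raise ValidationError("descriptor vector entries must be finite")


@dataclass(frozen=True)
class TargetRecord:
    """One protein target: UniProt accession, protein name, gene symbol."""

    uniprot_id: str
    protein_name: str
    gene_symbol: str


@dataclass(frozen=True)
class InteractionEdge:
    """One compound->target link with database provenance."""

    compound_id: str
    uniprot_id: str
    sources: frozenset[str]

    def __post_init__(self):
        bad = self.sources - EDGE_SOURCES
        if bad:
            raise ValidationError(f"unknown edge source(s): {sorted(bad)}")


@dataclass
class ExpressionMatrix:
    """Nonnegative gene-or-probe x tissue-or-sample intensity matrix."""

    values: pd.DataFrame  # rows: probe/gene ids; columns: tissue/sample labels
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate column labels in expression matrix")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate row ids in expression matrix")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be nonnegative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style); members are uppercased symbols."""

    sets: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self):
        ids = [s[0] for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate set_id in gene-set collection")
        for set_id, _desc, members in self.sets:
            if not members:
                raise ValidationError(f"gene set {set_id!r} is empty")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        for sid, _d, m in self.sets:
            if sid == set_id:
                return m
        raise KeyError(set_id)

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for _s, _d, m in self.sets:
            out |= m
        return frozenset(out)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if "\t" not in header and "," in header:
        raise ParseError(f"{path}: expected tab-separated input, found commas "
                         "in header (comma dialects are rejected, not sniffed)")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment=None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_float(raw: str, row: int, column: str) -> float:
    # tolerate the Unicode minus that survives copy/paste from typeset tables
    txt = raw.strip().replace("−", "-")
    try:
        val = float(txt)
    except ValueError:
        raise ParseError(f"non-numeric value {raw!r}", row=row, column=column)
    if not math.isfinite(val):
        raise ParseError(f"non-finite value {raw!r}", row=row, column=column)
    return val


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound ADME table (TSV: compound_id, name, ob_percent, caco2, dl)."""
    df = _read_tsv(path, ["compound_id", "name", "ob_percent", "caco2", "dl"])
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cid = row.compound_id.strip()
        if not cid:
            raise ParseError("empty compound_id", row=i, column="compound_id")
        if cid in seen:
            raise ParseError(f"duplicate compound_id {cid!r}", row=i,
                             column="compound_id")
        seen.add(cid)
        ob = _parse_float(row.ob_percent, i, "ob_percent")
        if ob < 0:
            raise ValidationError(f"ob_percent must be >= 0, got {ob} "
                                  f"(row {i}, compound {cid})")
        records.append(CompoundRecord(
            compound_id=cid, name=row.name.strip(), ob_percent=ob,
            caco2=_parse_float(row.caco2, i, "caco2"),
            dl=_parse_float(row.dl, i, "dl")))
    return records


def read_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a target table (TSV: uniprot_id, protein_name, gene_symbol).

    Gene symbols are uppercased; duplicate accessions are rejected.
    """
    df = _read_tsv(path, ["uniprot_id", "protein_name", "gene_symbol"])
    records: list[TargetRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        acc = row.uniprot_id.strip()
        if not _UNIPROT_RE.match(acc):
            raise ParseError(f"malformed UniProt accession {acc!r}", row=i,
                             column="uniprot_id")
        if acc in seen:
            raise ParseError(f"duplicate uniprot_id {acc!r}", row=i,
                             column="uniprot_id")
        seen.add(acc)
        sym = row.gene_symbol.strip().upper()
        if not sym:
            raise ParseError("empty gene_symbol", row=i, column="gene_symbol")
        records.append(TargetRecord(uniprot_id=acc,
                                    protein_name=row.protein_name.strip(),
                                    gene_symbol=sym))
    return records


def read_edge_table(path: str | Path) -> list[InteractionEdge]:
    """Read a compound-target edge list (TSV: compound_id, uniprot_id, source)."""
    df = _read_tsv(path, ["compound_id", "uniprot_id", "source"])
    edges = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        src = row.source.strip().upper()
        if src not in EDGE_SOURCES:
            raise ParseError(f"unknown source {row.source!r}", row=i,
                             column="source")
        edges.append(InteractionEdge(compound_id=row.compound_id.strip(),
                                     uniprot_id=row.uniprot_id.strip(),
                                     sources=frozenset({src})))
    return edges


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set_id TAB description TAB member..."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs set_id, description and at "
                                 "least one member", line=lineno)
            members = frozenset(p.strip().upper() for p in parts[2:]
                                if p.strip())
            if not members:
                raise ParseError("GMT line has no non-empty members",
                                 line=lineno)
            sets.append((parts[0].strip(), parts[1].strip(), members))
    return GeneSetCollection(sets=sets)


def read_expression_matrix(path: str | Path,
                           probe_to_gene: dict[str, str] | None = None
                           ) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column row_id, rest tissue labels."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if "\t" not in header and "," in header:
            raise ParseError(f"{path}: expected tab-separated input")
        cols = header.split("\t")
        ncol = len(cols)
        rows: list[str] = []
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ParseError(f"ragged row: expected {ncol} fields, "
                                 f"got {len(parts)}", line=lineno)
            rows.append(parts[0])
            vals = [_parse_float(p, lineno - 1, cols[j + 1])
                    for j, p in enumerate(parts[1:])]
            data.append(vals)
    df = pd.DataFrame(data, index=rows, columns=cols[1:], dtype=float)
    return ExpressionMatrix(values=df, probe_to_gene=probe_to_gene)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "row_id"
    df.to_csv(path, sep="\t")


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tname\tob_percent\tcaco2\tdl\n")
        for r in records:
            fh.write(f"{r.compound_id}\t{r.name}\t{r.ob_percent!r}\t"
                     f"{r.caco2!r}\t{r.dl!r}\n")


def write_target_table(records: list[TargetRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("uniprot_id\tprotein_name\tgene_symbol\n")
        for r in records:
            fh.write(f"{r.uniprot_id}\t{r.protein_name}\t{r.gene_symbol}\n")


def write_edge_table(edges: list[InteractionEdge], path: str | Path) -> None:
    """One row per (edge, source): the reader re-merges provenance."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tuniprot_id\tsource\n")
        for e in edges:
            for s in sorted(e.sources):
                fh.write(f"{e.compound_id}\t{e.uniprot_id}\t{s}\n")


# --- network export --------------------------------------------------------

NETWORK_DIALECTS = ("sif", "graphml", "edge-tsv")


def write_network(network, path: str | Path, dialect: str = "edge-tsv",
                  attributes: pd.DataFrame | None = None) -> None:
    """Export a bipartite network for external viewers (e.g. Cytoscape).

    dialect: 'sif', 'graphml' or 'edge-tsv'. A node-attribute table
    (partition, degree, betweenness) is written alongside as
    `<path>.nodes.tsv`; nodes without computed attributes get empty fields.
    """
    path = Path(path)
    if dialect not in NETWORK_DIALECTS:
        raise ValidationError(f"unknown network dialect {dialect!r}; "
                              f"expected one of {NETWORK_DIALECTS}")
    edges = sorted((min(u, v), max(u, v)) for u, v in network.edges())
    if dialect == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in edges:
                fh.write(f"{u}\tinteracts\t{v}\n")
    elif dialect == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\n")
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
    _write_node_attributes(network, path.with_suffix(path.suffix + ".nodes.tsv"),
                           attributes)


def _write_node_attributes(network, path: Path,
                           attributes: pd.DataFrame | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tpartition\tdegree\tbetweenness\n")
        for node in sorted(network.nodes()):
            part = "left" if node in network.left_nodes else "right"
            deg = bet = ""
            if attributes is not None and node in attributes.index:
                row = attributes.loc[node]
                deg = str(int(row["degree"])) if "degree" in row else ""
                if "betweenness" in row and pd.notna(row["betweenness"]):
                    bet = repr(float(row["betweenness"]))
            fh.write(f"{node}\t{part}\t{deg}\t{bet}\n")


def read_network_edge_tsv(path: str | Path) -> set[tuple[str, str]]:
    """Read an edge-TSV back as a set of canonically ordered pairs."""
    df = _read_tsv(path, ["source", "target"])
    return {(min(r.source, r.target), max(r.source, r.target))
            for r in df.itertuples(index=False)}


# --- packaged fixtures -----------------------------------------------------

_DATA = Path(__file__).parent / "data"


def load_compound_fixture() -> list[CompoundRecord]:
    """The packaged 32-compound ADME table."""
    return read_compound_table(_DATA / "table1_compounds.tsv")


def load_target_fixture() -> list[TargetRecord]:
    """The packaged 182-target table."""
    return read_target_table(_DATA / "table2_targets.tsv")


def load_common_gene_fixture() -> list[TargetRecord]:
    """The packaged table of targets also upregulated in Crohn's disease."""
    return read_target_table(_DATA / "table3_common_genes.tsv")


def _read_id_list(path: Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line list file ('#' comments allowed)."""
    return _read_id_list(Path(path))


def load_rescue_ids() -> list[str]:
    """Compound ids kept despite failing thresholds (literature support)."""
    return _read_id_list(_DATA / "rescue_compounds.txt")


def load_organ_panel() -> list[str]:
    """The 17 immunity-related tissues of the organ-localization panel."""
    return _read_id_list(_DATA / "organ_panel.txt")


def load_ibd_pathway() -> GeneSetCollection:
    """Minimal core-gene excerpt of the KEGG IBD pathway, as a GMT set."""
    return read_gmt(_DATA / "ibd_pathway.gmt")
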