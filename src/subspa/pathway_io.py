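"""Readers and writers for every external format the pipeline touches.

Formats
-------
* KGML (KEGG Markup Language) pathway topology -> :class:`PathwayGraph`.
* Regulation TSV (``lncrna_id<TAB>gene_id``) -> :class:`RegulationTable`.
* Expression TSV (features x samples, non-negative) -> ``pandas.DataFrame``.
* Clinical TSV (``sample_id<TAB>time<TAB>event[<TAB>group]``) -> ``pandas.DataFrame``.
* Subpathway definition file (``.spw``, documented below) for
  :class:`subspa.mining.SubpathwayGraph` lists.

All readers validate their input and raise :class:`subspa.errors.InputError`
(or :class:`~subspa.errors.KgmlParseError`) naming the offending record
rather than silently repairing it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree

from subspa.errors import InputError, KgmlParseError

logger = logging.getLogger(__name__)

# identifiers travel through tab-, comma- and hyphen-separated text formats
_FORBIDDEN_ID_CHARS = ("\t", ",", "-", "\n")


def _check_identifier(ident: str, context: str) -> None:
    if not ident:
        raise InputError(f"empty identifier in {context}")
    for ch in _FORBIDDEN_ID_CHARS:
        if ch in ident:
            raise InputError(
                f"identifier {ident!r} in {context} contains forbidden character {ch!r}"
            )


@dataclass(eq=False)
class PathwayGraph:
    """Undirected gene-interaction graph parsed from one pathway.

    Nodes are gene identifiers kept verbatim from the source (e.g.
    ``hsa:5290``); edges are unordered gene pairs. Self-loops are never
    stored.
    """

    pathway_id: str
    name: str
    graph: nx.Graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self.graph.edges)

    def validate(self) -> None:
        for u, v in self.graph.edges:
            if u == v:
                raise InputError(f"self-loop on {u!r} in pathway {self.pathway_id}")

    @classmethod
    def from_edges(
        cls, pathway_id: str, name: str, nodes: Iterable[str], edges: Iterable[tuple]
    ) -> "PathwayGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                raise InputError(f"self-loop on {u!r} in pathway {pathway_id}")
            if u not in g or v not in g:
                raise InputError(
                    f"edge ({u!r}, {v!r}) references unknown node in pathway {pathway_id}"
                )
            g.add_edge(u, v)
        return cls(pathway_id, name, g)


@dataclass(frozen=True)
class RegulationTable:
    """Non-redundant (lncRNA, gene) competitive-regulation pairs.

    The lncRNA and gene identifier namespaces must be disjoint: one
    identifier cannot appear on both sides of the table.
    """

    pairs: frozenset

    def __post_init__(self):
        lnc = {p[0] for p in self.pairs}
        gene = {p[1] for p in self.pairs}
        clash = lnc & gene
        if clash:
            raise InputError(
                f"identifier(s) {sorted(clash)[:5]} appear as both lncRNA and gene"
            )

    @property
    def lncrnas(self) -> frozenset:
        return frozenset(p[0] for p in self.pairs)

    @property
    def genes(self) -> frozenset:
        return frozenset(p[1] for p in self.pairs)

    def targets_of(self, lncrna: str) -> frozenset:
        return frozenset(g for l, g in self.pairs if l == lncrna)


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------

def read_kgml(path, bridge_compounds: bool = False) -> PathwayGraph:
    """Parse one KGML file into an undirected gene graph.

    Only entries of type ``gene`` become nodes; entry ``name`` tokens are
    kept verbatim, and multi-gene entries are expanded so every member
    inherits the entry's relations. ``group`` entries are flattened to
    their member genes with a clique among them. ``map`` and other
    non-gene entries are dropped. With ``bridge_compounds``, two gene
    entries that are both related to the same compound entry gain a
    direct edge (off by default).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        if isinstance(exc, OSError):
            raise
        raise KgmlParseError(f"malformed KGML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise KgmlParseError(f"malformed KGML in {path}: root element is <{root.tag}>")
    pathway_id = root.get("name", path.stem)
    title = root.get("title", "")

    entry_genes: dict[str, list[str]] = {}   # entry id -> gene tokens
    entry_type: dict[str, str] = {}
    group_members: dict[str, list[str]] = {}  # group entry id -> component entry ids
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        entry_type[eid] = etype
        if etype == "gene":
            entry_genes[eid] = entry.get("name", "").split()
        elif etype == "group":
            group_members[eid] = [c.get("id") for c in entry.findall("component")]

    def genes_of(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in group_members:
            out: list[str] = []
            for mid in group_members[eid]:
                out.extend(genes_of(mid))
            return out
        return []

    g = nx.Graph()
    for genes in entry_genes.values():
        g.add_nodes_from(genes)

    # group entries: clique among member genes
    for gid in group_members:
        members = genes_of(gid)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                if u != v:
                    g.add_edge(u, v)

    compound_partners: dict[str, set] = {}
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        g1, g2 = genes_of(e1), genes_of(e2)
        for u in g1:
            for v in g2:
                if u != v:
                    g.add_edge(u, v)
        if bridge_compounds:
            for eid, other in ((e1, e2), (e2, e1)):
                if entry_type.get(eid) == "compound":
                    compound_partners.setdefault(eid, set()).update(genes_of(other))

    if bridge_compounds:
        for partners in compound_partners.values():
            members = sorted(partners)
            for i, u in enumerate(members):
                for v in members[i + 1:]:
                    g.add_edge(u, v)

    if g.number_of_nodes() == 0:
        warnings.warn(f"KGML {path} contains no gene entries; empty graph", stacklevel=2)
    pg = PathwayGraph(pathway_id, title, g)
    pg.validate()
    return pg


# ---------------------------------------------------------------------------
# Regulation table
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"lncrna", "lnc", "lncrna_id", "gene", "gene_id", "mrna", "target"}


def read_regulations(path) -> RegulationTable:
    """Read a two-column ``lncrna<TAB>gene`` TSV; duplicates collapse.

    A header row is auto-detected when its fields look like column names
    (``lncRNA``, ``gene`` and friends) rather than identifiers.
    """
    path = Path(path)
    pairs: set[tuple] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated fields")
            lnc, gene = fields[0].strip(), fields[1].strip()
            if lineno == 1 and lnc.lower() in _HEADER_TOKENS and gene.lower() in _HEADER_TOKENS:
                continue
            pairs.add((lnc, gene))
    if not pairs:
        warnings.warn(f"regulation table {path} is empty", stacklevel=2)
    table = RegulationTable(frozenset(pairs))
    logger.info(
        "read %d regulations (%d lncRNAs, %d genes) from %s",
        len(table.pairs), len(table.lncrnas), len(table.genes), path,
    )
    return table


def write_regulations(table: RegulationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for lnc, gene in sorted(table.pairs):
            fh.write(f"{lnc}\t{gene}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def validate_expression(df: pd.DataFrame, origin: str = "expression matrix") -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{origin}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise InputError(f"{origin}: duplicate sample id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InputError(f"{origin}: non-numeric values present")
    if np.isnan(values).any():
        feat = df.index[np.isnan(values).any(axis=1)][0]
        raise InputError(f"{origin}: missing value in feature {feat!r}")
    if not np.isfinite(values).all():
        feat = df.index[~np.isfinite(values).all(axis=1)][0]
        raise InputError(f"{origin}: non-finite value in feature {feat!r}")
    if (values < 0).any():
        feat = df.index[(values < 0).any(axis=1)][0]
        raise InputError(f"{origin}: negative value in feature {feat!r}")
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a features-x-samples TSV with a header row of sample ids."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric expression value ({exc})") from exc
    return validate_expression(df, origin=str(path))


def write_expression(df: pd.DataFrame, path) -> None:
    validate_expression(df)
    df.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

def validate_clinical(df: pd.DataFrame, origin: str = "clinical table") -> pd.DataFrame:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{origin}: duplicate sample id {dup!r}")
    if "time" not in df.columns or "event" not in df.columns:
        raise InputError(f"{origin}: columns 'time' and 'event' are required")
    if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
        bad = df.index[(df["time"] <= 0) | ~np.isfinite(df["time"])][0]
        raise InputError(f"{origin}: non-positive survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0]
        raise InputError(f"{origin}: event flag for sample {bad!r} not in {{0,1}}")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read ``sample_id<TAB>time<TAB>event[<TAB>group]``, indexed by sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected at least time and event columns")
    df = df.rename(columns=dict(zip(df.columns[:2], ["time", "event"])))
    if df.shape[1] >= 3:
        df = df.rename(columns={df.columns[2]: "group"})
    try:
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric clinical value ({exc})") from exc
    return validate_clinical(df, origin=str(path))


def write_clinical(df: pd.DataFrame, path) -> None:
    validate_clinical(df)
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Subpathway definition files (.spw)
# ---------------------------------------------------------------------------
#
# Two lines per subpathway, bit-exact on round trip:
#   S<TAB>id<TAB>parent_id<TAB>parent_name<TAB>GENES=g1,g2,...<TAB>LNC=l1,l2,...
#   E<TAB>id<TAB>g1-g2,g2-g3,...<TAB>l1-g1,l2-g3,...
# Members and edges are written in sorted order; identifiers must not
# contain tab, comma or hyphen.

def write_subpathways(subpathways: Sequence, path) -> None:
    from subspa.mining import SubpathwayGraph  # local import avoids a cycle

    with open(path, "w", encoding="utf-8") as fh:
        for sub in subpathways:
            if not isinstance(sub, SubpathwayGraph):
                raise InputError(f"cannot serialize object of type {type(sub).__name__}")
            for ident in [sub.subpathway_id, *sub.genes, *sub.lncrnas]:
                # pathway-scoped ids like "path:05215_1" contain ':' which is fine
                _check_identifier(ident, f"subpathway {sub.subpathway_id}")
            genes = ",".join(sorted(sub.genes))
            lncs = ",".join(sorted(sub.lncrnas))
            gene_edges = ",".join(
                "-".join(sorted(e)) for e in sorted(sub.gene_edges, key=lambda e: sorted(e))
            )
            reg_edges = ",".join(f"{l}-{g}" for l, g in sorted(sub.reg_edges))
            fh.write(
                f"S\t{sub.subpathway_id}\t{sub.parent_id}\t{sub.parent_name}"
                f"\tGENES={genes}\tLNC={lncs}\n"
            )
            fh.write(f"E\t{sub.subpathway_id}\t{gene_edges}\t{reg_edges}\n")


def read_subpathways(path) -> list:
    from subspa.mining import SubpathwayGraph

    path = Path(path)
    out: list = []
    pending: dict | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if pending is not None:
                    raise InputError(f"{path}:{lineno}: S line before E line of previous record")
                if len(fields) != 6:
                    raise InputError(f"{path}:{lineno}: S line needs 6 fields, got {len(fields)}")
                _, sid, parent_id, parent_name, genes_f, lnc_f = fields
                if not genes_f.startswith("GENES=") or not lnc_f.startswith("LNC="):
                    raise InputError(f"{path}:{lineno}: malformed GENES=/LNC= fields")
                genes = frozenset(x for x in genes_f[6:].split(",") if x)
                lncs = frozenset(x for x in lnc_f[4:].split(",") if x)
                pending = dict(
                    subpathway_id=sid, parent_id=parent_id,
                    parent_name=parent_name, genes=genes, lncrnas=lncs,
                )
            elif tag == "E":
                if pending is None or len(fields) != 4 or fields[1] != pending["subpathway_id"]:
                    raise InputError(f"{path}:{lineno}: E line does not match preceding S line")
                gene_edges = frozenset(
                    frozenset(tok.split("-")) for tok in fields[2].split(",") if tok
                )
                reg_edges = frozenset(
                    tuple(tok.split("-")) for tok in fields[3].split(",") if tok
                )
                sub = SubpathwayGraph(
                    gene_edges=gene_edges, reg_edges=reg_edges, **pending
                )
                sub.validate()
                out.append(sub)
                pending = None
            else:
                raise InputError(f"{path}:{lineno}: unknown record tag {tag!r}")
    if pending is not None:
        raise InputError(f"{path}: truncated file, missing E line for {pending['subpathway_id']}")
    return out
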