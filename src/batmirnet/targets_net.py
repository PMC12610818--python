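"""High-confidence miRNA-target filtering and regulatory-network assembly.

Candidate miRNA-gene interactions are retained only when all three criteria
hold: binding score exactly 1, binding position in the 3'-UTR, and a
validated interaction accession present.  Retained interactions form the
bipartite miRNA-gene layer; gene-gene association edges are merged in to
give a mixed simple undirected network that downstream entropy analysis
consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("3UTR", "5UTR", "CDS")
VALIDATED_PATTERN = re.compile(r"^MIRT\d+$")

INTERACTION_COLUMNS = ["mirna", "gene", "coding_protein", "binding_score",
                       "region", "binding_energy", "validated_id"]


@dataclass(frozen=True)
class InteractionRecord:
    mirna_id: str
    gene_id: str
    binding_score: float
    region: str
    validated_id: str = ""
    binding_energy: float | None = None
    coding_protein: str = ""

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if not 0.0 <= self.binding_score <= 1.0:
            raise ValueError("binding_score must lie in [0, 1]")


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mirna_id, r.gene_id, r.coding_protein, r.binding_score, r.region,
          r.binding_energy, r.validated_id) for r in records],
        columns=INTERACTION_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[InteractionRecord]:
    out = []
    for idx, row in df.iterrows():
        region = str(row["region"])
        if region not in REGIONS:
            raise ValueError(f"row {idx}: malformed region token {region!r}")
        out.append(InteractionRecord(
            mirna_id=str(row["mirna"]), gene_id=str(row["gene"]),
            binding_score=float(row["binding_score"]), region=region,
            validated_id="" if pd.isna(row.get("validated_id", "")) else str(row["validated_id"]),
            binding_energy=(None if pd.isna(row.get("binding_energy"))
                            else float(row["binding_energy"])),
            coding_protein=str(row.get("coding_protein", ""))))
    return out


def filter_interactions(
    records: list[InteractionRecord],
    require_score: float = 1.0,
    require_region: str = "3UTR",
    require_validated: bool = True,
    strict_validated_pattern: bool = False,
) -> list[InteractionRecord]:
    """Retain interactions with binding score equal to ``require_score``
    (exact equality on the stored value), binding region matching, and a
    validated accession present; input order is preserved.

    Binding energies are carried through to reports but never filtered on.
    """
    out = []
    for r in records:
        if r.binding_score != require_score:
            continue
        if r.region != require_region:
            continue
        if require_validated:
            if not r.validated_id:
                continue
            if strict_validated_pattern and not VALIDATED_PATTERN.match(r.validated_id):
                continue
        out.append(r)
    logger.info("interaction filter: %d in -> %d retained", len(records), len(out))
    return out


@dataclass
class RegulatoryNetwork:
    """Mixed miRNA-gene / gene-gene simple undirected network; node kinds
    are stored as the node attribute ``kind`` and edge layers as ``kind``."""

    graph: nx.Graph

    @property
    def node_kinds(self) -> dict:
        return nx.get_node_attributes(self.graph, "kind")

    def __eq__(self, other):
        return (set(self.graph.nodes) == set(other.graph.nodes)
                and set(map(frozenset, self.graph.edges))
                == set(map(frozenset, other.graph.edges))
                and self.node_kinds == other.node_kinds)


def build_network(
    mi_gene: list[InteractionRecord],
    gene_gene: pd.DataFrame | None = None,
) -> RegulatoryNetwork:
    """Assemble the regulatory network from retained interactions plus an
    optional two-column (+ optional weight) gene-gene edge table.

    Duplicate edges collapse; self-loops are dropped with a logged count;
    an identifier appearing both as miRNA and as gene is rejected.
    """
    g = nx.Graph()
    mirnas = {r.mirna_id for r in mi_gene}
    genes = {r.gene_id for r in mi_gene}
    if gene_gene is not None and len(gene_gene):
        genes |= set(gene_gene.iloc[:, 0].astype(str)) | set(gene_gene.iloc[:, 1].astype(str))
    clash = mirnas & genes
    if clash:
        raise ValueError(f"ids used as both miRNA and gene: {sorted(clash)}")
    for m in sorted(mirnas):
        g.add_node(m, kind="miRNA")
    for t in sorted(genes):
        g.add_node(t, kind="gene")
    dropped = 0
    for r in mi_gene:
        g.add_edge(r.mirna_id, r.gene_id, kind="miRNA-gene")
    if gene_gene is not None:
        for _, row in gene_gene.iterrows():
            a, b = str(row.iloc[0]), str(row.iloc[1])
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b, kind="gene-gene")
    if dropped:
        logger.info("dropped %d self-loop gene-gene edges", dropped)
    return RegulatoryNetwork(g)


def export_network(net: RegulatoryNetwork, path, fmt: str = "edge-list") -> None:
    """Write the network as an edge-list TSV (source, target, edge kind plus
    a node-kind side table header comment) or GraphML; both round-trip."""
    if fmt == "edge-list":
        rows = [{"source": u, "target": v,
                 "edge_kind": d.get("kind", ""),
                 "source_kind": net.graph.nodes[u].get("kind", ""),
                 "target_kind": net.graph.nodes[v].get("kind", "")}
                for u, v, d in net.graph.edges(data=True)]
        df = pd.DataFrame(rows, columns=["source", "target", "edge_kind",
                                         "source_kind", "target_kind"])
        # isolated nodes kept as self-describing rows with empty target
        isolated = [n for n in net.graph.nodes if net.graph.degree(n) == 0]
        for n in isolated:
            df.loc[len(df)] = [n, "", "", net.graph.nodes[n].get("kind", ""), ""]
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown format token {fmt!r}")


def import_network(path, fmt: str = "edge-list") -> RegulatoryNetwork:
    if fmt == "edge-list":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_node(row["source"], kind=row["source_kind"])
            if row["target"]:
                g.add_node(row["target"], kind=row["target_kind"])
                g.add_edge(row["source"], row["target"], kind=row["edge_kind"])
        return RegulatoryNetwork(g)
    if fmt == "graphml":
        return RegulatoryNetwork(nx.read_graphml(path))
    raise ValueError(f"unknown format token {fmt!r}")
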