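"""Drug-gene interaction network and gene-set over-representation.

The network has two gene layers around a single drug node: "direct" genes
curated as interacting with the drug itself (PharmGKB-style drug-gene
pairs) and "indirect" genes linked to a direct gene by protein-protein
interaction evidence (BioGRID-style gene-gene pairs).  Over-representation
of a gene list in a gene-set collection uses the upper-tail hypergeometric
test with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "GeneNetwork",
    "GeneSet",
    "bh_adjust",
    "build_network",
    "export_network",
    "filter_significant",
    "hypergeometric_enrichment",
    "import_network_tsv",
    "read_edge_tsv",
    "read_gmt",
]

_ROLES = ("drug", "direct", "indirect")


@dataclass(frozen=True)
class GeneSet:
    """One ontology term with its member genes."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one gene set in a query list."""

    set_id: str
    name: str
    N: int
    K: int
    n: int
    k_overlap: int
    rate: float
    p_value: float
    p_adj: float
    overlap_genes: tuple[str, ...]


class GeneNetwork:
    """A two-layer drug-gene network backed by an undirected graph."""

    def __init__(self, graph: nx.Graph, drug: str):
        self.graph = graph
        self.drug = drug
        self.validate()

    @property
    def direct_genes(self) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r == "direct"}

    @property
    def indirect_genes(self) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r == "indirect"}

    @property
    def genes(self) -> set[str]:
        return self.direct_genes | self.indirect_genes

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def validate(self) -> None:
        roles = dict(self.graph.nodes(data="role"))
        drugs = [n for n, r in roles.items() if r == "drug"]
        if drugs != [self.drug]:
            raise ValueError("network must contain exactly one drug node")
        if any(r not in _ROLES for r in roles.values()):
            raise ValueError("unknown node role")
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        for g in self.direct_genes:
            if not self.graph.has_edge(self.drug, g):
                raise ValueError(f"direct gene {g} not adjacent to the drug")
        for g in self.indirect_genes:
            if not any(roles[nb] == "direct" for nb in self.graph.neighbors(g)):
                raise ValueError(f"indirect gene {g} not adjacent to any direct gene")


def build_network(
    drug_id: str,
    direct_edges: Iterable[tuple[str, str]],
    indirect_edges: Iterable[tuple[str, str]] = (),
) -> GeneNetwork:
    """Assemble the two-layer network from edge lists.

    ``direct_edges`` are (drug, gene) pairs; rows not referencing
    ``drug_id`` are ignored.  ``indirect_edges`` are (gene, gene) pairs;
    a pair is kept only when incident to at least one direct gene (others
    are dropped with a warning), and a gene already in the direct layer
    stays direct.  Edges are deduplicated as unordered pairs; self-loops
    are dropped.
    """
    if not drug_id:
        raise ValueError("drug_id must be non-empty")
    direct = set()
    for u, v in direct_edges:
        if u == drug_id and v and v != drug_id:
            direct.add(v)
        elif v == drug_id and u and u != drug_id:
            direct.add(u)
    if not direct:
        raise ValueError("no direct interactions")

    graph = nx.Graph()
    graph.add_node(drug_id, role="drug")
    for g in sorted(direct):
        graph.add_node(g, role="direct")
        graph.add_edge(drug_id, g)

    for u, v in indirect_edges:
        if u == v or not u or not v:
            continue
        if drug_id in (u, v):
            logger.warning("gene-gene edge (%s, %s) references the drug; dropped", u, v)
            continue
        if u not in direct and v not in direct:
            logger.warning(
                "gene-gene edge (%s, %s) not incident to a direct gene; dropped", u, v
            )
            continue
        for node in (u, v):
            if node not in graph:
                graph.add_node(node, role="indirect")
        graph.add_edge(u, v)
    return GeneNetwork(graph, drug_id)


def hypergeometric_enrichment(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    background: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    For each set, with background size N, K annotated members in the
    background, query size n (after intersection with the background) and
    overlap k: p = P(X >= k) for X hypergeometric(N, K, n), and the
    enrichment rate is (k/n)/(K/N).  Sets with no overlap report p = 1 and
    rate 0.  Results are sorted by raw p-value.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    query_list = list(dict.fromkeys(query))
    dropped = [g for g in query_list if g not in bg]
    if dropped:
        logger.warning("%d query genes outside the background dropped", len(dropped))
    q = [g for g in query_list if g in bg]
    if not q:
        raise ValueError("query is empty after intersection with background")
    qset = set(q)
    N, n = len(bg), len(q)

    rows = []
    for gene_set in collection:
        members = gene_set.members & bg
        K = len(members)
        overlap = sorted(qset & members)
        k = len(overlap)
        if k == 0:
            p, rate = 1.0, 0.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            rate = (k / n) / (K / N)
        rows.append((gene_set, K, k, rate, p, tuple(overlap)))

    adjusted = bh_adjust([row[4] for row in rows]) if rows else []
    results = [
        EnrichmentResult(
            set_id=gs.set_id,
            name=gs.name,
            N=N,
            K=K,
            n=n,
            k_overlap=k,
            rate=rate,
            p_value=p,
            p_adj=p_adj,
            overlap_genes=overlap,
        )
        for (gs, K, k, rate, p, overlap), p_adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


def filter_significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Subset with adjusted p strictly below ``alpha``, order preserved."""
    return [r for r in results if r.p_adj < alpha]


def export_network(network: GeneNetwork, path: Union[str, Path], fmt: str) -> None:
    """Write the network as ``sif``, ``graphml`` or ``edge-tsv``.

    The edge-tsv form carries node roles on both endpoints and round-trips
    losslessly through :func:`import_network_tsv`.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as handle:
            for u, v in sorted(network.graph.edges):
                handle.write(f"{u}\tinteracts\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "edge-tsv":
        roles = dict(network.graph.nodes(data="role"))
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(["source", "source_role", "target", "target_role"])
            for u, v in sorted(network.graph.edges):
                writer.writerow([u, roles[u], v, roles[v]])
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network_tsv(path: Union[str, Path]) -> GeneNetwork:
    """Read a network previously written with ``fmt='edge-tsv'``."""
    graph = nx.Graph()
    drug = None
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            for node, role in ((row["source"], row["source_role"]), (row["target"], row["target_role"])):
                graph.add_node(node, role=role)
                if role == "drug":
                    drug = node
            graph.add_edge(row["source"], row["target"])
    if drug is None:
        raise ValueError("edge-tsv file contains no drug node")
    return GeneNetwork(graph, drug)


def read_edge_tsv(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list; a non-data first row is skipped.

    The first row is treated as a header when either field matches a common
    column label (drug, gene, source, target, ...).
    """
    header_tokens = {
        "drug", "gene", "gene1", "gene2", "source", "target",
        "interactor_a", "interactor_b", "from", "to",
    }
    edges: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for i, row in enumerate(csv.reader(handle, delimiter="\t")):
            if not row or not any(field.strip() for field in row):
                continue
            if len(row) < 2:
                raise ValueError(f"line {i + 1}: expected 2 tab-separated columns")
            u, v = row[0].strip(), row[1].strip()
            if i == 0 and {u.lower(), v.lower()} & header_tokens:
                continue
            edges.append((u, v))
    return edges


def read_gmt(path: Union[str, Path]) -> list[GeneSet]:
    """Read a GMT gene-set collection (set id, description, members...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {i}: GMT rows need id, description and >=1 member")
            set_id, name = fields[0].strip(), fields[1].strip()
            if set_id in seen:
                raise ValueError(f"line {i}: duplicate set id {set_id!r}")
            seen.add(set_id)
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(set_id, name, members))
    return sets
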