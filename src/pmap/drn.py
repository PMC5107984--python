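"""Drug response network (DRN) mining on the PPI graph.

N1 genes are non-PDEG nodes adjacent to at least ``min_links`` PDEGs of a
phenotype class; N2 genes are non-PDEG nodes adjacent to at least one N1 gene
and at least ``min_links`` PDEGs (UBC excluded by rule).  N1 and N2 are role
ledgers, not a partition: a gene may occur in both, with its frequency
counted separately per role.  The pair
registry lists every (PDEG, N1) adjacency; its length M is the row dimension
of the M x F frequency matrix (F = 2 for the N1 and N2 role ledgers).  The
phenotypic frequency (PF) score of a gene is its occurrence count in the
sensitive network minus that in the resistant network of the same drug class.

No randomness anywhere in this module; all outputs sort lexicographically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from pmap.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DEFAULT_N2_EXCLUDED = frozenset({"UBC"})


def build_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Simple undirected graph from a cleaned edge list."""
    g = nx.Graph()
    for a, b in edges:
        if a == b:
            continue
        g.add_edge(a, b)
    return g


@dataclass
class DrnResult:
    """N1/N2 discovery output for one phenotype class on one graph."""

    phenotype_class: str
    pdegs_in_graph: set[str]
    n1: set[str]
    n2: set[str]
    pair_registry: list[tuple[str, str]]           # (pdeg, n1_gene), sorted
    freq_n1: dict[str, int]                        # N1-role occurrence counts
    freq_n2: dict[str, int]                        # N2-role occurrence counts
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def m(self) -> int:
        """Number of PDEG-N1 gene pairs (registry rows)."""
        return len(self.pair_registry)


def discover_n1(graph: nx.Graph, pdegs: set[str], min_links: int = 2
                ) -> tuple[set[str], list[tuple[str, str]]]:
    """N1 genes and the (pdeg, n1) pair registry.

    N1 = non-PDEG nodes with >= min_links PDEG neighbours.  Registry rows are
    sorted (pdeg, gene) pairs; a gene's N1 frequency is its row count.
    """
    if min_links < 1:
        raise ConfigError("min_links must be >= 1")
    if graph.number_of_nodes() == 0:
        raise DataError("empty PPI graph")
    pdegs_in_graph = pdegs & set(graph.nodes)
    dropped = len(pdegs) - len(pdegs_in_graph)
    if dropped:
        logger.info("%d PDEG(s) not present in graph", dropped)
    n1: set[str] = set()
    registry: list[tuple[str, str]] = []
    for node in graph.nodes:
        if node in pdegs_in_graph:
            continue
        pdeg_neighbors = pdegs_in_graph.intersection(graph.adj[node])
        if len(pdeg_neighbors) >= min_links:
            n1.add(node)
            registry.extend((p, node) for p in pdeg_neighbors)
    registry.sort()
    return n1, registry


def discover_n2(graph: nx.Graph, pdegs: set[str], n1: set[str],
                min_links: int = 2,
                excluded: frozenset[str] = DEFAULT_N2_EXCLUDED,
                registry: Sequence[tuple[str, str]] | None = None,
                exclude_n1: bool = False) -> tuple[set[str], dict[str, int]]:
    """N2 genes and their registry-row occurrence counts.

    N2 = non-PDEG nodes outside the exclusion list that touch >= 1 N1 gene
    and >= min_links PDEGs.  An N2 gene g "appears" in registry row (p, n)
    iff g is adjacent to both p and n; its N2 frequency is the count of such
    rows.

    The N1 and N2 roles are separate ledgers and may overlap: with equal
    ``min_links`` every N2 candidate also satisfies the N1 predicate, so
    forcing disjoint sets would leave N2 empty for any graph.  Pass
    ``exclude_n1=True`` for the strict disjoint variant.
    """
    pdegs_in_graph = pdegs & set(graph.nodes)
    n2: set[str] = set()
    for node in graph.nodes:
        if node in pdegs_in_graph or (exclude_n1 and node in n1):
            continue
        if node in excluded:
            if (n1.intersection(graph.adj[node])
                    and len(pdegs_in_graph.intersection(graph.adj[node])) >= min_links):
                logger.info("excluded gene %s met N2 criteria; skipped", node)
            continue
        if not n1.intersection(graph.adj[node]):
            continue
        if len(pdegs_in_graph.intersection(graph.adj[node])) >= min_links:
            n2.add(node)

    freq_n2: dict[str, int] = {}
    if registry is None:
        registry = discover_n1(graph, pdegs, min_links)[1]
    for g in n2:
        adj = graph.adj[g]
        freq_n2[g] = sum(1 for p, n in registry if p in adj and n in adj)
    return n2, freq_n2


def mine_drn(graph: nx.Graph, pdegs: set[str], phenotype_class: str,
             min_links: int = 2,
             excluded: frozenset[str] = DEFAULT_N2_EXCLUDED) -> DrnResult:
    """Full N1/N2 discovery plus induced DRN edges for one phenotype class."""
    n1, registry = discover_n1(graph, pdegs, min_links)
    n2, freq_n2 = discover_n2(graph, pdegs, n1, min_links, excluded, registry)
    freq_n1: dict[str, int] = {}
    for _, g in registry:
        freq_n1[g] = freq_n1.get(g, 0) + 1
    result = DrnResult(
        phenotype_class=phenotype_class,
        pdegs_in_graph=pdegs & set(graph.nodes),
        n1=n1, n2=n2, pair_registry=registry,
        freq_n1=freq_n1, freq_n2=freq_n2,
    )
    result.edges = assemble_drn(graph, result)
    return result


def assemble_drn(graph: nx.Graph, result: DrnResult
                 ) -> list[tuple[str, str, str]]:
    """Induced DRN edge list over PDEGs, N1 and N2, with role-pair labels.

    Label precedence for dual-role genes: PDEG > N1 > N2.
    """
    role = {}
    for g in result.n2:
        role[g] = "N2"
    for g in result.n1:
        role[g] = "N1"
    for g in result.pdegs_in_graph:
        role[g] = "PDEG"
    edges = []
    for a, b in graph.subgraph(role).edges:
        a, b = (a, b) if a < b else (b, a)
        edges.append((a, b, f"{role[a]}-{role[b]}"))
    edges.sort()
    return edges


def degree_summary(result: DrnResult) -> pd.DataFrame:
    """Per-node DRN degree table for hub auditing (hubs inflate N1/N2)."""
    deg: dict[str, int] = {}
    role: dict[str, str] = {}
    for g in result.n2:
        role[g] = "N2"
    for g in result.n1:
        role[g] = "N1"
    for g in result.pdegs_in_graph:
        role[g] = "PDEG"
    for a, b, _ in result.edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    rows = [{"gene": g, "role": role.get(g, "?"), "degree": d}
            for g, d in sorted(deg.items())]
    return pd.DataFrame(rows, columns=["gene", "role", "degree"])


# ---------------------------------------------------------------------------
# PF scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PfRecord:
    gene: str
    freq_sensitive_n1: int
    freq_resistant_n1: int
    freq_sensitive_n2: int
    freq_resistant_n2: int
    pf_n1: int
    pf_n2: int
    pf_sum: int
    rank: int


def pf_scores(sensitive: DrnResult, resistant: DrnResult) -> list[PfRecord]:
    """Per-gene PF records over the union of N1/N2 genes of both networks.

    pf_n1 = sensitive N1 frequency - resistant N1 frequency (missing role
    counts as 0), pf_n2 analogous, pf_sum their total.  Positive scores mean
    the gene occurs more often in the sensitive network.  Sorted by pf_sum
    descending, ties by symbol.
    """
    s_class = sensitive.phenotype_class.rsplit("-", 1)[0]
    r_class = resistant.phenotype_class.rsplit("-", 1)[0]
    if s_class != r_class:
        raise DataError(
            f"drug-class mismatch: {sensitive.phenotype_class} vs "
            f"{resistant.phenotype_class}"
        )
    genes = (set(sensitive.freq_n1) | set(sensitive.freq_n2)
             | set(resistant.freq_n1) | set(resistant.freq_n2))
    records = []
    for gene in genes:
        fs1 = sensitive.freq_n1.get(gene, 0)
        fr1 = resistant.freq_n1.get(gene, 0)
        fs2 = sensitive.freq_n2.get(gene, 0)
        fr2 = resistant.freq_n2.get(gene, 0)
        records.append((gene, fs1, fr1, fs2, fr2, fs1 - fr1, fs2 - fr2))
    records.sort(key=lambda t: (-(t[5] + t[6]), t[0]))
    return [
        PfRecord(gene=g, freq_sensitive_n1=fs1, freq_resistant_n1=fr1,
                 freq_sensitive_n2=fs2, freq_resistant_n2=fr2,
                 pf_n1=p1, pf_n2=p2, pf_sum=p1 + p2, rank=i + 1)
        for i, (g, fs1, fr1, fs2, fr2, p1, p2) in enumerate(records)
    ]


def pf_to_frame(records: Sequence[PfRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "gene": r.gene, "pf_n1": r.pf_n1, "pf_n2": r.pf_n2,
            "pf_sum": r.pf_sum, "rank": r.rank,
            "freq_sensitive_n1": r.freq_sensitive_n1,
            "freq_resistant_n1": r.freq_resistant_n1,
            "freq_sensitive_n2": r.freq_sensitive_n2,
            "freq_resistant_n2": r.freq_resistant_n2,
        } for r in records],
        columns=["gene", "pf_n1", "pf_n2", "pf_sum", "rank",
                 "freq_sensitive_n1", "freq_resistant_n1",
                 "freq_sensitive_n2", "freq_resistant_n2"],
    )
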