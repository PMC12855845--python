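"""Co-occurrence networks, topology, Zi-Pi node roles and keystone taxa.

Edges are Spearman correlations passing |rho| > 0.6 (strict) and
BH-adjusted p < 0.05; modules come from Louvain modularity maximisation on
|rho| weights; node roles follow the within-module degree z-score (Zi) and
participation coefficient (Pi) with thresholds 2.5 and 0.62.  Connectors,
module hubs and network hubs together form the keystone set.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, relative_abundance

__all__ = [
    "correlation_screen",
    "build_network",
    "detect_modules",
    "topology_stats",
    "zi_pi",
    "classify_roles",
    "group_network_pipeline",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def correlation_screen(
    table: FeatureTable,
    prevalence_min: float = 0.2,
    abundance_min: float = 0.0001,
) -> pd.DataFrame:
    """All-pairs Spearman screen with BH correction.

    Taxa are pre-filtered to prevalence >= ``prevalence_min`` and mean
    relative abundance >= ``abundance_min`` (sparse vectors make rank
    correlations unstable).  Constant taxa are untestable and skipped.
    Returns a tidy frame (taxon_a, taxon_b, rho, p, q).
    """
    if table.counts.shape[0] < 4:
        raise ValueError("need at least 4 samples for a correlation screen")
    rel = relative_abundance(table)
    prevalence = (table.counts > 0).mean(axis=0)
    mean_abund = rel.mean(axis=0)
    keep = (prevalence >= prevalence_min) & (mean_abund >= abundance_min)
    taxa = [t for t in table.taxon_ids if keep[t]]
    if len(taxa) < 2:
        raise ValueError("fewer than 2 taxa pass the prevalence/abundance filter")
    data = table.counts[taxa].to_numpy(dtype=float)
    variable = data.std(axis=0) > 0
    testable = [t for t, v in zip(taxa, variable) if v]
    data = data[:, variable]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(data, axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    iu, ju = np.triu_indices(len(testable), k=1)
    frame = pd.DataFrame(
        {
            "taxon_a": np.asarray(testable)[iu],
            "taxon_b": np.asarray(testable)[ju],
            "rho": rho[iu, ju],
            "p": p[iu, ju],
        }
    )
    frame = frame.dropna(subset=["rho", "p"]).reset_index(drop=True)
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["q"] = []
    return frame


def build_network(
    screen: pd.DataFrame, r_threshold: float = 0.6, q_threshold: float = 0.05
) -> nx.Graph:
    """Graph of taxa whose correlation passes both thresholds (strict).

    Edge attributes: ``rho`` (signed), ``weight`` (|rho|), ``q``.  Isolated
    taxa never enter the graph; an empty edge set yields an empty graph with
    a warning.
    """
    keep = screen[(screen["rho"].abs() > r_threshold) & (screen["q"] < q_threshold)]
    graph = nx.Graph()
    for row in keep.itertuples(index=False):
        graph.add_edge(
            row.taxon_a,
            row.taxon_b,
            rho=float(row.rho),
            weight=abs(float(row.rho)),
            q=float(row.q),
        )
    if graph.number_of_edges() == 0:
        warnings.warn("no correlation passed both thresholds; empty network")
    return graph


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Louvain modules on |rho| weights; ids stable-sorted by module size."""
    if graph.number_of_nodes() == 0:
        return {}
    communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {node: i for i, comm in enumerate(ordered) for node in sorted(comm)}


def topology_stats(graph: nx.Graph, modules: dict[str, int]) -> dict:
    """Whole-network summary used to compare genotype networks.

    Diameter is the longest shortest path (unweighted) within the largest
    connected component, the practical convention for disconnected
    co-occurrence graphs.
    """
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if n == 0:
        warnings.warn("empty network; all topology statistics are zero")
        return {
            "nodes": 0, "edges": 0, "average_degree": 0.0, "diameter": 0,
            "modularity": 0.0, "n_modules": 0, "positive_edge_fraction": 0.0,
        }
    largest_cc = max(nx.connected_components(graph), key=len)
    diameter = nx.diameter(graph.subgraph(largest_cc))
    comms: dict[int, set] = {}
    for node, mod in modules.items():
        comms.setdefault(mod, set()).add(node)
    modularity = nx.community.modularity(graph, comms.values(), weight="weight")
    pos = sum(1 for _, _, d in graph.edges(data=True) if d.get("rho", 1) > 0)
    return {
        "nodes": n,
        "edges": e,
        "average_degree": 2.0 * e / n,
        "diameter": int(diameter),
        "modularity": float(modularity),
        "n_modules": len(comms),
        "positive_edge_fraction": pos / e if e else 0.0,
    }


def zi_pi(graph: nx.Graph, modules: dict[str, int]) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (k_i - mean_k_module) / sd_k_module over the node's module (0 when
    the module's degree spread is zero); Pi = 1 - sum_s (k_is / k_i)^2 over
    modules s.  Degrees are unweighted, following the original
    Guimera-Amaral definitions.
    """
    nodes = list(graph.nodes)
    within_degree = {}
    for node in nodes:
        mod = modules[node]
        within_degree[node] = sum(
            1 for nb in graph.neighbors(node) if modules[nb] == mod
        )
    mod_members: dict[int, list[str]] = {}
    for node in nodes:
        mod_members.setdefault(modules[node], []).append(node)
    mod_stats = {}
    for mod, members in mod_members.items():
        ks = np.array([within_degree[m] for m in members], dtype=float)
        mod_stats[mod] = (ks.mean(), ks.std())
    rows = []
    for node in nodes:
        k = graph.degree(node)
        mu, sd = mod_stats[modules[node]]
        zi = (within_degree[node] - mu) / sd if sd > 0 else 0.0
        by_mod: dict[int, int] = {}
        for nb in graph.neighbors(node):
            by_mod[modules[nb]] = by_mod.get(modules[nb], 0) + 1
        pi = 1.0 - sum((ks / k) ** 2 for ks in by_mod.values()) if k else 0.0
        rows.append((node, modules[node], k, float(zi), float(pi)))
    return pd.DataFrame(
        rows, columns=["node", "module", "degree", "zi", "pi"]
    ).set_index("node")


def classify_roles(
    topology: pd.DataFrame,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Four node roles from (Zi, Pi); non-peripheral nodes are keystones."""
    out = topology.copy()

    def role(zi: float, pi: float) -> str:
        if zi > zi_threshold and pi > pi_threshold:
            return "Network hub"
        if zi > zi_threshold:
            return "Module hub"
        if pi > pi_threshold:
            return "Connector"
        return "Peripheral"

    out["role"] = [role(z, p) for z, p in zip(out["zi"], out["pi"])]
    out["keystone"] = out["role"] != "Peripheral"
    return out


def group_network_pipeline(
    table: FeatureTable,
    metadata: pd.Series,
    group: str,
    prevalence_min: float = 0.2,
    abundance_min: float = 0.0001,
    r_threshold: float = 0.6,
    q_threshold: float = 0.05,
    seed: int = 0,
) -> dict:
    """Full per-genotype network analysis: screen, graph, modules, roles.

    Returns a dict with the screen, graph, modules, topology stats, the
    node-role table, and the keystone taxon set for the group.
    """
    samples = [s for s in table.sample_ids if metadata.get(s) == group]
    if len(samples) < 4:
        raise ValueError(f"group {group!r} has fewer than 4 samples")
    sub = FeatureTable(table.counts.loc[samples], taxonomy=table.taxonomy)
    screen = correlation_screen(sub, prevalence_min, abundance_min)
    graph = build_network(screen, r_threshold, q_threshold)
    modules = detect_modules(graph, seed=seed)
    topo = topology_stats(graph, modules)
    if graph.number_of_nodes():
        roles = classify_roles(zi_pi(graph, modules))
        keystones = set(roles.index[roles["keystone"]])
    else:
        roles = pd.DataFrame(columns=["module", "degree", "zi", "pi", "role", "keystone"])
        keystones = set()
    return {
        "screen": screen,
        "graph": graph,
        "modules": modules,
        "topology": topo,
        "roles": roles,
        "keystones": keystones,
    }
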