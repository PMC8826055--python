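"""Co-occurrence network inference and topology for compositional count data.

The inference pipeline mirrors the SPIEC-EASI recipe in its neighborhood-
selection (MB) flavor, written here directly on top of scikit-learn's lasso
path solver:

1. filter taxa (top decile of total relative abundance, occurring in more
   than a quarter of samples),
2. centered log-ratio (CLR) transform to undo the constant-sum constraint,
3. per-node sparse (lasso) neighborhood regressions across a decreasing
   penalty path,
4. StARS stability selection: the densest penalty whose edge instability
   across random subsamples stays below a threshold,
5. edges combined across the two regression directions (OR rule by default),
   signed by the averaged coefficient.

Downstream topology (degree, betweenness, clustering, centralization),
modularity-based module detection, Zi–Pi node-role classification, module
abundance profiles, and natural-connectivity robustness curves operate on the
resulting :class:`networkx.Graph`, whose edges carry ``weight`` (averaged
coefficient) and ``sign`` attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import logsumexp
from sklearn.linear_model import lasso_path

from .diversity import bh_adjust
from .io_core import OtuTable

__all__ = [
    "ROLES",
    "RobustnessCurve",
    "filter_taxa",
    "clr_transform",
    "infer_network",
    "extract_subnetwork",
    "annotate_abundance",
    "topology",
    "detect_modules",
    "zi_pi",
    "module_abundance",
    "module_function_regression",
    "robustness",
    "natural_connectivity",
    "network_to_tables",
]

ROLES = ("network_hub", "module_hub", "connector", "peripheral")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.6


def role_for(zi: float, pi: float) -> str:
    """Topological role from the Zi/Pi quadrant thresholds (2.5 / 0.6)."""
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network_hub"
    if zi > ZI_THRESHOLD:
        return "module_hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


# ---------------------------------------------------------------------------
# Filtering and CLR
# ---------------------------------------------------------------------------

def filter_taxa(
    table: OtuTable,
    abundance_quantile: float = 0.10,
    occurrence_fraction: float = 0.25,
) -> OtuTable:
    """Keep dominant, frequent OTUs.

    An OTU survives when it ranks in the top ``abundance_quantile`` of OTUs
    by total relative abundance (ties broken by OTU id for determinism) AND
    occurs in strictly more than ``occurrence_fraction`` of samples.
    """
    if not (0 < abundance_quantile <= 1):
        raise ValueError("abundance_quantile must be in (0, 1]")
    if not (0 <= occurrence_fraction < 1):
        raise ValueError("occurrence_fraction must be in [0, 1)")
    rel_total = table.relative_abundance().sum(axis=0)
    order = sorted(
        range(table.n_otus), key=lambda j: (-rel_total[j], table.otu_ids[j])
    )
    n_top = int(np.ceil(abundance_quantile * table.n_otus))
    top = set(order[:n_top])
    occurrence = table.presence().sum(axis=0)
    cutoff = occurrence_fraction * table.n_samples
    keep = [
        o
        for j, o in enumerate(table.otu_ids)
        if j in top and occurrence[j] > cutoff and occurrence[j] > 0
    ]
    if not keep:
        raise ValueError("no OTU survives the abundance/occurrence filter")
    return table.select_otus(keep)


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform: log(count + pc) minus the sample mean log.

    Rows sum to zero; multiplying a sample's counts by a constant leaves its
    CLR row unchanged (up to the pseudocount), which is what removes the
    compositional constant-sum artifact.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(table.counts + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=list(table.sample_ids),
                        columns=list(table.otu_ids))


# ---------------------------------------------------------------------------
# Neighborhood selection + StARS
# ---------------------------------------------------------------------------

def _neighborhood_coefs(
    x: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Lasso neighborhood regressions for every node.

    Returns ``coefs[l, i, j]`` = coefficient of predictor j in the regression
    of node i at penalty ``lambdas[l]`` (0 on the diagonal).  Columns are
    standardized per call so the penalty acts uniformly.
    """
    n, p = x.shape
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0)
    sd[sd == 0] = 1.0
    xs = xs / sd
    coefs = np.zeros((len(lambdas), p, p))
    with warnings.catch_warnings():
        # near-threshold duality gaps at the dense end of the path are benign
        warnings.simplefilter("ignore")
        for i in range(p):
            others = np.delete(np.arange(p), i)
            _, path, _ = lasso_path(
                xs[:, others], xs[:, i], alphas=lambdas, max_iter=5000
            )
            # lasso_path returns coefficients for alphas in decreasing order
            coefs[:, i, others] = path.T
    return coefs


def _default_lambda_path(
    x: np.ndarray, n_lambda: int = 30, min_ratio: float = 0.01
) -> np.ndarray:
    xs = x - x.mean(axis=0)
    sd = xs.std(axis=0)
    sd[sd == 0] = 1.0
    xs = xs / sd
    n = xs.shape[0]
    gram = np.abs(xs.T @ xs) / n
    np.fill_diagonal(gram, 0.0)
    lam_max = gram.max()
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def infer_network(
    clr: pd.DataFrame,
    lambda_path: np.ndarray | None = None,
    stars_threshold: float = 0.05,
    n_subsamples: int = 20,
    subsample_ratio: float | None = None,
    seed: int = 0,
    rule: str = "or",
) -> nx.Graph:
    """Sparse association network via neighborhood selection + StARS.

    ``lambda_path`` must be decreasing (default: 30 log-spaced values from
    the data-driven maximum down to 1% of it).  For each random subsample
    (default size ``min(10·√n, 0.8·n)``) and penalty, per-node lasso
    regressions yield a candidate edge set (``rule='or'`` keeps an edge
    selected in either direction, ``'and'`` requires both); StARS picks the
    densest penalty whose monotonized mean edge instability ``2θ(1−θ)`` stays
    at or below ``stars_threshold``.  The final graph is refit on the full
    data at the selected penalty; edge sign is the sign of the two directed
    coefficients' mean.

    Graph attributes record the selected penalty and the instability path.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    x = clr.to_numpy(dtype=float)
    n, p = x.shape
    if n < 20:
        warnings.warn(
            f"only {n} samples; association estimates will be unstable",
            stacklevel=2,
        )
    if lambda_path is None:
        lambda_path = _default_lambda_path(x)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(lambda_path) >= 0):
        raise ValueError("lambda_path must be strictly decreasing")
    if subsample_ratio is None:
        b = int(min(np.ceil(10 * np.sqrt(n)), np.floor(0.8 * n)))
    else:
        b = int(np.floor(subsample_ratio * n))
    b = max(2, min(b, n))
    rng = np.random.default_rng(seed)

    combine = np.logical_or if rule == "or" else np.logical_and
    iu = np.triu_indices(p, k=1)
    sel_freq = np.zeros((len(lambda_path), len(iu[0])))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=b, replace=False)
        coefs = _neighborhood_coefs(x[idx], lambda_path)
        nz = coefs != 0
        edges = combine(nz, nz.transpose(0, 2, 1))
        sel_freq += edges[:, iu[0], iu[1]]
    theta = sel_freq / n_subsamples
    instability = (2 * theta * (1 - theta)).mean(axis=1)
    # monotonize from the sparse end: instability is treated as non-decreasing
    # along the path toward denser graphs
    mono = np.maximum.accumulate(instability)
    ok = np.nonzero(mono <= stars_threshold)[0]
    sel_idx = ok[-1] if len(ok) else 0
    lam = lambda_path[sel_idx]

    coefs = _neighborhood_coefs(x, np.array([lam]))[0]
    nz = coefs != 0
    edge_mask = combine(nz, nz.T)
    g = nx.Graph(
        lambda_selected=float(lam),
        stars_threshold=stars_threshold,
        instability_path=[float(v) for v in instability],
        lambda_path=[float(v) for v in lambda_path],
        rule=rule,
        n_samples=n,
        subsample_size=b,
    )
    g.add_nodes_from(clr.columns)
    cols = list(clr.columns)
    for a, bidx in zip(*np.nonzero(np.triu(edge_mask, k=1))):
        w = 0.5 * (coefs[a, bidx] + coefs[bidx, a])
        if w == 0:  # opposite-signed directions cancelling exactly
            w = coefs[a, bidx] or coefs[bidx, a]
        g.add_edge(
            cols[a], cols[bidx], weight=float(w),
            sign=1 if w > 0 else -1,
        )
    if g.number_of_edges() == 0:
        warnings.warn("no stable edges at any penalty; returning an empty "
                      "network", stacklevel=2)
    return g


# ---------------------------------------------------------------------------
# Sub-networks and annotation
# ---------------------------------------------------------------------------

def annotate_abundance(net: nx.Graph, table: OtuTable) -> None:
    """Attach each node's mean relative abundance (over the table's samples)."""
    rel = table.relative_abundance().mean(axis=0)
    lookup = dict(zip(table.otu_ids, rel))
    for node in net.nodes:
        net.nodes[node]["mean_relative_abundance"] = float(lookup.get(node, 0.0))


def extract_subnetwork(
    net: nx.Graph, table: OtuTable, sample_subset
) -> nx.Graph:
    """Induced subgraph on nodes present in at least one subset sample.

    Node abundances are recomputed on the subset.
    """
    subset = list(sample_subset)
    if not subset:
        raise ValueError("sample_subset must be non-empty")
    sub_table = table.select_samples(subset)
    present = sub_table.presence().any(axis=0)
    keep = [
        o for o, pres in zip(sub_table.otu_ids, present) if pres and o in net
    ]
    if not keep:
        raise ValueError("no network node is present in the sample subset")
    sub = net.subgraph(keep).copy()
    sub.graph = dict(net.graph)
    annotate_abundance(sub, sub_table.select_otus(keep))
    return sub


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def topology(net: nx.Graph) -> tuple[pd.DataFrame, dict]:
    """Per-node degree and betweenness plus whole-graph summary statistics.

    Betweenness is Brandes shortest-path betweenness on the unweighted,
    unsigned graph, reported unnormalized.  Centralization is Freeman degree
    centralization; ``average_neighbors`` is the mean degree.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    deg = dict(net.degree())
    btw = nx.betweenness_centrality(net, normalized=False)
    clus = nx.clustering(net)
    node_df = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "clustering": [clus[v] for v in nodes],
        },
        index=nodes,
    )
    n = len(nodes)
    degrees = node_df["degree"].to_numpy(float)
    if n > 2:
        centralization = (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
    else:
        centralization = 0.0
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    stats = {
        "n_nodes": n,
        "n_edges": net.number_of_edges(),
        "positive_edges": int(sum(1 for s in signs if s > 0)),
        "negative_edges": int(sum(1 for s in signs if s < 0)),
        "clustering_coefficient": float(np.mean(node_df["clustering"]))
        if n
        else 0.0,
        "average_neighbors": float(degrees.mean()),
        "degree_centralization": float(centralization),
    }
    return node_df, stats


# ---------------------------------------------------------------------------
# Modules, Zi-Pi, module abundance
# ---------------------------------------------------------------------------

def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain-style modularity maximization on the unsigned graph.

    Returns ``(module_of_node, Q)``; modules are labeled 1, 2, ... by
    decreasing size (ties broken by smallest member id).  An edgeless graph
    puts every node in its own module with Q = 0.
    """
    if net.number_of_edges() == 0:
        return {v: i + 1 for i, v in enumerate(sorted(net.nodes))}, 0.0
    unsigned = nx.Graph()
    unsigned.add_nodes_from(sorted(net.nodes))
    unsigned.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in net.edges))
    comms = nx.community.louvain_communities(unsigned, seed=seed)
    q = nx.community.modularity(unsigned, comms)
    ordered = sorted(comms, key=lambda c: (-len(c), min(c)))
    modules = {}
    for rank, comm in enumerate(ordered, start=1):
        for v in comm:
            modules[v] = rank
    return modules, float(q)


def zi_pi(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's mean
    and SD (0 when the SD is 0); Pi = 1 − Σₘ (kᵢₘ/kᵢ)².  Roles follow the
    quadrant thresholds Zi = 2.5 and Pi = 0.6: network hubs (both high),
    module hubs (high Zi only), connectors (high Pi only), peripherals.
    Isolated nodes get Zi = Pi = 0 and are peripheral.
    """
    missing = [v for v in net.nodes if v not in modules]
    if missing:
        raise ValueError(f"modules do not cover nodes: {missing[:5]}")
    nodes = sorted(net.nodes)
    within_degree = {}
    module_links = {}
    for v in nodes:
        counts: dict = {}
        for u in net.neighbors(v):
            counts[modules[u]] = counts.get(modules[u], 0) + 1
        module_links[v] = counts
        within_degree[v] = counts.get(modules[v], 0)

    by_module: dict = {}
    for v in nodes:
        by_module.setdefault(modules[v], []).append(within_degree[v])
    module_stats = {
        m: (float(np.mean(ks)), float(np.std(ks, ddof=0)))
        for m, ks in by_module.items()
    }

    rows = []
    for v in nodes:
        k = net.degree(v)
        mean_m, sd_m = module_stats[modules[v]]
        zi = (within_degree[v] - mean_m) / sd_m if sd_m > 0 else 0.0
        if k > 0:
            pi = 1.0 - sum((c / k) ** 2 for c in module_links[v].values())
        else:
            pi = 0.0
        role = role_for(zi, pi)
        rows.append(
            {"node": v, "module": modules[v], "degree": k, "zi": zi, "pi": pi,
             "role": role}
        )
    return pd.DataFrame(rows).set_index("node")


def module_abundance(table: OtuTable, modules: dict) -> pd.DataFrame:
    """Per-sample module abundance: mean z-scored relative abundance of members.

    Each member OTU's relative abundance is standardized across samples
    (zero-variance members contribute 0 with a warning); a module's profile is
    the mean over its members, so each profile has mean ≈ 0 across samples.
    """
    rel = table.relative_abundance()
    otu_index = {o: j for j, o in enumerate(table.otu_ids)}
    unknown = [o for o in modules if o not in otu_index]
    if unknown:
        raise ValueError(f"module members absent from table: {unknown[:5]}")
    profiles = {}
    for m in sorted(set(modules.values())):
        members = [o for o, mm in modules.items() if mm == m]
        zs = []
        for o in members:
            x = rel[:, otu_index[o]]
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
            if sd == 0:
                warnings.warn(
                    f"OTU {o!r} has zero variance; contributes 0 to module {m}",
                    stacklevel=2,
                )
                zs.append(np.zeros_like(x))
            else:
                zs.append((x - x.mean()) / sd)
        profiles[f"module_{m}"] = np.mean(zs, axis=0)
    return pd.DataFrame(profiles, index=list(table.sample_ids))


def module_function_regression(
    module_profiles: pd.DataFrame, mop: pd.Series
) -> pd.DataFrame:
    """OLS of each module abundance profile on per-sample MOP, BH-corrected."""
    mop = mop.dropna()
    shared = [s for s in module_profiles.index if s in mop.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples with MOP")
    x = mop[shared].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError("zero variance in MOP")
    rows = []
    for col in module_profiles.columns:
        y = module_profiles.loc[shared, col].to_numpy(float)
        if np.std(y) == 0:
            raise ValueError(f"zero-variance module profile: {col}")
        fit = scipy.stats.linregress(x, y)
        rows.append(
            {
                "module": col,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.rvalue**2,
                "p": fit.pvalue,
            }
        )
    out = pd.DataFrame(rows).set_index("module")
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustnessCurve:
    removed_fraction: np.ndarray
    natural_connectivity: np.ndarray
    removal_mode: str
    n_repeats: int
    truncated: bool = False


def natural_connectivity(net: nx.Graph) -> float:
    """ln( (1/N) Σᵢ exp(λᵢ) ) over the unsigned adjacency spectrum."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    adj = nx.to_numpy_array(net, nodelist=sorted(net.nodes))
    adj = np.abs(np.sign(adj))  # unsigned, unweighted
    eig = np.linalg.eigvalsh(adj)
    return float(logsumexp(eig) - np.log(n))


def robustness(
    net: nx.Graph,
    removal_mode: str = "random",
    fractions=None,
    n_repeats: int = 50,
    seed: int = 0,
) -> RobustnessCurve:
    """Natural connectivity as nodes are progressively removed.

    ``random`` removes uniformly chosen nodes, averaged over ``n_repeats``
    independent orders; ``targeted_degree`` removes nodes in decreasing order
    of their degree in the intact network (ties broken by node id).  The
    curve is truncated (and flagged) at fractions that would empty the graph.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if fractions is None:
        fractions = np.arange(0.0, 0.8001, 0.05)
    fractions = np.asarray(list(fractions), dtype=float)
    if np.any(np.diff(fractions) <= 0):
        raise ValueError("fractions must be strictly increasing")
    nodes = sorted(net.nodes)
    n = len(nodes)
    rng = np.random.default_rng(seed)

    def curve_for_order(order) -> list[float]:
        vals = []
        for f in fractions:
            k = int(round(f * n))
            if n - k < 1:
                break
            remaining = net.subgraph([v for v in nodes if v not in order[:k]])
            vals.append(natural_connectivity(remaining))
        return vals

    if removal_mode == "targeted_degree":
        order = sorted(nodes, key=lambda v: (-net.degree(v), v))
        set_order = curve_for_order(order)
        curves = [set_order]
        n_repeats = 1
    elif removal_mode == "random":
        curves = []
        for _ in range(n_repeats):
            order = list(rng.permutation(nodes))
            curves.append(curve_for_order(order))
    else:
        raise ValueError(f"unknown removal_mode {removal_mode!r}")

    min_len = min(len(c) for c in curves)
    truncated = min_len < len(fractions)
    mean_curve = np.mean([c[:min_len] for c in curves], axis=0)
    return RobustnessCurve(
        removed_fraction=fractions[:min_len],
        natural_connectivity=mean_curve,
        removal_mode=removal_mode,
        n_repeats=n_repeats,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def network_to_tables(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (node_a, node_b, sign, weight) and node attribute table."""
    edges = pd.DataFrame(
        [
            {
                "node_a": min(u, v),
                "node_b": max(u, v),
                "sign": d.get("sign", 1),
                "weight": d.get("weight", np.nan),
            }
            for u, v, d in net.edges(data=True)
        ]
    ).sort_values(["node_a", "node_b"]) if net.number_of_edges() else pd.DataFrame(
        columns=["node_a", "node_b", "sign", "weight"]
    )
    nodes = pd.DataFrame(
        [{"node": v, **net.nodes[v]} for v in sorted(net.nodes)]
    ).set_index("node")
    return edges.reset_index(drop=True), nodes
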