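"""Cross-compartment Spearman co-expression networks.

For every DET pair across two compartments (coral–algal, algal–prokaryotic,
coral–prokaryotic), the Spearman rank correlation is computed over matched
samples; significant pairs (p ≤ 0.05, large-sample t approximation,
two-sided) form a bipartite network. Hubs are ranked by size-adjusted
betweenness: raw shortest-path betweenness divided by the number of
transcripts included in the network, so hub scores are comparable across
networks of different sizes. The top-k (default 20) nodes are the network's
core transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)

NETWORK_NAMES: tuple[str, ...] = (
    "coral-algal",
    "algal-prokaryotic",
    "coral-prokaryotic",
)

#: The compartment pair behind each network name.
NETWORK_PAIRS: dict[str, tuple[str, str]] = {
    "coral-algal": ("coral", "symbiodiniaceae"),
    "algal-prokaryotic": ("symbiodiniaceae", "prokaryote"),
    "coral-prokaryotic": ("coral", "prokaryote"),
}


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (midranks for ties) and two-sided p from the t approximation.

    t = rho * sqrt((n−2)/(1−rho²)) with n−2 degrees of freedom; |rho| = 1
    yields p = 0.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DataError("constant input: Spearman rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_approx_p(np.array([rho]), n)[0]


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    return np.minimum(p, 1.0)


def correlate_pairs(
    expr_a: pd.DataFrame, expr_b: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """All cross-compartment Spearman correlations between two DET matrices.

    ``expr_a`` and ``expr_b`` are transcripts × samples (matched columns;
    any monotone per-transcript transform, e.g. log2(CPM+1), leaves rho
    unchanged). Returns an edge table (transcript_a, transcript_b, rho,
    p_value, sign) and n_pairs_tested = |A| × |B|. Constant transcripts are
    excluded from the edge table with a logged warning but still count
    toward n_pairs_tested.
    """
    if list(expr_a.columns) != list(expr_b.columns):
        raise DataError("sample columns of the two compartments do not match")
    n = expr_a.shape[1]
    if n < 4:
        raise DataError("need at least 4 matched samples for correlation")
    n_pairs = expr_a.shape[0] * expr_b.shape[0]

    def _ranks(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        r = stats.rankdata(df.to_numpy(dtype=float), axis=1)
        mean = r.mean(axis=1, keepdims=True)
        sd = r.std(axis=1)
        ok = sd > 0
        z = np.zeros_like(r)
        z[ok] = (r[ok] - mean[ok]) / sd[ok, None]
        return z, ok

    za, ok_a = _ranks(expr_a)
    zb, ok_b = _ranks(expr_b)
    for df, ok in ((expr_a, ok_a), (expr_b, ok_b)):
        for tid in df.index[~ok]:
            logger.warning("constant transcript %s excluded from correlation", tid)

    rho = za @ zb.T / n  # |A| × |B|
    p = _t_approx_p(rho.ravel(), n).reshape(rho.shape)
    ia, ib = np.nonzero(np.outer(ok_a, ok_b))
    edges = pd.DataFrame(
        {
            "transcript_a": expr_a.index.to_numpy()[ia],
            "transcript_b": expr_b.index.to_numpy()[ib],
            "rho": rho[ia, ib],
            "p_value": p[ia, ib],
        }
    )
    edges["sign"] = np.where(edges["rho"] >= 0, "positive", "negative")
    return edges, int(n_pairs)


@dataclass
class BipartiteNetwork:
    """Significant cross-compartment correlation edges plus bookkeeping."""

    name: str
    graph: nx.Graph
    n_pairs_tested: int
    n_significant: int
    alpha: float = 0.05
    adjusted_betweenness: dict = field(default_factory=dict)

    @property
    def proportion_significant(self) -> float:
        """Fraction of tested pairs with p ≤ alpha, in [0, 1]."""
        if self.n_pairs_tested == 0:
            return 0.0
        return self.n_significant / self.n_pairs_tested

    @property
    def percent_significant(self) -> float:
        return 100.0 * self.proportion_significant


def build_network(
    edges: pd.DataFrame,
    n_pairs_tested: int,
    name: str = "coral-algal",
    alpha: float = 0.05,
    compartments: tuple[str, str] | None = None,
) -> BipartiteNetwork:
    """Keep edges with p ≤ alpha and assemble the bipartite graph.

    Node attributes carry the compartment label (side A or B of the pair).
    """
    if name not in NETWORK_PAIRS and compartments is None:
        raise DataError(f"unknown network name {name!r}")
    comp_a, comp_b = compartments or NETWORK_PAIRS[name]
    sig = edges[edges["p_value"] <= alpha]
    g = nx.Graph(name=name)
    for row in sig.itertuples(index=False):
        g.add_node(row.transcript_a, compartment=comp_a)
        g.add_node(row.transcript_b, compartment=comp_b)
        g.add_edge(
            row.transcript_a,
            row.transcript_b,
            rho=float(row.rho),
            p_value=float(row.p_value),
            sign=row.sign,
        )
    net = BipartiteNetwork(
        name=name,
        graph=g,
        n_pairs_tested=int(n_pairs_tested),
        n_significant=int(len(sig)),
        alpha=alpha,
    )
    net.adjusted_betweenness = adjusted_betweenness(net)
    return net


def adjusted_betweenness(
    network: BipartiteNetwork | nx.Graph,
    normalization: str = "node_count",
) -> dict[str, float]:
    """Size-adjusted betweenness centrality for every node.

    Raw shortest-path betweenness on the unweighted graph, divided by the
    number of transcripts included in the network (``node_count``; this keeps
    hub scores monotone in raw betweenness while removing the direct effect
    of network size). ``pair_count`` instead divides by (N−1)(N−2)/2, the
    conventional normalization. Isolated and degree-1 nodes score 0.
    """
    g = network.graph if isinstance(network, BipartiteNetwork) else network
    n = g.number_of_nodes()
    if n == 0:
        return {}
    raw = nx.betweenness_centrality(g, normalized=False)
    if normalization == "node_count":
        denom = float(n)
    elif normalization == "pair_count":
        denom = max((n - 1) * (n - 2) / 2.0, 1.0)
    else:
        raise DataError(f"unknown normalization {normalization!r}")
    return {node: b / denom for node, b in raw.items()}


def core_transcripts(
    network: BipartiteNetwork, k: int = 20
) -> list[tuple[str, float]]:
    """Top-k nodes by adjusted betweenness.

    Deterministic tie-break: centrality descending, then transcript id
    ascending. Returns all nodes when the network has fewer than k.
    """
    if network.graph.number_of_nodes() == 0:
        raise DataError("core_transcripts() needs a network with >= 1 node")
    scores = network.adjusted_betweenness or adjusted_betweenness(network)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def node_table(network: BipartiteNetwork, k_core: int = 20) -> pd.DataFrame:
    """Node attribute table (transcript, compartment, centrality, is_core)."""
    core = {t for t, _ in core_transcripts(network, k_core)} if network.graph else set()
    rows = [
        {
            "transcript_id": node,
            "compartment": data.get("compartment", ""),
            "adjusted_betweenness": network.adjusted_betweenness.get(node, 0.0),
            "is_core": node in core,
        }
        for node, data in network.graph.nodes(data=True)
    ]
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "compartment", "adjusted_betweenness", "is_core"],
    )
    return df.sort_values(
        ["adjusted_betweenness", "transcript_id"], ascending=[False, True]
    ).reset_index(drop=True)


def edge_table(network: BipartiteNetwork) -> pd.DataFrame:
    """Cytoscape-importable edge list for one network."""
    rows = [
        {
            "source": u,
            "target": v,
            "rho": d["rho"],
            "p_value": d["p_value"],
            "sign": d["sign"],
            "network_name": network.name,
        }
        for u, v, d in network.graph.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "rho", "p_value", "sign", "network_name"]
    )
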