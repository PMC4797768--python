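"""Analysis of sociometric matrices: reciprocity statistics and network
structure.

Three summaries characterize a cooperation matrix:

* the within-subject given-vs-received relation — for every agent i,
  regress / correlate the acts i gave to each partner j on the acts i
  received from j, then aggregate across agents (a positive mean
  correlation is the signature of "apparent reciprocity");
* Freeman degree centralization of the symmetrized, binarized network
  (1 for a star, 0 for any regular graph);
* Newman modularity Q of the symmetrized weighted network under a greedy
  agglomerative (CNM) community partition.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .single_gen import SociometricMatrix

__all__ = [
    "ReciprocityReport",
    "NetworkSummary",
    "given_received_regression",
    "degree_centralization",
    "modularity",
    "export_network",
    "read_network",
]


@dataclasses.dataclass
class ReciprocityReport:
    """Per-agent and population-level given-vs-received statistics.

    Agents whose given or received vector has zero variance across partners
    have no defined slope/correlation; they are flagged, excluded from the
    aggregates, and counted in ``n_excluded``.
    """

    per_agent: pd.DataFrame  # columns: agent, slope, pearson_r, defined
    mean_slope: float
    mean_r: float
    frac_positive_r: float
    t_statistic: float
    p_value: float
    n_defined: int
    n_excluded: int

    @property
    def empty(self) -> bool:
        return self.n_defined == 0

    def to_csv(self, path: str | Path) -> None:
        """Per-agent rows followed by one summary row."""
        df = self.per_agent.copy()
        summary = pd.DataFrame(
            [
                {
                    "agent": "population",
                    "slope": self.mean_slope,
                    "pearson_r": self.mean_r,
                    "defined": self.n_defined,
                }
            ]
        )
        pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)


def given_received_regression(m: SociometricMatrix) -> ReciprocityReport:
    """Within-subject OLS slope and Pearson r of given on received.

    For agent i the paired observations over partners j != i are
    ``(received_ij = counts[j, i], given_ij = counts[i, j])``; the slope is
    from the ordinary least-squares fit of given on received.
    """
    counts = m.counts.astype(float)
    n = m.n
    if n < 3:
        raise ValueError("need at least 3 agents")
    rows = []
    for i in range(n):
        mask = np.arange(n) != i
        given = counts[i, mask]
        received = counts[mask, i]
        if given.std() == 0 or received.std() == 0:
            rows.append(
                {"agent": i, "slope": np.nan, "pearson_r": np.nan, "defined": False}
            )
            continue
        slope = float(np.cov(received, given, ddof=0)[0, 1] / received.var())
        r = float(np.corrcoef(received, given)[0, 1])
        rows.append({"agent": i, "slope": slope, "pearson_r": r, "defined": True})
    per_agent = pd.DataFrame(rows)
    defined = per_agent[per_agent["defined"]]
    n_defined = len(defined)
    if n_defined == 0:
        return ReciprocityReport(
            per_agent, np.nan, np.nan, np.nan, np.nan, np.nan, 0, n
        )
    rs = defined["pearson_r"].to_numpy()
    if n_defined >= 2 and rs.std() > 0:
        t_stat, p_val = stats.ttest_1samp(rs, 0.0)
    else:
        t_stat, p_val = np.nan, np.nan
    return ReciprocityReport(
        per_agent=per_agent,
        mean_slope=float(defined["slope"].mean()),
        mean_r=float(rs.mean()),
        frac_positive_r=float((rs > 0).mean()),
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_defined=n_defined,
        n_excluded=n - n_defined,
    )


def pooled_dyad_regression(m: SociometricMatrix) -> tuple[float, float]:
    """Alternative aggregation: one regression over all ordered dyads
    pooled; returns ``(slope, pearson_r)``."""
    counts = m.counts.astype(float)
    n = m.n
    off = ~np.eye(n, dtype=bool)
    given = counts[off]
    received = counts.T[off]
    slope = float(np.cov(received, given, ddof=0)[0, 1] / received.var())
    r = float(np.corrcoef(received, given)[0, 1])
    return slope, r


def degree_centralization(m: SociometricMatrix, weighted: bool = False) -> float:
    """Freeman degree centralization of the symmetrized network.

    Default: binarize the symmetrized matrix at weight > 0 and compute
    ``sum(c_max - c_i) / ((N-1)(N-2))`` over degrees — 1 for a star, 0 for
    any regular graph.  With ``weighted=True``, degrees are replaced by
    node strengths and the sum is normalized by ``(N-1) * s_max`` (0 when
    every strength equals the maximum).
    """
    n = m.n
    if n < 3:
        raise ValueError("need at least 3 agents")
    sym = m.symmetrized()
    if weighted:
        s = sym.sum(axis=1).astype(float)
        s_max = s.max()
        if s_max == 0:
            return 0.0
        return float((s_max - s).sum() / ((n - 1) * s_max))
    deg = (sym > 0).sum(axis=1)
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


@dataclasses.dataclass
class NetworkSummary:
    """Community structure of the symmetrized weighted cooperation network."""

    centralization: float
    modularity_Q: float
    n_communities: int
    partition: dict[int, int]


def _to_graph(m: SociometricMatrix) -> nx.Graph:
    sym = m.symmetrized()
    g = nx.Graph()
    g.add_nodes_from(range(m.n))
    rows, cols = np.nonzero(np.triu(sym, k=1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(sym[i, j])) for i, j in zip(rows, cols)
    )
    return g


def modularity(m: SociometricMatrix) -> NetworkSummary:
    """Greedy (CNM) community partition and its Newman weighted modularity.

    Q(partition) = (1/2W) * sum_ij [w_ij - k_i k_j / 2W] * 1[same community]
    on the symmetrized graph.  The agglomerative optimizer is deterministic,
    so repeated calls return the same partition.
    """
    if np.count_nonzero(m.counts) == 0:
        raise ValueError("modularity is undefined for an empty graph")
    g = _to_graph(m)
    communities = nx.community.greedy_modularity_communities(g, weight="weight")
    q = nx.community.modularity(g, communities, weight="weight")
    partition = {int(node): ci for ci, comm in enumerate(communities) for node in comm}
    return NetworkSummary(
        centralization=degree_centralization(m),
        modularity_Q=float(q),
        n_communities=len(communities),
        partition=partition,
    )


def export_network(
    m: SociometricMatrix, path: str | Path, node_attrs: dict[int, dict] | None = None
) -> None:
    """Write the directed weighted cooperation network as GraphML.

    Every agent becomes a node (isolates included); every nonzero count an
    edge with a ``weight`` attribute.  Round-trips through
    :func:`read_network`.
    """
    g = nx.DiGraph()
    for i in range(m.n):
        attrs = (node_attrs or {}).get(i, {})
        g.add_node(i, **attrs)
    rows, cols = np.nonzero(m.counts)
    for i, j in zip(rows, cols):
        g.add_edge(int(i), int(j), weight=int(m.counts[i, j]))
    nx.write_graphml(g, path)


def read_network(path: str | Path) -> SociometricMatrix:
    """Read a GraphML cooperation network back into a count matrix."""
    g = nx.read_graphml(path)
    nodes = sorted(g.nodes, key=lambda s: int(s))
    n = len(nodes)
    counts = np.zeros((n, n), dtype=np.int64)
    for u, v, data in g.edges(data=True):
        counts[int(u), int(v)] = int(data["weight"])
    return SociometricMatrix(counts)
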