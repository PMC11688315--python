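"""Copied-visit detection, contagion graphs, and group engagement metrics.

A drinking corner counts as *demonstrated* immediately after any animal's
visit there.  A visit is a *copied visit* when a different animal enters the
same corner with latency below the threshold (default 4 s, strict ``<``).
The latency is measured from the previous occupant's exit to the follower's
entry — the corner holds one animal at a time, so an entry-to-entry
reference would conflate long leader visits with slow following; the
entry-to-entry variant is available for sensitivity analysis.  Only the
immediately preceding occupant can be the leader: an intervening visitor
has itself become the new demonstrator, so chains A->B->C yield two copied
visits and every visit copies at most one leader.

Each cage's contagion episode is summarized as an undirected weighted graph:
nodes are animals (with activation state), and the weight of an edge is the
*association index* — the number of copied visits between that pair in
either direction.  An observer is *activated* when it made at least one
corner visit inside the contagion window, and *passive* otherwise; a
*follower* is an observer that appears as the follower of at least one
copied visit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .events import (
    ROLE_DEMONSTRATOR,
    ROLE_OBSERVER,
    ValidationError,
    cage_strains,
    observers,
)

DEFAULT_LATENCY_THRESHOLD = 4.0

COPIED_COLUMNS = [
    "cage", "leader", "follower", "corner",
    "leader_exit", "follower_entry", "latency",
]

ACT_DEMONSTRATOR = "demonstrator"
ACT_ACTIVATED = "activated"
ACT_PASSIVE = "passive"


def detect_copied_visits(
    visits: pd.DataFrame,
    window: tuple[float, float],
    latency_threshold: float = DEFAULT_LATENCY_THRESHOLD,
    latency_reference: str = "exit",
) -> pd.DataFrame:
    """Detect copied visits inside a window.

    Parameters
    ----------
    visits : validated visit table (single-occupancy guaranteed upstream).
    window : ``[start, end)``; both the leader's and the follower's entries
        must fall inside it.
    latency_threshold : strict upper bound on the latency, seconds.
    latency_reference : ``"exit"`` (leader exit -> follower entry, default)
        or ``"entry"`` (leader entry -> follower entry).

    Returns a DataFrame with columns :data:`COPIED_COLUMNS`, ordered by
    follower entry time.  Deterministic in the input row order (an internal
    sort fixes the order).
    """
    if latency_reference not in ("exit", "entry"):
        raise ValueError("latency_reference must be 'exit' or 'entry'")
    start, end = window
    rows: list[tuple] = []
    if len(visits) == 0 or latency_threshold <= 0:
        return pd.DataFrame(rows, columns=COPIED_COLUMNS)

    ent = visits["entry"].to_numpy()
    sel = visits.iloc[np.nonzero((ent >= start) & (ent < end))[0]]
    for (cage, corner), grp in sel.groupby(["cage", "corner"], sort=True):
        g = grp.sort_values("entry", kind="mergesort")
        animal = g["animal"].to_numpy()
        entry = g["entry"].to_numpy()
        exit_ = g["exit"].to_numpy()
        ref = exit_ if latency_reference == "exit" else entry
        lat = entry[1:] - ref[:-1]
        if latency_reference == "exit" and (lat < 0).any():
            raise ValidationError(
                "negative copy latency: overlapping occupancy escaped validation"
            )
        hit = (animal[1:] != animal[:-1]) & (lat >= 0) & (lat < latency_threshold)
        for i in np.nonzero(hit)[0]:
            rows.append(
                (
                    cage, animal[i], animal[i + 1], corner,
                    float(exit_[i]), float(entry[i + 1]), float(lat[i]),
                )
            )
    out = pd.DataFrame(rows, columns=COPIED_COLUMNS)
    return out.sort_values(
        ["follower_entry", "cage", "corner"], kind="mergesort"
    ).reset_index(drop=True)


def build_graph(
    copied: pd.DataFrame,
    roster: pd.DataFrame,
    contagion_summary: pd.DataFrame,
    cage: str,
) -> nx.Graph:
    """Build one cage's contagion graph.

    Nodes carry ``role`` and ``activation`` attributes; activation of an
    observer requires at least one visit (un-normalized total over the
    contagion window) — the summary passed here must therefore be computed
    over the same window as ``copied`` with divisor 1.  Each copied visit
    increments the weight of the unordered {leader, follower} pair.
    """
    members = roster[roster["cage"] == cage]
    if len(members) == 0:
        raise ValidationError(f"cage {cage!r} absent from roster")
    if (contagion_summary["normalization_divisor"] != 1.0).any():
        raise ValidationError("activation requires an un-normalized contagion summary")
    totals = contagion_summary.set_index("animal")["total_visits"]

    G = nx.Graph(cage=str(cage))
    for _, row in members.iterrows():
        a = str(row["animal"])
        if row["role"] == ROLE_DEMONSTRATOR:
            act = ACT_DEMONSTRATOR
        else:
            act = ACT_ACTIVATED if totals.get(a, 0.0) >= 1 else ACT_PASSIVE
        G.add_node(a, role=str(row["role"]), activation=act)

    ccage = copied[copied["cage"] == cage]
    unknown = set(ccage["leader"]).union(ccage["follower"]) - set(G.nodes)
    if unknown:
        raise ValidationError(
            f"copied visits reference animals missing from cage {cage!r}: {sorted(unknown)}"
        )
    for _, cv in ccage.iterrows():
        u, v = str(cv["leader"]), str(cv["follower"])
        if G.has_edge(u, v):
            G[u][v]["weight"] += 1
        else:
            G.add_edge(u, v, weight=1)
    return G


@dataclass(frozen=True)
class GroupMetrics:
    """Engagement metrics of one cage over the contagion window."""

    cage: str
    n: int                       # group size N (observers + demonstrator)
    n_observers: int
    n_activated_observers: int
    n_passive_observers: int
    n_followers: int             # observers following in >= 1 copied visit
    actual_edges: int
    possible_edges: int          # (N^2 - N) / 2

    def as_dict(self) -> dict:
        return asdict(self)


def possible_edges(n: int) -> int:
    """Number of unordered animal pairs in a group of size ``n``."""
    return (n * n - n) // 2


def compute_group_metrics(graph: nx.Graph, copied: pd.DataFrame) -> GroupMetrics:
    """Reduce one cage graph (plus its copied visits) to engagement counts."""
    cage = str(graph.graph["cage"])
    roles = nx.get_node_attributes(graph, "role")
    acts = nx.get_node_attributes(graph, "activation")
    obs = [a for a, r in roles.items() if r == ROLE_OBSERVER]
    activated = [a for a in obs if acts[a] == ACT_ACTIVATED]
    followers = set(copied.loc[copied["cage"] == cage, "follower"].astype(str)) & set(obs)
    n = graph.number_of_nodes()
    return GroupMetrics(
        cage=cage,
        n=n,
        n_observers=len(obs),
        n_activated_observers=len(activated),
        n_passive_observers=len(obs) - len(activated),
        n_followers=len(followers),
        actual_edges=graph.number_of_edges(),
        possible_edges=possible_edges(n),
    )


@dataclass(frozen=True)
class PooledMetrics:
    """Plain sums of per-cage metrics within one strain."""

    strain: str
    n_cages: int
    n_observers: int
    n_activated_observers: int
    n_passive_observers: int
    n_followers: int
    actual_edges: int
    possible_edges: int

    def as_dict(self) -> dict:
        return asdict(self)


def pool_metrics(
    metrics: list[GroupMetrics], roster: pd.DataFrame, strain: str
) -> PooledMetrics:
    """Pool per-cage metrics across the cages of one strain.

    Cages of a different strain in ``metrics`` are an error: pooled counts
    are strain cohorts, never mixtures.
    """
    strains = cage_strains(roster)
    for m in metrics:
        got = strains.get(m.cage)
        if got is None:
            raise ValidationError(f"cage {m.cage!r} absent from roster")
        if got != strain:
            raise ValidationError(
                f"cage {m.cage!r} belongs to strain {got!r}, cannot pool into {strain!r}"
            )
    return PooledMetrics(
        strain=str(strain),
        n_cages=len(metrics),
        n_observers=sum(m.n_observers for m in metrics),
        n_activated_observers=sum(m.n_activated_observers for m in metrics),
        n_passive_observers=sum(m.n_passive_observers for m in metrics),
        n_followers=sum(m.n_followers for m in metrics),
        actual_edges=sum(m.actual_edges for m in metrics),
        possible_edges=sum(m.possible_edges for m in metrics),
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.Graph, path) -> None:
    """Serialize a cage graph to Graphviz DOT (plain writer, no dependency)."""
    lines = [f'graph "{graph.graph.get("cage", "cage")}" {{']
    for node, attrs in sorted(graph.nodes(data=True)):
        attr = ", ".join(f'{k}="{v}"' for k, v in sorted(attrs.items()))
        lines.append(f'  "{node}" [{attr}];')
    for u, v, attrs in sorted(graph.edges(data=True)):
        a, b = sorted((u, v))
        lines.append(f'  "{a}" -- "{b}" [weight={attrs.get("weight", 1)}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
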