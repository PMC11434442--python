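"""Greedy hierarchical agglomeration of network modules (CNM-style).

Starting from singleton communities, the connected pair of communities whose
merge gives the largest modularity gain is merged repeatedly; the partition
with the highest modularity along the merge path is returned. Ties in the
gain are broken by the lowest (min id, max id) community pair so runs are
fully reproducible. Modularity is unweighted by default (edge presence
only); a weighted variant is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from rhizonet.errors import ValidationError


@dataclass(frozen=True)
class Partition:
    """Node -> module assignment with its modularity score."""

    membership: dict
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def module_sizes(self) -> dict:
        sizes: dict = {}
        for module in self.membership.values():
            sizes[module] = sizes.get(module, 0) + 1
        return sizes

    def as_sets(self) -> list[set]:
        groups: dict = {}
        for node, module in self.membership.items():
            groups.setdefault(module, set()).add(node)
        return [groups[m] for m in sorted(groups)]


def _edge_weight(data: dict, weighted: bool) -> float:
    return float(data.get("weight", 1.0)) if weighted else 1.0


def modularity(g: nx.Graph, membership: dict, weighted: bool = False) -> float:
    """Q = sum over modules of (internal edge fraction - attachment^2)."""
    missing = [v for v in g.nodes if v not in membership]
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing[:5]}")
    m2 = sum(_edge_weight(d, weighted) for _, _, d in g.edges(data=True)) * 2.0
    if m2 == 0:
        return 0.0
    internal: dict = {}
    deg_sum: dict = {}
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d, weighted)
        cu, cv = membership[u], membership[v]
        if cu == cv:
            internal[cu] = internal.get(cu, 0.0) + w
        deg_sum[cu] = deg_sum.get(cu, 0.0) + w
        deg_sum[cv] = deg_sum.get(cv, 0.0) + w
    q = 0.0
    for c in set(membership.values()):
        e_cc = 2.0 * internal.get(c, 0.0) / m2
        a_c = deg_sum.get(c, 0.0) / m2
        q += e_cc - a_c * a_c
    return q


def fast_greedy(g: nx.Graph, weighted: bool = False) -> Partition:
    """Greedy modularity maximization by hierarchical agglomeration.

    Returns the best partition along the merge path. Zero-edge graphs yield
    singleton modules with Q = 0. Module ids are densely renumbered from 0.
    """
    if g.is_multigraph():
        raise ValidationError("multigraphs are not supported")
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return Partition(membership={}, modularity=0.0)
    index = {v: i for i, v in enumerate(nodes)}

    m2 = sum(_edge_weight(d, weighted) for _, _, d in g.edges(data=True)) * 2.0
    if m2 == 0:
        return Partition(membership={v: i for i, v in enumerate(nodes)}, modularity=0.0)

    # community state: between-community edge weight, per-community degree sum
    members: dict[int, set] = {i: {v} for v, i in index.items()}
    deg_sum = {i: 0.0 for i in members}
    between: dict[int, dict[int, float]] = {i: {} for i in members}
    for u, v, d in g.edges(data=True):
        w = _edge_weight(d, weighted)
        iu, iv = index[u], index[v]
        deg_sum[iu] += w
        deg_sum[iv] += w
        if iu != iv:
            between[iu][iv] = between[iu].get(iv, 0.0) + w
            between[iv][iu] = between[iv].get(iu, 0.0) + w

    def current_q() -> float:
        q = 0.0
        for c in members:
            a_c = deg_sum[c] / m2
            q -= a_c * a_c
        q += internal_total * 2.0 / m2
        return q

    internal_total = sum(
        _edge_weight(d, weighted) for u, v, d in g.edges(data=True) if u == v
    )
    best_q = current_q()
    best_members = {c: set(s) for c, s in members.items()}

    while len(members) > 1:
        best_gain = None
        best_pair = None
        for a in sorted(between):
            for b in sorted(between[a]):
                if b <= a:
                    continue
                gain = (
                    2.0 * between[a][b] / m2
                    - 2.0 * (deg_sum[a] / m2) * (deg_sum[b] / m2)
                )
                if (
                    best_gain is None
                    or gain > best_gain + 1e-15
                    or (abs(gain - best_gain) <= 1e-15 and (a, b) < best_pair)
                ):
                    best_gain = gain
                    best_pair = (a, b)
        if best_pair is None:  # no connected pairs left (disconnected graph)
            break
        a, b = best_pair
        internal_total += between[a][b]
        deg_sum[a] += deg_sum.pop(b)
        members[a] |= members.pop(b)
        # fold b's neighbour weights into a
        for c, w in between.pop(b).items():
            if c == a:
                continue
            between[c].pop(b, None)
            between[a][c] = between[a].get(c, 0.0) + w
            between[c][a] = between[a][c]
        between[a].pop(b, None)
        for c in list(between[a]):
            if c == b:
                del between[a][c]

        q = current_q()
        if q > best_q + 1e-15:
            best_q = q
            best_members = {c: set(s) for c, s in members.items()}

    membership: dict = {}
    for new_id, c in enumerate(sorted(best_members)):
        for v in best_members[c]:
            membership[v] = new_id
    return Partition(membership=membership, modularity=best_q)
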