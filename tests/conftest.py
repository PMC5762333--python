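"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: mining
is verified by exhaustive subset enumeration, activity scoring by a
naive sort-and-average implementation, and enrichment by exact
rational-arithmetic summation.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from subspa.mining import SubpathwayGraph


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_subpathways(graph: nx.Graph, k: int):
    """Maximal distance-<=k gene sets by exhaustive subset enumeration."""
    nodes = list(graph.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(graph))

    def ok(subset):
        return all(
            v in dist.get(u, {}) and dist[u][v] <= k
            for u, v in combinations(subset, 2)
        )

    valid = [
        frozenset(c)
        for r in range(1, len(nodes) + 1)
        for c in combinations(nodes, r)
        if ok(c)
    ]
    maximal = [
        s for s in valid
        if not any(s < t for t in valid)
    ]
    return set(maximal)


def naive_spa(values: dict, components, exponent_sign=+1) -> float:
    """sPA for one sample by materializing the sorted feature list.

    ``values`` maps feature id -> expression. Ranks are assigned by
    explicit position averaging over sorted order.
    """
    items = sorted(values.items(), key=lambda kv: kv[1])
    n = len(items)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j + 1 < n and items[j + 1][1] == items[i][1]:
            j += 1
        avg = (i + 1 + j + 1) / 2.0
        for idx in range(i, j + 1):
            ranks[items[idx][0]] = avg
        i = j + 1
    weights = {f: r * np.exp(exponent_sign * r / n) for f, r in ranks.items()}
    comp = [weights[f] for f in values if f in components]
    compl = [weights[f] for f in values if f not in components]
    return float(np.mean(comp) - np.mean(compl))


def exact_hypergeom_upper_tail(m: int, t: int, n: int, r: int) -> float:
    """P(X >= r) by exact rational summation of the lower tail."""
    total = comb(m, n)
    acc = Fraction(0)
    for k in range(r):
        acc += Fraction(comb(t, k) * comb(m - t, n - k), total)
    return float(1 - acc)


def grid_cox_coefficient(x, time, event, lo=-6.0, hi=6.0):
    """Maximize the tie-free Cox partial likelihood on a fine grid."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]

    def neg_log_pl(bgrid):
        out = np.zeros_like(bgrid)
        for i in range(len(x)):
            if event[i] != 1:
                continue
            risk = x[i:]  # later or equal times are at risk
            out += -(bgrid * x[i]) + np.log(
                np.exp(np.outer(bgrid, risk)).sum(axis=1)
            )
        return out

    grid = np.linspace(lo, hi, 24001)
    best = grid[np.argmin(neg_log_pl(grid))]
    fine = np.linspace(best - 1e-3, best + 1e-3, 4001)
    return float(fine[np.argmin(neg_log_pl(fine))])


def two_group_logrank_statistic(time, event, group):
    """Classical 2-group log-rank chi-square by event-time tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    assert len(labels) == 2
    u = v = 0.0
    for tj in np.unique(time[event == 1]):
        at_risk = time >= tj
        nj = at_risk.sum()
        n1j = (at_risk & (group == labels[0])).sum()
        dj = ((time == tj) & (event == 1)).sum()
        d1j = ((time == tj) & (event == 1) & (group == labels[0])).sum()
        u += d1j - dj * n1j / nj
        if nj > 1:
            v += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    return u * u / v


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

KGML_TEMPLATE = """<?xml version="1.0"?>
<pathway name="{name}" title="{title}">
{entries}
{relations}
</pathway>
"""


def make_kgml(entries, relations, name="path:test01", title="Toy pathway"):
    """Build a KGML document. ``entries``: (id, type, name-or-components);
    ``relations``: (entry1, entry2) pairs."""
    e_lines = []
    for eid, etype, payload in entries:
        if etype == "group":
            comps = "".join(f'<component id="{c}"/>' for c in payload)
            e_lines.append(f'  <entry id="{eid}" type="group">{comps}</entry>')
        else:
            e_lines.append(f'  <entry id="{eid}" name="{payload}" type="{etype}"/>')
    r_lines = [
        f'  <relation entry1="{a}" entry2="{b}" type="PPrel"/>'
        for a, b in relations
    ]
    return KGML_TEMPLATE.format(
        name=name, title=title,
        entries="\n".join(e_lines), relations="\n".join(r_lines),
    )


@pytest.fixture
def path_graph_5():
    """Path graph A-B-C-D-E as a PathwayGraph."""
    from subspa.pathway_io import PathwayGraph

    return PathwayGraph.from_edges(
        "path:p5", "path of five", "ABCDE",
        [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")],
    )


@pytest.fixture
def toy_subpathway():
    return SubpathwayGraph(
        subpathway_id="path:test01_1",
        parent_id="path:test01",
        parent_name="Toy pathway",
        genes=frozenset({"g1", "g2", "g3"}),
        lncrnas=frozenset({"L1", "L2"}),
        gene_edges=frozenset({frozenset(("g1", "g2")), frozenset(("g2", "g3"))}),
        reg_edges=frozenset({("L1", "g1"), ("L2", "g2"), ("L2", "g3")}),
    )


def random_expression(rng, features, samples, tie_prob=0.0):
    data = rng.lognormal(1.0, 1.0, size=(len(features), len(samples)))
    if tie_prob:
        mask = rng.random(data.shape) < tie_prob
        data[mask] = np.round(data[mask], 0)
    return pd.DataFrame(data, index=features, columns=samples)
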