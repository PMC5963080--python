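"""Independent brute-force oracles shared by the metric and heuristic tests.

Everything here is deliberately naive — explicit enumeration over pairs,
adjacency rebuilt from the raw link list — and shares no code path with
the package implementation it checks.
"""

import math


# -- ranking metric oracles ------------------------------------------------


def oracle_auroc(labels, scores):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def oracle_ap(labels_ranked):
    """Precision after each positive, averaged over positives."""
    vals = []
    hits = 0
    for i, l in enumerate(labels_ranked, 1):
        if l:
            hits += 1
            vals.append(hits / i)
    return sum(vals) / len(vals)


def oracle_p_at_k(labels_ranked, k_ratio):
    k = math.ceil(k_ratio * sum(labels_ranked))
    return sum(labels_ranked[:k]) / k


def oracle_node_metrics(pairs_ranked, labels_ranked):
    """(MAP, averaged R-precision) by per-node recount."""
    nodes = sorted({n for p in pairs_ranked for n in p})
    aps, rps = [], []
    for node in nodes:
        sub = [l for p, l in zip(pairs_ranked, labels_ranked) if node in p]
        n_pos = sum(sub)
        if n_pos == 0:
            continue
        aps.append(oracle_ap(sub))
        rps.append(sum(sub[:n_pos]) / n_pos)
    return sum(aps) / len(aps), sum(rps) / len(rps)


# -- heuristic oracles -----------------------------------------------------


def adj_from_links(links):
    adj = {}
    for u, v in links:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def oracle_cn(links, u, v):
    adj = adj_from_links(links)
    return len(adj.get(u, set()) & adj.get(v, set()))


def oracle_cn_bipartite(links, u, v):
    adj = adj_from_links(links)
    nhat = set()
    for w in adj.get(v, set()):
        nhat |= adj.get(w, set())
    return len(adj.get(u, set()) & nhat)


def oracle_jaccard(links, u, v):
    adj = adj_from_links(links)
    nu, nv = adj.get(u, set()), adj.get(v, set())
    return len(nu & nv) / len(nu | nv) if nu | nv else 0.0


def oracle_jaccard_bipartite(links, u, v):
    adj = adj_from_links(links)
    nu = adj.get(u, set())
    nhat = set()
    for w in adj.get(v, set()):
        nhat |= adj.get(w, set())
    return len(nu & nhat) / len(nu | nhat) if nu | nhat else 0.0


def oracle_aa(links, u, v, bipartite=False):
    c = oracle_cn_bipartite(links, u, v) if bipartite else oracle_cn(links, u, v)
    if c == 0:
        return 0.0
    if c == 1:
        return 2.0 / math.log(2.0)
    return 1.0 / math.log(c)
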