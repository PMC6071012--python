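"""Definition-level reference implementations used as independent oracles.

Everything here is computed from first principles with plain Python sets
and exhaustive enumeration over the full lncRNA x disease grid — no
adjacency matrices, no shared code with the package's scoring path.
"""

from __future__ import annotations

from collections import deque


def _adjacent(edges, key, key_first):
    """Neighbours of ``key`` by scanning an edge collection."""
    if key_first:
        return {b for a, b in edges if a == key}
    return {a for a, b in edges if b == key}


def brute_features(network, lncrna, disease):
    """Feature partition of a pair: list of ('miRNA'|'gene'|'pair', members)."""
    cm = (_adjacent(network.mln.edges, lncrna, key_first=False)
          & _adjacent(network.mdn.edges, disease, key_first=False))
    features = []
    if network.mode == "GN2":
        cg = (_adjacent(network.gln.edges, lncrna, key_first=False)
              & _adjacent(network.gdn.edges, disease, key_first=False))
        pairs = sorted((m, g) for m in cm for g in cg
                       if (g, m) in network.gmn.edges)
        covered_m = {m for m, _ in pairs}
        covered_g = {g for _, g in pairs}
        features += [("pair", pair) for pair in pairs]
        features += [("miRNA", (m,)) for m in sorted(cm - covered_m)]
        features += [("gene", (g,)) for g in sorted(cg - covered_g)]
    else:
        features += [("miRNA", (m,)) for m in sorted(cm)]
    return features


def _feature_adjacency(network, kind, members):
    """(lncRNA set, disease set) adjacent to a feature, from definitions."""
    if kind == "miRNA":
        (m,) = members
        return (_adjacent(network.mln.edges, m, key_first=True),
                _adjacent(network.mdn.edges, m, key_first=True))
    if kind == "gene":
        (g,) = members
        return (_adjacent(network.gln.edges, g, key_first=True),
                _adjacent(network.gdn.edges, g, key_first=True))
    m, g = members
    lncs = (_adjacent(network.mln.edges, m, key_first=True)
            & _adjacent(network.gln.edges, g, key_first=True))
    diss = (_adjacent(network.mdn.edges, m, key_first=True)
            & _adjacent(network.gdn.edges, g, key_first=True))
    return lncs, diss


def brute_counts(network, kind, members, excluded_edge=None):
    """(N+, N-, Nl, Nd) by enumerating every lncRNA x disease pair."""
    known = set(network.ldn.edges)
    known.discard(excluded_edge)
    lncs, diss = _feature_adjacency(network, kind, members)
    n_plus = n_minus = 0
    for l in network.lncrnas:
        for d in network.diseases:
            if l in lncs and d in diss:
                if (l, d) in known:
                    n_plus += 1
                else:
                    n_minus += 1
    return n_plus, n_minus, len(lncs), len(diss)


def brute_score(network, lncrna, disease, excluded_edge=None):
    """Posterior-odds score from definitions (prior, features, counts)."""
    known = set(network.ldn.edges)
    known.discard(excluded_edge)
    n_pairs = len(network.lncrnas) * len(network.diseases)
    p1 = len(known) / n_pairs
    if p1 == 0:
        return 0.0
    if p1 == 1:
        return float("inf")
    phi = p1 / (1 - p1)
    score = phi
    for kind, members in brute_features(network, lncrna, disease):
        n_plus, n_minus, _, _ = brute_counts(network, kind, members,
                                             excluded_edge)
        score *= (n_plus + 1) / (n_minus + 1) / phi
    return score


def brute_auc(pos_scores, neg_scores):
    """Exhaustive pairwise-comparison AUC with half credit for ties."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def bfs_depths(parents, sources):
    """Minimum hop distance from any source, following parent links."""
    depth = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        node = queue.popleft()
        for parent in parents.get(node, ()):
            if parent not in depth:
                depth[parent] = depth[node] + 1
                queue.append(parent)
    return depth
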