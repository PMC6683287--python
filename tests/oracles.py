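"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or
direct evaluation, without touching the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def bruteforce_best(hits, evalue_max=1e-5):
    """Per-query best hit by exhaustive scan (bitscore, -evalue, identity,
    then lexicographically smallest subject)."""
    best = {}
    for h in hits:
        if h.evalue >= evalue_max or h.query == h.subject:
            continue
        key = (h.bitscore, -h.evalue, h.identity)
        cur = best.get(h.query)
        if cur is None:
            best[h.query] = h
            continue
        cur_key = (cur.bitscore, -cur.evalue, cur.identity)
        if key > cur_key or (key == cur_key and h.subject < cur.subject):
            best[h.query] = h
    return best


def bruteforce_bbh(hits_ab, hits_ba, evalue_max=1e-5):
    """Reciprocal best-hit pairs [(a, b, mean identity)], sorted by a."""
    best_ab = bruteforce_best(hits_ab, evalue_max)
    best_ba = bruteforce_best(hits_ba, evalue_max)
    pairs = []
    for a, ha in best_ab.items():
        hb = best_ba.get(ha.subject)
        if hb is not None and hb.subject == a:
            pairs.append((a, ha.subject, (ha.identity + hb.identity) / 2.0))
    return sorted(pairs)


def bruteforce_wgrr(rep_a, rep_b, hits_ab, hits_ba, evalue_max=1e-5):
    pairs = bruteforce_bbh(hits_ab, hits_ba, evalue_max)
    return 100.0 * sum(p[2] for p in pairs) / min(rep_a.n_proteins, rep_b.n_proteins)


def bruteforce_concordance_cutoff(pairs, target=0.95):
    """Scan every observed wGRR value ascending; first satisfying wins."""
    best = None
    for t in sorted({p.wgrr for p in pairs}):
        selected = [p for p in pairs if p.wgrr >= t]
        if sum(p.same_label for p in selected) / len(selected) >= target:
            best = t
            break
    return best


def grid_search_rss(xs, ys, n_alpha=60, n_beta=60, n_gamma=60):
    """Dense 3-d grid minimum RSS for Y = alpha*exp(-beta*X) + gamma."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    span = ys.max() - ys.min()
    alphas = np.linspace(-0.5 * span, 2.5 * span + 1.0, n_alpha)
    betas = np.logspace(-3, 0.7, n_beta)
    gammas = np.linspace(ys.min() - span - 1.0, ys.max() + 1.0, n_gamma)
    best = np.inf
    for beta in betas:
        basis = np.exp(-beta * xs)  # (n_points,)
        pred = (
            alphas[:, None, None] * basis[None, None, :]
            + gammas[None, :, None]
        )
        rss = ((pred - ys[None, None, :]) ** 2).sum(axis=2)
        best = min(best, float(rss.min()))
    return best


def connected_components(edges, nodes):
    """Connected components by BFS over an explicit adjacency map."""
    adjacency = {n: set() for n in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    seen = set()
    components = []
    for node in nodes:
        if node in seen:
            continue
        queue, component = [node], set()
        while queue:
            current = queue.pop()
            if current in component:
                continue
            component.add(current)
            queue.extend(adjacency[current] - component)
        seen |= component
        components.append(frozenset(component))
    return set(components)
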