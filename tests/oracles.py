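"""Independent, loop-based reference implementations used as test oracles.

Everything here is written deliberately naively (pure Python, explicit
loops, no shared code with the package) so that agreement with the
vectorized production pipeline is meaningful evidence of correctness.
"""

from __future__ import annotations

import math


def naive_structural_weights(w: list[list[float]]):
    """Per-node (uw, dw, sw) triples from a weight matrix, by hand."""
    n = len(w)
    k = [sum(1 for y in range(n) if w[x][y] > 0) for x in range(n)]
    s = [sum(w[x]) for x in range(n)]
    sum_k = sum(k)
    sum_s = sum(s)
    triples = []
    for x in range(n):
        if k[x] == 0:
            triples.append((0.0, 0.0, 0.0))
        else:
            triples.append(
                (
                    s[x] / k[x],
                    k[x] ** 2 / sum_k / s[x],
                    s[x] ** 2 / sum_s / k[x],
                )
            )
    return triples, k, s


def naive_redd_matrix(w: list[list[float]], d: int) -> list[list[float]]:
    """Per-pair REDD similarity recomputed from scratch.

    Follows the full chain: structural triples -> Euclidean distances ->
    normalized probability distributions -> top-d reduction (unit-weight
    ranking, index tie-break, isolated nodes excluded) -> per-term
    zero-convention base-2 relative entropy -> symmetric difference ->
    1 - d_xy / d_max.
    """
    n = len(w)
    triples, k, _ = naive_structural_weights(w)
    if all(kx == 0 for kx in k):
        return [[1.0] * n for _ in range(n)]

    def dist(x, y):
        return math.sqrt(sum((triples[x][i] - triples[y][i]) ** 2 for i in range(3)))

    dd = [[dist(x, y) for y in range(n)] for x in range(n)]
    prob = []
    for x in range(n):
        total = sum(dd[x])
        if total == 0:
            prob.append([1.0] * n)
        else:
            prob.append([1.0 - dd[x][y] / total for y in range(n)])

    candidates = [x for x in range(n) if k[x] > 0]
    candidates.sort(key=lambda x: (-triples[x][0], x))
    top = candidates[:d]

    reduced = []
    for x in range(n):
        v = [prob[x][z] for z in top]
        total = sum(v)
        if total == 0:
            v = [1.0 / len(top)] * len(top)
        else:
            v = [e / total for e in v]
        reduced.append(v)

    def re(x, y):
        acc = 0.0
        for pz, qz in zip(reduced[x], reduced[y]):
            if pz > 0 and qz > 0:
                acc += pz * math.log2(pz / qz)
        return acc

    diff = [[0.0] * n for _ in range(n)]
    d_max = 0.0
    for x in range(n):
        for y in range(x + 1, n):
            dxy = (re(x, y) + re(y, x)) / 2.0
            diff[x][y] = diff[y][x] = dxy
            d_max = max(d_max, dxy)

    sim = [[1.0] * n for _ in range(n)]
    if d_max > 0:
        for x in range(n):
            for y in range(n):
                sim[x][y] = 1.0 if x == y else 1.0 - diff[x][y] / d_max
    return sim


def naive_cn(w):
    n = len(w)
    out = [[0.0] * n for _ in range(n)]
    for x in range(n):
        for y in range(n):
            if x != y:
                out[x][y] = sum(1 for z in range(n) if w[x][z] > 0 and w[y][z] > 0)
    return out


def naive_wcn(w):
    n = len(w)
    out = [[0.0] * n for _ in range(n)]
    for x in range(n):
        for y in range(n):
            if x != y:
                out[x][y] = sum(
                    w[x][z] + w[y][z]
                    for z in range(n)
                    if w[x][z] > 0 and w[y][z] > 0
                )
    return out


def naive_aa(w):
    n = len(w)
    k = [sum(1 for y in range(n) if w[x][y] > 0) for x in range(n)]
    out = [[0.0] * n for _ in range(n)]
    for x in range(n):
        for y in range(n):
            if x != y:
                out[x][y] = sum(
                    1.0 / math.log(k[z])
                    for z in range(n)
                    if w[x][z] > 0 and w[y][z] > 0
                )
    return out


def naive_waa(w):
    n = len(w)
    s = [sum(w[x]) for x in range(n)]
    out = [[0.0] * n for _ in range(n)]
    for x in range(n):
        for y in range(n):
            if x != y:
                out[x][y] = sum(
                    (w[x][z] + w[y][z]) / math.log(1.0 + s[z])
                    for z in range(n)
                    if w[x][z] > 0 and w[y][z] > 0
                )
    return out


def naive_walk_density(w, x: int, t: int) -> list[float]:
    """t-step unweighted walk density from node x by repeated
    vector-matrix multiplication (isolated nodes self-loop)."""
    n = len(w)
    k = [sum(1 for y in range(n) if w[x2][y] > 0) for x2 in range(n)]
    p = [
        [
            (1.0 if (k[i] == 0 and i == j) else ((w[i][j] > 0) / k[i] if k[i] else 0.0))
            for j in range(n)
        ]
        for i in range(n)
    ]
    pi = [1.0 if i == x else 0.0 for i in range(n)]
    for _ in range(t):
        pi = [sum(p[i][j] * pi[i] for i in range(n)) for j in range(n)]
    return pi


def naive_re_lrw(w, d: int, t: int):
    """Per-pair RE-LRW similarity via loops, mirroring the construction."""
    n = len(w)
    k = [sum(1 for y in range(n) if w[x][y] > 0) for x in range(n)]
    pis = [naive_walk_density(w, x, t) for x in range(n)]
    order = sorted(range(n), key=lambda x: (-k[x], x))
    top = order[:d]
    reduced = []
    for x in range(n):
        v = [pis[x][z] for z in top]
        total = sum(v)
        if total == 0:
            v = [1.0 / len(top)] * len(top)
        else:
            v = [e / total for e in v]
        reduced.append(v)
    return _difference_similarity(reduced, n)


def naive_lre(w):
    """Per-pair LRE similarity from closed-neighborhood degree histograms."""
    n = len(w)
    k = [sum(1 for y in range(n) if w[x][y] > 0) for x in range(n)]
    observed = sorted(set(k))
    reduced = []
    for x in range(n):
        members = [x] + [y for y in range(n) if w[x][y] > 0]
        hist = [0.0] * len(observed)
        for y in members:
            hist[observed.index(k[y])] += 1.0
        reduced.append([h / len(members) for h in hist])
    return _difference_similarity(reduced, n)


def _difference_similarity(reduced, n):
    def re(x, y):
        acc = 0.0
        for pz, qz in zip(reduced[x], reduced[y]):
            if pz > 0 and qz > 0:
                acc += pz * math.log2(pz / qz)
        return acc

    diff = [[0.0] * n for _ in range(n)]
    d_max = 0.0
    for x in range(n):
        for y in range(x + 1, n):
            dxy = (re(x, y) + re(y, x)) / 2.0
            diff[x][y] = diff[y][x] = dxy
            d_max = max(d_max, dxy)
    sim = [[1.0] * n for _ in range(n)]
    if d_max > 0:
        for x in range(n):
            for y in range(n):
                sim[x][y] = 1.0 if x == y else 1.0 - diff[x][y] / d_max
    return sim
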