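"""Independent brute-force oracles used by the test suite.

Everything here works on plain ``{term: [parents]}`` dicts and simple loops,
deliberately sharing no code with the package implementation: closures by
fixpoint expansion, IC by explicit entity counting, MICA by exhaustive
intersection scan, and the full percentage score re-derived scalar by
scalar.
"""

from __future__ import annotations

import math


def naive_ancestors(parents: dict[str, list[str]], term: str) -> set[str]:
    """Reflexive ancestor set by repeated parent expansion to a fixpoint."""
    closure = {term}
    while True:
        grown = set(closure)
        for t in closure:
            grown.update(parents[t])
        if grown == closure:
            return closure
        closure = grown


def naive_ic(
    parents: dict[str, list[str]],
    corpus: list[tuple[str, set[str]]],
    roots: set[str],
) -> dict[str, float]:
    """IC by explicit counting: an entity counts for every ancestor of its terms."""
    n = len(corpus)
    ic: dict[str, float] = {}
    for term in parents:
        if term in roots:
            ic[term] = 0.0
            continue
        count = 0
        for _, terms in corpus:
            covered = set()
            for t in terms:
                covered |= naive_ancestors(parents, t)
            if term in covered:
                count += 1
        ic[term] = math.log(n) if count == 0 else -math.log(count / n)
    return ic


def naive_mica_ic(
    parents: dict[str, list[str]], ic: dict[str, float], t1: str, t2: str
) -> float:
    """Maximum IC over the full intersection of the two ancestor sets."""
    common = naive_ancestors(parents, t1) & naive_ancestors(parents, t2)
    return max((ic[c] for c in common), default=0.0)


def naive_pair_score(
    parents: dict[str, list[str]], ic: dict[str, float], t1: str, t2: str
) -> float:
    """sqrt(Jaccard(ancestors) * IC(MICA)) recomputed from scratch."""
    a1 = naive_ancestors(parents, t1)
    a2 = naive_ancestors(parents, t2)
    inter = a1 & a2
    if not inter:
        return 0.0
    jac = len(inter) / len(a1 | a2)
    return math.sqrt(jac * naive_mica_ic(parents, ic, t1, t2))


def naive_phenodigm(
    parents: dict[str, list[str]],
    ic: dict[str, float],
    disease_terms: set[str],
    model_terms: set[str],
) -> tuple[float, float, float]:
    """(raw_max, raw_mean, percentage): the whole formula, re-derived.

    Every pairwise similarity, each query's best match, the max and mean of
    those, the disease self-optimum, and the normalised percentage.
    """
    best = [
        max(naive_pair_score(parents, ic, q, h) for h in model_terms)
        for q in disease_terms
    ]
    raw_max = max(best)
    raw_mean = sum(best) / len(best)
    selfs = [naive_pair_score(parents, ic, t, t) for t in disease_terms]
    opt_max = max(selfs)
    opt_mean = sum(selfs) / len(selfs)
    if opt_max <= 0:
        return raw_max, raw_mean, 0.0
    pct = 100.0 * (raw_max / opt_max + raw_mean / opt_mean) / 2.0
    return raw_max, raw_mean, min(100.0, max(0.0, pct))


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating hypergeometric tables.

    Conditions on the margins of [[a, b], [c, d]] and sums the probabilities
    of every table at most as probable as the observed one (with a small
    relative tolerance for float ties, as is conventional).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up: q(i) = min over j >= i of p(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


def wilcoxon_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    from itertools import combinations

    pooled = sorted(x + y)
    # midranks
    ranks: dict[float, float] = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        for v in pooled[i:j]:
            ranks[v] = (i + j + 1) / 2.0
        i = j
    obs = sum(ranks[v] for v in x)
    n, nx = len(pooled), len(x)
    mean = nx * (n + 1) / 2.0
    all_ranks = [ranks[v] for v in pooled]
    stats = [sum(combo) for combo in combinations(all_ranks, nx)]
    dev = abs(obs - mean)
    hits = sum(1 for s in stats if abs(s - mean) >= dev - 1e-12)
    return hits / len(stats)
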