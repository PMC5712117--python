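"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available —
exhaustive enumeration, direct definition, or textbook series — fully
independently of the library code paths it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from vinenc.types import AlignmentHit

_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def brute_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum nested base-pair count by exhaustive recursion.

    Recurses over contiguous index intervals: the first position is
    either unpaired or paired with every admissible partner, splitting
    the interval into inside and outside. Exponential; for n <= 12 only.
    """
    seq = sequence.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:  # interval [i, j)
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j):
            if (seq[i], seq[k]) in _PAIR:
                best = max(best, 1 + rec(i + 1, k) + rec(k + 1, j))
        return best

    return rec(0, len(seq))


def brute_ks_statistic(a, b) -> float:
    """sup |ECDF1 - ECDF2| over the pooled value set, by direct counting."""
    a, b = list(a), list(b)
    best = 0.0
    for x in a + b:
        f1 = sum(1 for v in a if v <= x) / len(a)
        f2 = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(f1 - f2))
    return best


def kolmogorov_sf_series(x: float, terms: int = 200) -> float:
    """Asymptotic Kolmogorov survival function, textbook alternating series."""
    if x <= 0:
        return 1.0
    s = 0.0
    for k in range(1, terms + 1):
        s += (-1) ** (k - 1) * math.exp(-2.0 * k * k * x * x)
    return max(0.0, min(1.0, 2.0 * s))


def infix_edit_distance(query: str, target: str) -> int:
    """Best edit distance of query against any substring of target (full DP)."""
    nq, nt = len(query), len(target)
    prev = [0] * (nt + 1)  # free leading gap in target
    for i in range(1, nq + 1):
        cur = [i] + [0] * nt
        for j in range(1, nt + 1):
            cost = 0 if query[i - 1] == target[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def connected_components_union_find(edges, nodes) -> set[frozenset]:
    """Connected components via a hand-rolled union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent[find(u)] = find(v)
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def random_reciprocal_tables(rng: np.random.Generator, n_a: int, n_b: int,
                             density: float = 0.5):
    """Random bipartite score tables with mirrored directional rows."""
    fwd, rev = [], []
    for i in range(n_a):
        for j in range(n_b):
            if rng.random() < density:
                bits = round(float(rng.uniform(50, 500)), 1)
                ev = 10.0 ** -float(rng.uniform(6, 60))
                ident = round(float(rng.uniform(50, 100)), 2)
                fwd.append(AlignmentHit(f"a{i}", f"b{j}", ident, 300, ev, bits))
                # reverse direction, slightly perturbed but order-preserving
                rev.append(AlignmentHit(f"b{j}", f"a{i}", ident, 300, ev, bits))
    return fwd, rev


def _top_hit(hits_for_query) -> str | None:
    """Best subject by bit desc, E asc, identity desc, subject id asc."""
    best = None
    for h in hits_for_query:
        key = (-h.bit_score, h.evalue, -h.percent_identity, h.subject_id)
        if best is None or key < best[0]:
            best = (key, h.subject_id)
    return best[1] if best else None


def classical_rbh_pairs(fwd, rev, evalue_max=1e-5) -> set[tuple[str, str]]:
    """Single-pass RBH pair set, recomputed directly from the definition."""
    by_q_fwd: dict[str, list] = {}
    for h in fwd:
        if h.evalue <= evalue_max:
            by_q_fwd.setdefault(h.query_id, []).append(h)
    by_q_rev: dict[str, list] = {}
    for h in rev:
        if h.evalue <= evalue_max:
            by_q_rev.setdefault(h.query_id, []).append(h)
    pairs = set()
    for a, hits in by_q_fwd.items():
        b = _top_hit(hits)
        if b is not None and b in by_q_rev and _top_hit(by_q_rev[b]) == a:
            pairs.add((a, b))
    return pairs


def irbh_iteration_consistency(fwd, rev, pairs, evalue_max=1e-5) -> bool:
    """Check that iteration-k pairs equal the classical RBHs of the tables
    with all genes anchored in rounds 1..k-1 removed."""
    max_iter = max((p.iteration for p in pairs), default=0)
    for k in range(1, max_iter + 1):
        done_a = {p.a_id for p in pairs if p.iteration < k}
        done_b = {p.b_id for p in pairs if p.iteration < k}
        f = [h for h in fwd if h.query_id not in done_a and h.subject_id not in done_b]
        r = [h for h in rev if h.query_id not in done_b and h.subject_id not in done_a]
        expect = classical_rbh_pairs(f, r, evalue_max)
        got = {(p.a_id, p.b_id) for p in pairs if p.iteration == k}
        if got != expect:
            return False
    return True
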