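"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a different route than the
implementation under test: a textbook quadratic DP for alignment scores, a
breadth-first search for connected components, brute-force set logic for
reciprocity, explicit entropy/pair-counting sums for the metrics, and an
exhaustive enumeration of contingency tables for E[MI].  They are
deliberately simple and slow.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal affine-gap local alignment score by the textbook O(nm)
    three-matrix recurrence.  A gap of length L costs gap_open + L*gap_extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def bfs_components(nodes, edges) -> list[frozenset]:
    """Connected components by explicit breadth-first search."""
    adj: dict = {n: set() for n in nodes}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            x = queue.popleft()
            comp.add(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        comps.append(frozenset(comp))
    return comps


def brute_force_reciprocal_edges(hits, threshold) -> set[frozenset]:
    """Edge set by direct set logic: {a,b} iff a!=b and both directed hits
    pass the e-value threshold."""
    passing = {(h.query_id, h.target_id) for h in hits if h.evalue <= threshold}
    return {
        frozenset((q, t))
        for (q, t) in passing
        if q != t and (t, q) in passing
    }


def entropy_hcv(truth, pred) -> tuple[float, float, float]:
    """Homogeneity/completeness/V by explicit conditional-entropy sums."""
    n = len(truth)
    classes = sorted(set(truth))
    clusters = sorted(set(pred))

    def H(labels):
        out = 0.0
        for val in set(labels):
            p = labels.count(val) / len(labels)
            out -= p * math.log(p)
        return out

    h_c = H(list(truth))
    h_k = H(list(pred))
    # H(C|K) = sum_k p(k) H(C within cluster k)
    h_c_given_k = 0.0
    for k in clusters:
        members = [truth[i] for i in range(n) if pred[i] == k]
        h_c_given_k += len(members) / n * H(members)
    h_k_given_c = 0.0
    for c in classes:
        members = [pred[i] for i in range(n) if truth[i] == c]
        h_k_given_c += len(members) / n * H(members)
    h = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    v = 0.0 if h + c == 0 else 2 * h * c / (h + c)
    return h, c, v


def pair_counting_ari(truth, pred) -> float:
    """ARI by iterating over all C(n,2) item pairs."""
    n = len(truth)
    both = t_only = p_only = neither = 0
    for i, j in itertools.combinations(range(n), 2):
        same_t = truth[i] == truth[j]
        same_p = pred[i] == pred[j]
        if same_t and same_p:
            both += 1
        elif same_t:
            t_only += 1
        elif same_p:
            p_only += 1
        else:
            neither += 1
    total = math.comb(n, 2)
    sum_a = both + t_only
    sum_b = both + p_only
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def _tables_with_margins(a, b):
    """All non-negative integer tables with row sums a and column sums b."""
    if len(a) == 1:
        if all(x >= 0 for x in b):
            yield [list(b)]
        return
    ranges = [range(0, min(a[0], bj) + 1) for bj in b]
    for combo in itertools.product(*ranges):
        if sum(combo) == a[0]:
            rest = [bj - c for bj, c in zip(b, combo)]
            for tail in _tables_with_margins(a[1:], rest):
                yield [list(combo)] + tail


def exhaustive_expected_mi(a, b) -> float:
    """E[MI] by enumerating every contingency table with the given margins,
    weighted by its generalized hypergeometric probability.  Feasible only
    for tiny N."""
    n = sum(a)
    assert sum(b) == n
    emi = 0.0
    log_const = (
        sum(math.lgamma(x + 1) for x in a)
        + sum(math.lgamma(x + 1) for x in b)
        - math.lgamma(n + 1)
    )
    for table in _tables_with_margins(list(a), list(b)):
        logw = log_const - sum(
            math.lgamma(c + 1) for row in table for c in row
        )
        mi = 0.0
        for i, row in enumerate(table):
            for j, c in enumerate(row):
                if c > 0:
                    mi += c / n * math.log(n * c / (a[i] * b[j]))
        emi += math.exp(logw) * mi
    return emi
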