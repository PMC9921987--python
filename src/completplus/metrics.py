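"""External clustering-quality metrics, implemented from their formulas.

Given a ground-truth labeling (classes C) and a predicted clustering
(clusters K) over the same items, the contingency table n_ij counts items
with class i and cluster j.  From it:

* homogeneity   h = 1 - H(C|K)/H(C)   (1 when every cluster is pure),
* completeness  c = 1 - H(K|C)/H(K)   (1 when every class is whole),
* V-measure     v = 2hc/(h+c)          (harmonic mean),
* ARI: the Rand index adjusted for chance via pair counting,
* AMI: mutual information adjusted for chance via the exact hypergeometric
  expectation E[MI] over tables with fixed margins, normalized by the
  arithmetic mean of the two label entropies.

Entropies are in nats.  Degenerate-case conventions (single class, single
cluster, zero denominators) follow the scikit-learn conventions so numbers
are comparable with the wider literature; the implementations here are
from-formula and depend only on numpy/scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from completplus.errors import CompletPlusError

_EPS = np.finfo(np.float64).eps


@dataclass
class ContingencyTable:
    """Class-by-cluster count matrix with canonical (sorted) label order."""

    counts: np.ndarray          # shape (n_classes, n_clusters), ints
    row_labels: list            # true-class labels, sorted
    col_labels: list            # predicted-cluster labels, sorted

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    homogeneity: float
    completeness: float
    v_measure: float
    ami: float
    ari: float
    n_items: int
    n_classes: int
    n_clusters: int


def contingency(truth: Sequence, pred: Sequence) -> ContingencyTable:
    """Build the contingency table of two equal-length labelings."""
    if len(truth) != len(pred):
        raise CompletPlusError(
            f"labelings differ in length ({len(truth)} vs {len(pred)})"
        )
    if len(truth) == 0:
        raise CompletPlusError("empty labelings")
    row_labels = sorted(set(truth))
    col_labels = sorted(set(pred))
    ri = {l: i for i, l in enumerate(row_labels)}
    ci = {l: j for j, l in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[ri[t], ci[p]] += 1
    return ContingencyTable(counts, row_labels, col_labels)


def _entropy(counts: np.ndarray) -> float:
    """Entropy (nats) of the empirical distribution given by counts."""
    counts = counts[counts > 0].astype(np.float64)
    n = counts.sum()
    if n == 0 or counts.size <= 1:
        return 0.0
    p = counts / n
    return float(-(p * np.log(p)).sum())


def mutual_information(table: ContingencyTable) -> float:
    """MI (nats) between the two labelings from the contingency table."""
    n = table.n
    nz = table.counts > 0
    nij = table.counts[nz].astype(np.float64)
    outer = np.outer(table.row_sums, table.col_sums)[nz].astype(np.float64)
    return float((nij / n * (np.log(nij * n) - np.log(outer))).sum())


def homogeneity_completeness_v(table: ContingencyTable) -> tuple[float, float, float]:
    """(homogeneity, completeness, V-measure).

    h = MI/H(C) and c = MI/H(K), algebraically equal to 1 - H(C|K)/H(C)
    and 1 - H(K|C)/H(K); the convention is 1.0 when the corresponding
    entropy is zero, and v = 0 when h + c = 0.
    """
    h_true = _entropy(table.row_sums)
    h_pred = _entropy(table.col_sums)
    mi = mutual_information(table)
    h = 1.0 if h_true == 0.0 else mi / h_true
    c = 1.0 if h_pred == 0.0 else mi / h_pred
    v = 0.0 if h + c == 0.0 else 2.0 * h * c / (h + c)
    return h, c, v


def adjusted_rand(table: ContingencyTable) -> float:
    """Adjusted Rand index via pair counting.

    ARI = (sum_ij C(n_ij,2) - E) / (M - E) with
    E = [sum_i C(a_i,2) * sum_j C(b_j,2)] / C(N,2) and
    M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2; returns 1.0 when M = E
    (both partitions all-singletons or a single block — the index is at
    its maximum).
    """
    n = table.n
    if n < 2:
        raise CompletPlusError("adjusted Rand index needs at least 2 items")
    sum_ij = sum(math.comb(int(x), 2) for x in table.counts.ravel())
    sum_a = sum(math.comb(int(x), 2) for x in table.row_sums)
    sum_b = sum(math.comb(int(x), 2) for x in table.col_sums)
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def expected_mutual_information(table: ContingencyTable) -> float:
    """Exact E[MI] under the hypergeometric model of random tables with
    the observed margins (the adjustment term of AMI).

    For each cell (i, j) the inner sum runs over all feasible n_ij from
    max(1, a_i + b_j - N) to min(a_i, b_j), weighting the MI contribution
    (n_ij/N) log(N n_ij / a_i b_j) by the hypergeometric probability of
    n_ij, computed in log space with gammaln.
    """
    a = table.row_sums.astype(np.int64)
    b = table.col_sums.astype(np.int64)
    n = table.n
    log_n = math.log(n)
    gln_n1 = gammaln(n + 1)
    emi = 0.0
    for ai in a:
        ai = int(ai)
        for bj in b:
            bj = int(bj)
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1, dtype=np.float64)
            log_p = (
                gammaln(ai + 1) + gammaln(bj + 1)
                + gammaln(n - ai + 1) + gammaln(n - bj + 1)
                - gln_n1
                - gammaln(nij + 1) - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1) - gammaln(n - ai - bj + nij + 1)
            )
            term = nij / n * (np.log(nij) + log_n - math.log(ai) - math.log(bj))
            emi += float((np.exp(log_p) * term).sum())
    return emi


def adjusted_mutual_information(table: ContingencyTable) -> float:
    """AMI = (MI - E[MI]) / (mean(H(C), H(K)) - E[MI]) with arithmetic-mean
    normalization; 1.0 when both labelings are a single label (nothing to
    adjust); a vanishing denominator is clamped to machine epsilon with the
    sign preserved (reference-library convention)."""
    r, c = table.counts.shape
    if r == 1 and c == 1:
        return 1.0
    mi = mutual_information(table)
    emi = expected_mutual_information(table)
    h_true = _entropy(table.row_sums)
    h_pred = _entropy(table.col_sums)
    normalizer = 0.5 * (h_true + h_pred)
    denom = normalizer - emi
    if denom < 0:
        denom = min(denom, -_EPS)
    else:
        denom = max(denom, _EPS)
    return (mi - emi) / denom


def evaluate_clustering(truth: Sequence, pred: Sequence) -> MetricReport:
    """All five metrics for a predicted clustering against ground truth."""
    table = contingency(truth, pred)
    h, c, v = homogeneity_completeness_v(table)
    return MetricReport(
        homogeneity=h,
        completeness=c,
        v_measure=v,
        ami=adjusted_mutual_information(table),
        ari=adjusted_rand(table) if table.n >= 2 else 1.0,
        n_items=table.n,
        n_classes=len(table.row_labels),
        n_clusters=len(table.col_labels),
    )
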