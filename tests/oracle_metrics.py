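"""Textbook-formula clustering-metric oracles, independent of sklearn."""

import numpy as np
from scipy.special import gammaln


def contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ai = np.unique(a, return_inverse=True)
    ub, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=int)
    np.add.at(table, (ai, bi), 1)
    return table


def entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij:
                mi += nij / n * np.log(n * nij / (a[i] * b[j]))
    return mi


def expected_mutual_information(table: np.ndarray) -> float:
    n = int(table.sum())
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo, hi = max(1, ai + bj - n), min(ai, bj)
            for nij in range(lo, hi + 1):
                term = nij / n * np.log(n * nij / (ai * bj))
                logp = (
                    gammaln(ai + 1)
                    + gammaln(bj + 1)
                    + gammaln(n - ai + 1)
                    + gammaln(n - bj + 1)
                    - gammaln(n + 1)
                    - gammaln(nij + 1)
                    - gammaln(ai - nij + 1)
                    - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += term * np.exp(logp)
    return emi


def nmi_oracle(a, b):
    t = contingency(a, b)
    hu, hv = entropy(t.sum(axis=1)), entropy(t.sum(axis=0))
    if hu == 0 and hv == 0:
        return 1.0
    return mutual_information(t) / ((hu + hv) / 2)


def ami_oracle(a, b):
    t = contingency(a, b)
    hu, hv = entropy(t.sum(axis=1)), entropy(t.sum(axis=0))
    mi, emi = mutual_information(t), expected_mutual_information(t)
    denom = (hu + hv) / 2 - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


def ari_oracle(a, b):
    t = contingency(a, b)
    comb = lambda x: x * (x - 1) / 2  # noqa: E731
    sum_ij = comb(t.astype(float)).sum()
    sum_a = comb(t.sum(axis=1).astype(float)).sum()
    sum_b = comb(t.sum(axis=0).astype(float)).sum()
    expected = sum_a * sum_b / comb(float(t.sum()))
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def homo_oracle(true, pred):
    t = contingency(true, pred)
    h_c = entropy(t.sum(axis=1))
    if h_c == 0:
        return 1.0
    n = t.sum()
    b = t.sum(axis=0)
    h_ck = 0.0
    for j in range(t.shape[1]):
        for i in range(t.shape[0]):
            nij = t[i, j]
            if nij:
                h_ck -= nij / n * np.log(nij / b[j])
    return 1 - h_ck / h_c


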