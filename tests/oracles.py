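"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as straight loops from first principles, on
purpose: no scipy ranking, no statsmodels, no shared code with the package.
"""

from __future__ import annotations

import math


def midrank(values, x) -> float:
    """Mid-rank of x within values: (#less) + (#equal + 1)/2."""
    less = sum(1 for v in values if v < x)
    equal = sum(1 for v in values if v == x)
    return less + (equal + 1) / 2.0


def brunner_munzel(x, y):
    """(W, df, p_two_sided) per the mid-rank formulas, evaluated naively."""
    from scipy.stats import t as tdist  # p only; W/df are scipy-free

    n1, n2 = len(x), len(y)
    pooled = list(x) + list(y)
    R1 = [midrank(pooled, v) for v in x]
    R2 = [midrank(pooled, v) for v in y]
    r1 = [midrank(x, v) for v in x]
    r2 = [midrank(y, v) for v in y]
    Rb1 = sum(R1) / n1
    Rb2 = sum(R2) / n2
    S1 = sum((R1[k] - r1[k] - Rb1 + (n1 + 1) / 2) ** 2 for k in range(n1)) / (n1 - 1)
    S2 = sum((R2[k] - r2[k] - Rb2 + (n2 + 1) / 2) ** 2 for k in range(n2)) / (n2 - 1)
    pooled_var = n1 * S1 + n2 * S2
    if pooled_var == 0:
        return None  # degenerate: complete separation or all ties
    W = n1 * n2 * (Rb2 - Rb1) / ((n1 + n2) * math.sqrt(pooled_var))
    df = pooled_var**2 / ((n1 * S1) ** 2 / (n1 - 1) + (n2 * S2) ** 2 / (n2 - 1))
    p = 2.0 * tdist.sf(abs(W), df)
    return W, df, min(p, 1.0)


def bh_stepup(pvals):
    """q_i = min over j with p_(j) >= p_i of m*p_(j)/j, clipped at 1."""
    m = len(pvals)
    qs = []
    for p_i in pvals:
        candidates = []
        srt = sorted(pvals)
        for j, p_j in enumerate(srt, start=1):
            if p_j >= p_i:
                candidates.append(m * p_j / j)
        qs.append(min(1.0, min(candidates)))
    return qs


def overlap_fraction(lesion_voxels: set, region_voxels: set) -> float:
    return len(lesion_voxels & region_voxels) / len(region_voxels)


def tract_integrity_min(lesion_voxels: set, tract_voxels: set, axis: int) -> float:
    slices = sorted({v[axis] for v in tract_voxels})
    spared = []
    for s in slices:
        in_slice = {v for v in tract_voxels if v[axis] == s}
        hit = len(in_slice & lesion_voxels)
        spared.append(1.0 - hit / len(in_slice))
    return min(spared)


def rrelieff_exhaustive(X, y, k):
    """Straight-loop RReliefF, uniform 1/k influence, lowest-index tie-break.

    X: list of lists (instances x features); y: list.  Exhaustive pass over
    every instance in order.  Returns the list of feature weights.
    """
    n = len(X)
    d = len(X[0])
    lo = [min(row[a] for row in X) for a in range(d)]
    hi = [max(row[a] for row in X) for a in range(d)]
    rng = [hi[a] - lo[a] for a in range(d)]

    def nz(i, a):
        if rng[a] == 0:
            return 0.0
        return (X[i][a] - lo[a]) / rng[a]

    ylo, yhi = min(y), max(y)

    def ydiff(i, j):
        return abs(y[i] - y[j]) / (yhi - ylo)

    def adiff(i, j, a):
        return abs(nz(i, a) - nz(j, a))

    def dist(i, j):
        return sum(adiff(i, j, a) for a in range(d))

    N_dC = 0.0
    N_dA = [0.0] * d
    N_dCdA = [0.0] * d
    for i in range(n):
        others = sorted(
            (j for j in range(n) if j != i), key=lambda j: (dist(i, j), j)
        )
        for j in others[:k]:
            dy = ydiff(i, j)
            N_dC += dy / k
            for a in range(d):
                da = adiff(i, j, a)
                N_dA[a] += da / k
                N_dCdA[a] += dy * da / k
    weights = []
    for a in range(d):
        first = N_dCdA[a] / N_dC if N_dC > 0 else 0.0
        denom = n - N_dC
        second = (N_dA[a] - N_dCdA[a]) / denom if denom > 0 else 0.0
        weights.append(first - second)
    return weights
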