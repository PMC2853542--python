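"""Naive full dynamic-programming oracle for affine-gap local alignment.

Pure-Python Gotoh recurrence over the complete matrix, independent of the
package's alignment engine. Gap convention matches the package: a gap of
length L scores ``gap_open + L * gap_extend`` (both non-positive), and any
column involving N scores the mismatch penalty.
"""

NEG = float("-inf")


def oracle_local_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    n, m = len(a), len(b)
    first_gap = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fi1 = F[i], F[i - 1]
        bi = b
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] + first_gap, Ei[j - 1] + gap_extend)
            Fi[j] = max(Hi1[j] + first_gap, Fi1[j] + gap_extend)
            s = match if (ai == bi[j - 1] and ai != "N") else mismatch
            h = Hi1[j - 1] + s
            v = h if h > 0 else 0.0
            if Ei[j] > v:
                v = Ei[j]
            if Fi[j] > v:
                v = Fi[j]
            Hi[j] = v
            if v > best:
                best = v
    return best


def oracle_pearson_r(x, y) -> float:
    """Direct covariance-formula Pearson r (no library call)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)
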