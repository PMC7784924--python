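"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: plain-Python dynamic programming for
alignment identity, a direct candidate scan for the threshold optimizer,
and a closed-form one-factor PERMANOVA from within-group distance sums.
They share no code with the package internals they check.
"""

import itertools

import numpy as np


def brute_identity(a: str, b: str) -> float:
    """Global alignment identity (match +1, mismatch -1, gap -1) by plain DP.

    Score ties prefer more matches, then shorter alignments, identical to
    the package contract.  Cell values are (score, matches, -alen) tuples.
    """
    la, lb = len(a), len(b)
    cell = [[None] * (lb + 1) for _ in range(la + 1)]
    cell[0][0] = (0, 0, 0)
    for i in range(1, la + 1):
        cell[i][0] = (-i, 0, -i)
    for j in range(1, lb + 1):
        cell[0][j] = (-j, 0, -j)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            hit = a[i - 1] == b[j - 1]
            ds, dm, dl = cell[i - 1][j - 1]
            us, um, ul = cell[i - 1][j]
            ls, lm, ll = cell[i][j - 1]
            cell[i][j] = max(
                (ds + (1 if hit else -1), dm + hit, dl - 1),
                (us - 1, um, ul - 1),
                (ls - 1, lm, ll - 1),
            )
    s, m, neg_alen = cell[la][lb]
    return m / -neg_alen


def brute_optimize_threshold(within, among):
    """Scan every candidate interval directly, counting FP/FN one by one.

    Returns (theta, fp, fn, interval).  Interval rule: half-open intervals
    between consecutive distinct pooled values (plus the extremes), choose
    minimal |FP - FN|, then minimal FP + FN, then the lowest interval;
    theta is the interval midpoint.
    """
    within = sorted(within)
    among = sorted(among)
    values = sorted(set(within) | set(among))
    bounds = [0.0] + values
    intervals = []
    for k, lo in enumerate(bounds):
        hi = values[k] if k < len(values) else 1.0
        if lo >= hi:
            continue
        t = (lo + hi) / 2.0
        fp = sum(1 for v in among if v >= t)
        fn = sum(1 for v in within if v < t)
        intervals.append((abs(fp - fn), fp + fn, k, t, fp, fn, (lo, hi)))
    _, _, _, theta, fp, fn, interval = min(intervals)
    return theta, fp, fn, interval


def one_factor_permanova_f(d2: np.ndarray, groups) -> float:
    """Closed-form one-factor pseudo-F from within-group squared distances.

    SS_total = sum_{i<j} d2_ij / n; SS_within = sum_g sum_{i<j in g} d2 / n_g
    (McArdle & Anderson); F = (SS_between/df_b) / (SS_within/df_w).
    """
    groups = np.asarray(groups)
    n = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = len(np.unique(groups)) - 1
    df_w = n - len(np.unique(groups))
    return (ss_between / df_b) / (ss_within / df_w)


def brute_one_factor_p(d2: np.ndarray, groups) -> float:
    """Exact permutation p for a one-factor design by full enumeration."""
    f_obs = one_factor_permanova_f(d2, groups)
    groups = np.asarray(groups)
    n = len(groups)
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        f = one_factor_permanova_f(d2, groups[list(perm)])
        hits += f >= f_obs - 1e-12
        total += 1
    return hits / total
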