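"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from first principles (direct
scans, pairwise counting, explicit enumeration) rather than reusing any code
path from the package.
"""

import itertools

import numpy as np


def brute_extrema(values, rate, t0, min_separation_s, min_prominence_frac,
                  which="maxima"):
    """O(n*w) peak engine: direct candidate scan, prominence walk, and
    iterative pick-the-tallest selection."""
    x = np.asarray(values, dtype=float)
    if which == "minima":
        x = -x
    n = x.size
    if n < 3:
        return np.empty(0)

    # interior local maxima; plateau -> earliest sample
    cands = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                cands.append(i)
            i = j + 1
        else:
            i += 1
    if not cands:
        return np.empty(0)

    robust_amp = float(np.percentile(values, 95) - np.percentile(values, 5))
    if robust_amp > 0 and min_prominence_frac > 0:
        kept = []
        for i in cands:
            higher_left = np.nonzero(x[:i] > x[i])[0]
            lbase = x[higher_left[-1] + 1:i + 1].min() if higher_left.size else x[:i + 1].min()
            higher_right = np.nonzero(x[i + 1:] > x[i])[0]
            if higher_right.size:
                rbase = x[i:i + 2 + higher_right[0]].min()
            else:
                rbase = x[i:].min()
            prom = x[i] - max(lbase, rbase)
            if prom >= min_prominence_frac * robust_amp - 1e-12:
                kept.append(i)
        cands = kept
    if not cands:
        return np.empty(0)

    # iterative selection: tallest first (earliest sample on ties),
    # discard everything closer than the separation
    min_sep = min_separation_s * rate
    remaining = list(cands)
    selected = []
    while remaining:
        best = max(remaining, key=lambda i: (x[i], -i))
        selected.append(best)
        remaining = [i for i in remaining
                     if i != best and abs(i - best) >= min_sep - 1e-9]
    return t0 + np.sort(np.asarray(selected)) / rate


def mwu_by_pairwise_counting(x, y):
    """U statistic of x via direct pairwise comparison (no ranks)."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def mwu_exact_p_enumeration(x, y):
    """Two-sided exact p by enumerating every assignment of the pooled values
    to the two groups, computing U by pairwise counting for each."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = mwu_by_pairwise_counting(x, y)
    dev = abs(u_obs - mu)
    count = total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in chosen]
        if abs(mwu_by_pairwise_counting(xs, ys) - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total
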