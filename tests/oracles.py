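"""Independent brute-force oracles used by the tests.

Everything here is deliberately written with plain Python loops / direct
formula transcription, independent of the package's vectorized paths.
"""

import math


def time_domain_oracle(x):
    """Direct-summation transcription of the 13 time-domain statistics."""
    x = [float(v) for v in x]
    n = len(x)
    f1 = max(x)
    f2 = min(x)
    f3 = sum(x) / n
    f4 = f1 - f2
    f5 = sum(abs(v) for v in x) / n
    f6 = sum((v - f3) ** 2 for v in x) / (n - 1)
    f7 = math.sqrt(f6)
    f8 = (sum((v - f3) ** 4 for v in x) / n) / f7**4 if f7 > 0 else math.nan
    f9 = (sum((v - f3) ** 3 for v in x) / n) / f7**3 if f7 > 0 else math.nan
    f10 = math.sqrt(sum(v**2 for v in x) / n)
    f11 = f10 / f5 if f5 > 0 else math.nan
    f12 = f4 / f5 if f5 > 0 else math.nan
    f13 = f4 / f10 if f10 > 0 else math.nan
    return {
        "maximum": f1,
        "minimum": f2,
        "mean": f3,
        "peak_to_peak": f4,
        "absolute_average": f5,
        "variance": f6,
        "standard_deviation": f7,
        "kurtosis": f8,
        "skewness": f9,
        "root_mean_square": f10,
        "shape_factor": f11,
        "impulse_factor": f12,
        "crest_factor": f13,
    }


def frequency_domain_oracle(freqs, magnitude, power):
    """Direct-summation transcription of the 9 frequency-domain statistics."""
    f = [float(v) for v in freqs]
    a = [float(v) for v in magnitude]
    p = [float(v) for v in power]
    nb = len(f)
    sum_a = sum(a)
    sum_p = sum(p)
    f14 = sum_a / nb
    f20 = sum_p
    f21 = sum_p / nb
    if sum_a > 0 and sum_p > 0:
        f15 = sum(fi * ai for fi, ai in zip(f, a)) / sum_a
        f16 = sum(fi**2 * ai for fi, ai in zip(f, a)) / sum_a
        f17 = math.sqrt(f16)
        f18 = sum((fi - f15) ** 2 * ai for fi, ai in zip(f, a)) / sum_a
        f19 = sum(fi * pi for fi, pi in zip(f, p)) / sum_p
        pmax = max(p)
        f22 = min(fi for fi, pi in zip(f, p) if pi == pmax)
    else:
        f15 = f16 = f17 = f18 = f19 = f22 = math.nan
    return {
        "mean_magnitude_freq": f14,
        "centroid_frequency": f15,
        "mean_squared_frequency": f16,
        "variance_frequency": f17,
        "frequency_variance": f18,
        "mean_frequency": f19,
        "total_power": f20,
        "average_power": f21,
        "peak_frequency": f22,
    }


def natural_cubic_spline_oracle(ts, ys, t_eval):
    """Natural cubic spline by a direct tridiagonal solve; evaluates t_eval.

    Second derivatives M_i solve the classic tridiagonal system with
    M_0 = M_{n-1} = 0; evaluation uses the standard piecewise-cubic form.
    """
    ts = [float(v) for v in ts]
    ys = [float(v) for v in ys]
    n = len(ts)
    h = [ts[i + 1] - ts[i] for i in range(n - 1)]
    # build and solve the (n-2)-sized tridiagonal system by Thomas algorithm
    if n == 2:
        m = [0.0, 0.0]
    else:
        # system row i (i = 0..n-3): sub = h[i], diag = 2(h[i]+h[i+1]), sup = h[i+1]
        diag = [2.0 * (h[i] + h[i + 1]) for i in range(n - 2)]
        rhs = [
            6.0 * ((ys[i + 2] - ys[i + 1]) / h[i + 1] - (ys[i + 1] - ys[i]) / h[i])
            for i in range(n - 2)
        ]
        for i in range(1, n - 2):  # forward sweep (Thomas)
            w = h[i] / diag[i - 1]
            diag[i] -= w * h[i]
            rhs[i] -= w * rhs[i - 1]
        mm = [0.0] * (n - 2)
        mm[-1] = rhs[-1] / diag[-1]
        for i in range(n - 4, -1, -1):  # back substitution
            mm[i] = (rhs[i] - h[i + 1] * mm[i + 1]) / diag[i]
        m = [0.0] + mm + [0.0]

    out = []
    for t in t_eval:
        t = float(t)
        # locate interval
        i = n - 2
        for j in range(n - 1):
            if t <= ts[j + 1]:
                i = j
                break
        hi = h[i]
        a = (ts[i + 1] - t) / hi
        b = (t - ts[i]) / hi
        val = (
            a * ys[i]
            + b * ys[i + 1]
            + ((a**3 - a) * m[i] + (b**3 - b) * m[i + 1]) * hi**2 / 6.0
        )
        out.append(val)
    return out


def kruskal_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H via the textbook rank formula."""
    pooled = []
    for gi, vals in enumerate(groups):
        pooled.extend((float(v), gi) for v in vals)
    pooled.sort(key=lambda t: t[0])
    n = len(pooled)
    # midranks
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        r = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[k] = r
        i = j
    rank_sums = [0.0] * len(groups)
    for (val, gi), r in zip(pooled, ranks):
        rank_sums[gi] += r
    h = 12.0 / (n * (n + 1)) * sum(
        rank_sums[g] ** 2 / len(groups[g]) for g in range(len(groups))
    ) - 3.0 * (n + 1)
    # tie correction
    tie = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def auc_concordance_oracle(labels, scores):
    """AUC as the concordant-pair fraction (ties count one half)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = len(pos) * len(neg)
    count = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                count += 1.0
            elif sp == sn:
                count += 0.5
    return count / total
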