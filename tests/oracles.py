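"""Independent brute-force oracles for the subgroup machinery.

These deliberately avoid the package's vectorised/streaming code paths:
plain Python loops, explicit type-1 quantiles, exhaustive level sweeps.
"""

import math

import numpy as np




def type1_quantile(values, p):
    """Inverted-CDF quantile: the ceil(p*n)-th order statistic."""
    s = sorted(values)
    idx = max(math.ceil(p * len(s)) - 1, 0)
    return s[idx]


def band_oracle(values, level):
    """(mean, sd, multiplier) from exhaustive enumeration of sup deviations."""
    values = np.asarray(values, dtype=float)
    k, m = values.shape
    mean = np.empty(m)
    sd = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(k):
            s += values[i, j]
        mean[j] = s / k
        ss = 0.0
        for i in range(k):
            dev = values[i, j] - mean[j]
            ss += dev * dev
        sd[j] = math.sqrt(ss / max(k - 1, 1))
    valid = [j for j in range(m) if sd[j] > 0.0]
    w = []
    for i in range(k):
        if valid:
            w.append(max(abs(values[i, j] - mean[j]) / sd[j] for j in valid))
        else:
            w.append(0.0)
    return mean, sd, float(type1_quantile(w, level))


def classify_oracle(values, level, threshold):
    """(D, S) masks by direct application of the decision rule, stated
    in the standardized domain (same algebra as the implementation)."""
    mean, sd, c = band_oracle(values, level)
    m = len(mean)
    D = np.zeros(m, dtype=bool)
    S = np.zeros(m, dtype=bool)
    for j in range(m):
        if sd[j] == 0.0:
            D[j] = mean[j] > threshold
            S[j] = mean[j] > threshold
        else:
            D[j] = (mean[j] - threshold) / sd[j] > c
            S[j] = (threshold - mean[j]) / sd[j] < c
    return D, S


def bracket_oracle(values, D, S, threshold):
    """Exact fraction of draws bracketing the benefit set."""
    values = np.asarray(values, dtype=float)
    hits = 0
    for row in values:
        benefit = row > threshold
        if benefit[D].all() and not benefit[~S].any():
            hits += 1
    return hits / values.shape[0]


def max_level_oracle(values, threshold, level_grid):
    """Signed max credible level per point via a full level sweep."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    out = np.zeros(m)
    for level in sorted(level_grid):
        D, S = classify_oracle(values, level, threshold)
        for j in range(m):
            if D[j]:
                out[j] = level
            elif not S[j] and out[j] <= 0.0:
                out[j] = -level
    return out
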