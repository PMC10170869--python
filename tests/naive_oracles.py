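"""Independent naive-loop reference implementations used as test oracles.

Deliberately written with explicit Python loops and none of the package's
vectorized code paths, so agreement with the package is meaningful.
"""

from __future__ import annotations

import math


def naive_voxel_count(labels, wanted: set[int]) -> int:
    n = 0
    for plane in labels:
        for row in plane:
            for v in row:
                if int(v) in wanted:
                    n += 1
    return n


def naive_mla(data, labels, wanted: set[int]) -> float:
    total = 0.0
    n = 0
    for i in range(len(data)):
        for j in range(len(data[i])):
            for k in range(len(data[i][j])):
                if int(labels[i][j][k]) in wanted:
                    total += float(data[i][j][k])
                    n += 1
    return total / n


def naive_classify(hu: float) -> str:
    """Bracket convention: [-860,-435] normo, (-435,-121) hypo, [-121,121] non."""
    if -860.0 <= hu <= -435.0:
        return "normo"
    if -121.0 <= hu <= 121.0:
        return "non"
    if -435.0 < hu < -121.0:
        return "hypo"
    return "other"


def naive_fractions(data, labels, wanted: set[int]):
    counts = {"normo": 0, "hypo": 0, "non": 0, "other": 0}
    n = 0
    for i in range(len(data)):
        for j in range(len(data[i])):
            for k in range(len(data[i][j])):
                if int(labels[i][j][k]) in wanted:
                    counts[naive_classify(float(data[i][j][k]))] += 1
                    n += 1
    return tuple(100.0 * counts[c] / n for c in ("normo", "hypo", "non", "other"))


def naive_histogram(values, bin_width: float):
    """Half-open bins from min, last bin closed; returns (edges, counts)."""
    lo = min(values)
    hi = max(values)
    if hi > lo:
        n_bins = int(math.ceil((hi - lo) / bin_width))
    else:
        n_bins = 1
    edges = [lo + bin_width * i for i in range(n_bins + 1)]
    counts = [0] * n_bins
    for v in values:
        if v == edges[-1]:
            counts[-1] += 1
            continue
        idx = int((v - lo) // bin_width)
        # guard against float ulp at the right edge of a bin
        while idx + 1 < len(edges) and v >= edges[idx + 1]:
            idx += 1
        while v < edges[idx]:
            idx -= 1
        counts[idx] += 1
    return edges, counts


def naive_rank_average_ties(x):
    """1-based ranks with average assignment on ties."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def naive_spearman(x, y) -> float:
    """Rank-then-Pearson, handling ties by average ranks."""
    rx = naive_rank_average_ties(x)
    ry = naive_rank_average_ties(y)
    n = len(x)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def naive_spearman_no_ties(x, y) -> float:
    """Closed form 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    rx = naive_rank_average_ties(x)
    ry = naive_rank_average_ties(y)
    n = len(x)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
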