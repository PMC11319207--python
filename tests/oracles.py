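"""Independent brute-force oracles used to cross-check the fast paths.

Each function here is written from the mathematical definition with
plain Python loops, deliberately sharing no code with the package.
"""

import numpy as np


def brute_ranks(v):
    """Average ranks with ties, by definition (1-based)."""
    v = list(v)
    ranks = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        # average of ranks less+1 .. less+equal
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def brute_spearman(x, y):
    """Product-moment correlation of average ranks; None if undefined."""
    rx, ry = brute_ranks(x), brute_ranks(y)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx)
    dy = sum((b - my) ** 2 for b in ry)
    if dx == 0 or dy == 0:
        return None
    return num / (dx * dy) ** 0.5


def brute_prominent_peaks(values, min_prominence):
    """Topographic peak prominence by exhaustive path search.

    Plateaus are collapsed; a collapsed plateau that is a local maximum
    is reported at its middle sample.  Prominence = height minus the
    larger of the two side minima, each minimum taken along the path to
    the nearest strictly higher point (or the signal edge).
    """
    v = list(values)
    n = len(v)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i > 0 and v[i - 1] < v[i]
        right_ok = j < n - 1 and v[j + 1] < v[i]
        if left_ok and right_ok:
            mid = (i + j) // 2
            # each side: walk until a strictly higher point or the edge,
            # tracking the minimum; the base is that minimum
            left_base = v[i]
            k = i - 1
            while k >= 0 and v[k] <= v[i]:
                left_base = min(left_base, v[k])
                k -= 1
            right_base = v[j]
            k = j + 1
            while k < n and v[k] <= v[j]:
                right_base = min(right_base, v[k])
                k += 1
            prominence = v[i] - max(left_base, right_base)
            if prominence >= min_prominence:
                peaks.append((mid, v[i], prominence))
        i = j + 1
    return peaks


def brute_shell_counts(pa, pb, dr, r_max, exclude_self=False):
    """Double-loop pair counts per half-open shell [k*dr, (k+1)*dr)."""
    n_shells = int(r_max / dr)
    counts = [0] * n_shells
    for i, p in enumerate(pa):
        for j, q in enumerate(pb):
            if exclude_self and i == j:
                continue
            d = sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5
            k = int(d // dr)
            if k < n_shells and d < r_max:
                counts[k] += 1
    return np.array(counts)


def brute_msd(frames, xy, dt):
    """All-pairs MSD per frame lag, from the definition."""
    frames = list(frames)
    lags, msds, ns = [], [], []
    max_lag = frames[-1] - frames[0]
    for k in range(1, max_lag + 1):
        sq = []
        for a in range(len(frames)):
            for b in range(len(frames)):
                if frames[b] - frames[a] == k:
                    dx = xy[b][0] - xy[a][0]
                    dy = xy[b][1] - xy[a][1]
                    sq.append(dx * dx + dy * dy)
        if sq:
            lags.append(k * dt)
            msds.append(sum(sq) / len(sq))
            ns.append(len(sq))
    return np.array(lags), np.array(msds), np.array(ns)
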