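"""Independent brute-force oracles used by the test suite.

Everything here is written from the direct definitions (explicit scans and
enumerations), deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import datetime as dt

import numpy as np


def brute_force_peaks(v, height, prominence, distance):
    """Direct-definition peak caller on a gap-free sample sequence.

    Returns a list of ``(index, height, prominence)``: enumerate local
    maxima (leftmost sample of a flat maximal run, strictly smaller
    neighbors on both sides required), compute prominence by scanning to the
    nearest strictly higher sample (or boundary), filter by height and
    prominence, then greedily prune by descending height (ties by ascending
    index), discarding candidates closer than ``distance`` to a kept peak.
    """
    v = list(map(float, v))
    n = len(v)
    maxima = []
    for i in range(1, n - 1):
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j + 1 < n and v[j + 1] < v[i]:
                maxima.append(i)
    candidates = []
    for p in maxima:
        x = v[p]
        if x < height:
            continue
        left_min = x
        k = p - 1
        while k >= 0 and v[k] <= x:
            left_min = min(left_min, v[k])
            k -= 1
        right_min = x
        k = p + 1
        while k < n and v[k] <= x:
            right_min = min(right_min, v[k])
            k += 1
        prom = x - max(left_min, right_min)
        if prom < prominence:
            continue
        candidates.append((p, x, prom))
    order = sorted(candidates, key=lambda t: (-t[1], t[0]))
    kept = []
    for p, x, prom in order:
        if all(abs(p - q) >= distance for q, _, _ in kept):
            kept.append((p, x, prom))
    kept.sort()
    return kept


def brute_force_smooth(values, present, half):
    """Shrinking-window centered mean on a minute grid.

    ``values``/``present`` are aligned to the full grid (absent minutes have
    ``present`` False); returns smoothed values at present minutes only.
    """
    n = len(values)
    out = []
    for i in range(n):
        if not present[i]:
            continue
        h = min(half, i, n - 1 - i)
        window = [values[j] for j in range(i - h, i + h + 1) if present[j]]
        out.append(sum(window) / len(window))
    return out


def brute_force_resting_mask(step_values, lookback):
    """Direct windowed scan of the zero-step rule on a minute grid.

    ``step_values`` is aligned to the grid with ``None`` for absent minutes.
    """
    n = len(step_values)
    window = max(lookback, 1)
    mask = []
    for m in range(n):
        if step_values[m] is None or step_values[m] != 0:
            mask.append(False)
            continue
        ok = True
        for j in range(max(0, m - window + 1), m + 1):
            if step_values[j] is not None and step_values[j] > 0:
                ok = False
                break
        mask.append(ok)
    return mask


def mann_whitney_auc(pos_scores, neg_scores):
    """AUC as the normalized rank-sum statistic U / (n1 * n2)."""
    u = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos_scores) * len(neg_scores))


def brute_force_travel_exclusion(dates, travel_days):
    """Per-date enumeration of the travel + 2 following days rule."""
    out = set()
    for d in dates:
        hit = False
        for t in travel_days:
            if t <= d <= t + dt.timedelta(days=2):
                hit = True
                break
        if not hit:
            out.add(d)
    return out
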