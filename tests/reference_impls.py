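"""Independent brute-force re-implementations used as oracles in tests.

These deliberately avoid the package's code paths: plain Python loops and
two-pass summations, replaying only the documented contracts (FIFO
frontier, N..NW neighbor order, running mean updated after admission).
"""

from __future__ import annotations

import math

OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def flood_fill_grow(window, seed, xi, adaptive=True):
    """List-based replay of the adaptive growth rule; returns a set of (r, c)."""
    h = len(window)
    w = len(window[0])
    m = sum(sum(row) for row in window) / (h * w)
    var = sum(sum((v - m) ** 2 for v in row) for row in window) / (h * w)
    threshold = xi * math.sqrt(var)
    sr, sc = seed
    members = [(sr, sc)]
    member_sum = window[sr][sc]
    seen = {(sr, sc)}
    queue = [(sr, sc)]
    head = 0
    while head < len(queue):
        r, c = queue[head]
        head += 1
        for dr, dc in OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or (rr, cc) in seen:
                continue
            seen.add((rr, cc))
            mean = member_sum / len(members) if adaptive else window[sr][sc]
            if abs(window[rr][cc] - mean) <= threshold:
                members.append((rr, cc))
                member_sum += window[rr][cc]
                queue.append((rr, cc))
    return set(members)


def two_pass_stats(values):
    """Population mean and standard deviation by direct summation."""
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


def weighted_region_stats(image, phi, epsilon):
    """Direct-summation Heaviside-weighted moments (loops, no numpy)."""
    h = len(image)
    w = len(image[0])
    out = []
    for region in (1, 2):
        sw = si = 0.0
        for r in range(h):
            for c in range(w):
                m = 0.5 * (1 + (2 / math.pi) * math.atan(phi[r][c] / epsilon))
                if region == 2:
                    m = 1.0 - m
                sw += m
                si += m * image[r][c]
        u = si / sw
        sv = 0.0
        for r in range(h):
            for c in range(w):
                m = 0.5 * (1 + (2 / math.pi) * math.atan(phi[r][c] / epsilon))
                if region == 2:
                    m = 1.0 - m
                sv += m * (image[r][c] - u) ** 2
        out.append((u, sv / sw))
    return out  # [(u1, var1), (u2, var2)]
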