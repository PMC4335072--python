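"""Naive reference implementation used to cross-check the engine.

Everything here is deliberately written with plain Python loops, dicts and
math-module scalars — no numpy, no shared code with the package beyond the
rule definitions themselves.  Because both sides compute per-cell sums with
math.fsum over identical addends, agreement is expected bit-for-bit.
"""

import math

NEIGH = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]


def kern(family, n, d2):
    d = math.sqrt(d2)
    if family == "polynomial":
        return d ** (-n)
    return math.exp(-n * d)


def field_at(sources, p, family, n):
    return math.fsum(
        kern(family, n, (x - p[0]) ** 2 + (y - p[1]) ** 2)
        for (x, y) in sources
        if (x, y) != p
    )


def naive_run(
    nodes,
    removed,
    family="polynomial",
    n=2.0,
    rule="3b",
    eps=1e-14,
    enforce=True,
    inherit=True,
    margin=5,
    max_steps=500,
    stop=1e-9,
):
    """Step-by-step greedy regeneration; returns (status, placements)."""
    nodes = set(nodes)
    removed = set(removed)
    control = nodes - removed
    blastema = {
        c for c in control if any((c[0] + dx, c[1] + dy) in removed for dx, dy in NEIGH)
    }
    xs = [p[0] for p in nodes]
    ys = [p[1] for p in nodes]
    window = (min(xs) - margin, min(ys) - margin, max(xs) + margin, max(ys) + margin)

    u_star = {p: field_at(nodes, p, family, n) for p in control}
    placements = []
    new = []
    while True:
        occupied = control | set(new)
        measured = dict(u_star)
        if inherit:
            for p in new:
                measured[p] = field_at(nodes, p, family, n)
        u = {p: field_at(occupied, p, family, n) for p in measured}
        if any((u[p] - measured[p]) / measured[p] >= eps for p in measured):
            return "violation", placements
        if max((measured[p] - u[p]) / measured[p] for p in measured) <= stop:
            return "exact", placements
        if len(placements) >= max_steps:
            return "step_limit", placements

        candidates = set()
        for s in blastema | set(new):
            for dx, dy in NEIGH:
                p = (s[0] + dx, s[1] + dy)
                if p in occupied:
                    continue
                if window[0] <= p[0] <= window[2] and window[1] <= p[1] <= window[3]:
                    candidates.add(p)
        best = None
        best_score = -math.inf
        for c in sorted(candidates, key=lambda p: (p[1], p[0])):
            contrib = {
                p: kern(family, n, (p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2)
                for p in measured
            }
            if enforce and any(
                (u[p] + contrib[p] - measured[p]) / measured[p] >= eps for p in measured
            ):
                continue
            if rule == "3a":
                score = math.fsum(contrib.values())
            else:
                score = math.fsum(contrib[p] * (measured[p] - u[p]) for p in measured)
            if score > best_score:
                best, best_score = c, score
        if best is None:
            return "stalled", placements
        new.append(best)
        placements.append(best)
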