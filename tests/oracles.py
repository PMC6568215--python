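"""Independent brute-force oracles used by the test suite.

These deliberately re-implement contracts as literal per-frame loops with no
shared code with the package, so they can cross-check the vectorized paths.
"""

import math

from clockmaze.arena import ZoneKind, trial_zones


def inspection_oracle(track, arena, true_exit, debounce_s=0.1, rearm_factor=1.5):
    """Literal per-frame point-in-circle + state-machine event detector.

    Returns (zone_name, t_on, t_off, is_true_exit) tuples sorted by onset.
    """
    events = []
    t = track.t
    n = len(t)
    for zone in trial_zones(arena, true_exit):
        cx, cy = zone.geometry.center
        r = zone.geometry.radius
        rd = r * rearm_factor
        state = "idle"
        entry = None
        t_on = None
        for i in range(n):
            d = math.hypot(track.nose[i][0] - cx, track.nose[i][1] - cy)
            inside = d <= r
            inside_dil = d <= rd
            if state == "idle":
                if inside:
                    state = "pending"
                    entry = i
            elif state == "pending":
                if inside:
                    if t[i] - t[entry] >= debounce_s:
                        state = "open"
                        t_on = t[entry]
                else:
                    state = "idle"
            elif state == "open":
                if not inside_dil:
                    events.append(
                        (zone.name, float(t_on), float(t[i - 1]),
                         zone.kind is ZoneKind.EXIT)
                    )
                    state = "idle"
        if state == "open":
            events.append(
                (zone.name, float(t_on), float(t[n - 1]), zone.kind is ZoneKind.EXIT)
            )
    events.sort(key=lambda e: (e[1], e[0]))
    return events


def midrank_oracle(values):
    """Hand-rolled average ranks (1-based) with ties sharing the mid-rank."""
    n = len(values)
    ranks = [0.0] * n
    for i, v in enumerate(values):
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        # ranks occupied: smaller+1 .. smaller+equal; average them
        ranks[i] = smaller + (equal + 1) / 2.0
    return ranks


def spearman_oracle(x, y):
    rx = midrank_oracle(list(x))
    ry = midrank_oracle(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)
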