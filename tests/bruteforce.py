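"""Brute-force reference miner used as an independent oracle in tests.

Implements the sliding-window collection and tolerance clustering contract
directly with plain Python lists and explicit loops -- no signature
bucketing, no early exits -- so the fast miner can be checked for set
equality against it on small datasets.
"""

import numpy as np


def bf_mine(data, window, match_tolerance, min_units, min_occurrences):
    """Return [(elements, [(anchor, duration, rel_times)])] like the miner.

    elements: tuple of (unit, rel_time) sorted by (time, unit);
    occurrences are the accepted (non-overlapping) ones with repeat order.
    """
    ev = list(zip(data.events["time"].tolist(), data.events["unit"].tolist()))
    n = len(ev)
    candidates = []  # (anchor, [(unit, rel_time) ...]) in time order
    for i in range(n):
        t0 = ev[i][0]
        win = [(u, t - t0) for (t, u) in ev[i:] if t < t0 + window]
        if len({u for u, _ in win}) < min_units:
            continue
        candidates.append((t0, win))

    templates = []  # canonical per-unit time-ordered (units, times)
    occs = []  # per template: list of (anchor, duration, residual)

    def canon(win):
        pairs = sorted(win, key=lambda x: (x[0], x[1]))  # by unit, then time
        units = tuple(u for u, _ in pairs)
        times = [rt for _, rt in pairs]
        return units, times

    for anchor, win in candidates:
        units, times = canon(win)
        duration = max(rt for _, rt in win)
        best = None
        best_res = None
        for tid, (tu, tt) in enumerate(templates):
            if tu != units:
                continue
            d = [a - b for a, b in zip(times, tt)]
            res = (max(d) - min(d)) / 2.0
            if res <= match_tolerance and (best_res is None or res < best_res):
                best = tid
                best_res = res
        if best is None:
            templates.append((units, times))
            occs.append([(anchor, duration, 0.0)])
        else:
            occs[best].append((anchor, duration, best_res))

    out = []
    for tid, (tu, tt) in enumerate(templates):
        occ = sorted(occs[tid], key=lambda o: (o[0], o[2]))
        accepted = []
        last_end = -np.inf
        for anchor, duration, res in occ:
            if anchor > last_end:
                accepted.append((anchor, duration))
                last_end = anchor + max(duration, 0.0)
        if len(accepted) >= min_occurrences:
            elements = tuple(
                sorted(
                    ((u, rt) for u, rt in zip(tu, tt)),
                    key=lambda x: (x[1], x[0]),
                )
            )
            out.append((elements, accepted))
    return out
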