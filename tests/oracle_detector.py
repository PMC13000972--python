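"""Independent brute-force windfleck detector used as a test oracle.

Deliberately naive: extrema are enumerated by explicit scanning of the raw
value runs, and after every removal the full list of adjacent pairs is
re-scanned for the smallest sub-threshold pair.  Shares no code with the
package implementation.
"""

from __future__ import annotations


def _runs(values):
    runs = []
    i = 0
    n = len(values)
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        runs.append((i, j, values[i]))
        i = j + 1
    return runs


def _extrema(values):
    runs = _runs(values)
    if len(runs) < 2:
        return []
    ext = []
    last = len(runs) - 1
    for k, (first, lastidx, val) in enumerate(runs):
        if k == 0:
            kind = "min" if runs[1][2] > val else "max"
        elif k == last:
            kind = "min" if runs[k - 1][2] > val else "max"
        else:
            before, after = runs[k - 1][2], runs[k + 1][2]
            if before < val and after < val:
                kind = "max"
            elif before > val and after > val:
                kind = "min"
            else:
                kind = None
        if kind is not None:
            ext.append([kind, first, lastidx, val])
    return ext


def brute_force_events(values, rel_threshold=0.05, abs_threshold=5.0):
    """Return (start_idx, peak_idx, end_idx) triples after smallest-first
    pruning of sub-threshold adjacent extremum pairs."""
    values = list(values)
    ext = _extrema(values)
    while True:
        worst = None
        for i in range(len(ext) - 1):
            amp = abs(ext[i + 1][3] - ext[i][3])
            base = min(ext[i][3], ext[i + 1][3])
            if amp < abs_threshold or amp < rel_threshold * base:
                if worst is None or amp < worst[0]:
                    worst = (amp, i)
        if worst is None:
            break
        i = worst[1]
        del ext[i: i + 2]
    events = []
    for i in range(len(ext) - 2):
        if ext[i][0] == "min" and ext[i + 1][0] == "max" and ext[i + 2][0] == "min":
            events.append((ext[i][2], ext[i + 1][1], ext[i + 2][1]))
    return events
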