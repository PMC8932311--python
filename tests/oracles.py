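"""Independent brute-force reference implementations.

Plain-Python, character-by-character reimplementations of every operator's
definition, used to cross-check the vectorised package code.  Deliberately
slow and simple; they never import the implementation under test.
"""

import math
from collections import Counter

GAP = "-"


def span(seq: str):
    pos = [i for i, c in enumerate(seq) if c != GAP]
    if not pos:
        return None
    return pos[0], pos[-1], len(pos)


def consensus(rows):
    out = []
    for j in range(len(rows[0])):
        counts = Counter(r[j] for r in rows if r[j] != GAP)
        if not counts:
            out.append(GAP)
            continue
        best = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == best))
    return "".join(out)


def consensus_with_gaps(rows):
    """Majority mode: gaps count but lose frequency ties to residues."""
    out = []
    for j in range(len(rows[0])):
        counts = Counter(r[j] for r in rows)
        best = max(counts.values())
        tied = sorted(c for c, n in counts.items() if n == best)
        residues = [c for c in tied if c != GAP]
        out.append(residues[0] if residues else GAP)
    return "".join(out)


def divergent_removed(names, rows, min_identity):
    cons = consensus(rows)
    removed = []
    for name, row in zip(names, rows):
        nongap = [j for j, c in enumerate(row) if c != GAP]
        if not nongap:
            removed.append(name)
            continue
        matches = sum(1 for j in nongap if row[j] == cons[j])
        if matches / len(nongap) < min_identity:
            removed.append(name)
    return removed


def insertion_runs(rows, min_size, max_size, min_flank):
    n_cols = len(rows[0])
    spans_ = [span(r) for r in rows]

    def covering(j):
        return [i for i, s in enumerate(spans_) if s and s[0] <= j <= s[1]]

    candidate = []
    for j in range(n_cols):
        cov = covering(j)
        gapped = [i for i in cov if rows[i][j] == GAP]
        candidate.append(bool(cov) and 2 * len(gapped) > len(cov))

    runs, j = [], 0
    while j < n_cols:
        if candidate[j]:
            k = j
            while k < n_cols and candidate[k]:
                k += 1
            runs.append((j, k))
            j = k
        else:
            j += 1

    out = []
    for s, e in runs:
        width = e - s
        if not (min_size <= width <= max_size):
            continue
        if s - min_flank < 0 or e + min_flank > n_cols:
            continue
        cov = [i for i, sp in enumerate(spans_) if sp and sp[0] <= s and sp[1] >= e - 1]
        if not cov:
            continue
        ok = 0
        for i in cov:
            if any(rows[i][j] != GAP for j in range(s, e)):
                continue
            left = sum(1 for j in range(s - min_flank, s) if rows[i][j] != GAP)
            right = sum(1 for j in range(e, e + min_flank) if rows[i][j] != GAP)
            if left >= min_flank and right >= min_flank:
                ok += 1
        if 2 * ok > len(cov):
            out.append((s, e))
    return out


def crop_start(seq, mingap_prop=0.05, redefine_prop=0.1):
    pos = [i for i, c in enumerate(seq) if c != GAP]
    if not pos:
        return 0
    L = len(pos)
    w = min(math.floor(redefine_prop * L), L)
    if w < 1:
        return pos[0]
    t = max(1, math.floor(mingap_prop * L))
    d = [pos[0]] + [pos[i] - pos[i - 1] - 1 for i in range(1, w)]
    best = None
    for i in range(w):
        if d[i] >= t:
            best = i
    return pos[best] if best is not None else pos[0]


def crop_end(seq, mingap_prop=0.05, redefine_prop=0.1):
    return len(seq) - 1 - crop_start(seq[::-1], mingap_prop, redefine_prop)


def short_removed(names, rows, min_length):
    return [
        n for n, r in zip(names, rows)
        if sum(1 for c in r if c != GAP) < min_length
    ]


def gaponly_cols(rows):
    return [
        j for j in range(len(rows[0])) if all(r[j] == GAP for r in rows)
    ]


def coverage(rows):
    return [
        sum(1 for r in rows if r[j] != GAP) / len(rows)
        for j in range(len(rows[0]))
    ]


def similarity(rows):
    n = len(rows)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            both = [
                k for k in range(len(rows[i]))
                if rows[i][k] != GAP and rows[j][k] != GAP
            ]
            if both:
                out[i][j] = sum(1 for k in both if rows[i][k] == rows[j][k]) / len(both)
    return out
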