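"""Independent oracles used by the test suite.

These deliberately avoid the package's alignment/forensics code paths:
a full-matrix Gotoh affine-gap DP with explicit traceback, a brute-force
filler decomposition, a quadratic tandem-period scan, and a linear
divergence scan.  They are written for clarity at small problem sizes.
"""

from __future__ import annotations

import numpy as np

NEG = -10 ** 9

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def gotoh_catalog(a: str, b: str, match: int = 1, mismatch: int = -2,
                  gap_open: int = 4, gap_extend: int = 1) -> dict:
    """Exact affine-gap global alignment (gap of length k costs open + k*ext).

    Returns score plus the SNP/indel/identity catalog of one optimal
    traceback: n_snps (mismatch columns), n_indels (maximal gap runs),
    consensus_length (alignment columns) and identity_pct.
    """
    n, m = len(a), len(b)
    first = -(gap_open + gap_extend)
    ext = -gap_extend
    av = np.frombuffer(a.encode(), np.uint8)
    bv = np.frombuffer(b.encode(), np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch).astype(np.int32)

    M = np.full((n + 1, m + 1), NEG, np.int32)
    Ix = np.full((n + 1, m + 1), NEG, np.int32)  # gap in b (A advances)
    Iy = np.full((n + 1, m + 1), NEG, np.int32)  # gap in a (B advances)
    M[0, 0] = 0
    for j in range(1, m + 1):
        Iy[0, j] = first + ext * (j - 1)
    for i in range(1, n + 1):
        Ix[i, 0] = first + ext * (i - 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + first,
            Ix[i - 1, 1:] + ext,
        )
        # Iy[i, j] = max(M[i, j-1] + first, Ix[i, j-1] + first, Iy[i, j-1] + ext)
        #          = running_max over k < j of (mi[k] - k*|ext|) ... via accumulate
        mi = np.maximum(M[i, :-1], Ix[i, :-1]).astype(np.int64)
        j_idx = np.arange(m)
        t = np.maximum.accumulate(mi + first - ext * (j_idx + 1))
        Iy[i, 1:] = t + ext * (j_idx + 1)
        # boundary column j=0 already set; recompute exact Iy sequentially is
        # avoided: the accumulate above is exact because ext is the per-column
        # decay and first the opening charge.

    score = int(max(M[n, m], Ix[n, m], Iy[n, m]))

    # traceback (prefer M, then Ix, then Iy on ties)
    i, j = n, m
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    cols = []                   # 'M' match col, 'X' a-gap col?, per-column ops
    while i > 0 or j > 0:
        if state == 0:
            cols.append(("M", a[i - 1], b[j - 1]))
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append(("D", a[i - 1], "-"))
            if i == 1 and j == 0:
                i = 0
                continue
            opts = [M[i - 1, j] + first, Ix[i - 1, j] + ext, Iy[i - 1, j] + first]
            state = int(np.argmax(opts))
            i -= 1
        else:
            cols.append(("I", "-", b[j - 1]))
            if j == 1 and i == 0:
                j = 0
                continue
            opts = [M[i, j - 1] + first, Ix[i, j - 1] + first, Iy[i, j - 1] + ext]
            state = int(np.argmax(opts))
            j -= 1
    cols.reverse()

    n_match = sum(1 for op, x, y in cols if op == "M" and x == y)
    n_snps = sum(1 for op, x, y in cols if op == "M" and x != y)
    n_indels = 0
    indel_lengths = []
    prev_op = "M"
    run = 0
    for op, _, _ in cols + [("M", "", "")]:
        if op == prev_op and op in "DI":
            run += 1
        else:
            if prev_op in "DI" and run:
                n_indels += 1
                indel_lengths.append(run)
            run = 1 if op in "DI" else 0
        prev_op = op
    consensus = len(cols)
    return {
        "score": score,
        "n_snps": n_snps,
        "n_indels": n_indels,
        "indel_lengths": tuple(indel_lengths),
        "consensus_length": consensus,
        "identity_pct": 100.0 * n_match / consensus,
    }


def brute_force_filler(ins: str, up_win: str, down_win: str,
                       min_frag: int = 4) -> list:
    """Greedy maximal-prefix filler decomposition by exhaustive search.

    At each position, every substring length (longest first) and every donor
    placement in both windows and strands is enumerated; ties resolved as
    nearest occurrence, downstream before upstream, + before -.
    """
    out = []
    i = 0
    while i < len(ins):
        placed = False
        for length in range(len(ins) - i, min_frag - 1, -1):
            frag = ins[i:i + length]
            hits = []
            for strand, needle in (("+", frag), ("-", rc(frag))):
                for p in range(len(down_win) - length + 1):
                    if down_win[p:p + length] == needle and "N" not in needle:
                        hits.append((p, "downstream", strand))
                for p in range(len(up_win) - length + 1):
                    if up_win[p:p + length] == needle and "N" not in needle:
                        hits.append(
                            (len(up_win) - (p + length), "upstream", strand)
                        )
            if hits:
                hits.sort(key=lambda h: (h[0], h[1] != "downstream", h[2] != "+"))
                out.append((i, frag, *hits[0]))
                i += length
                placed = True
                break
        if not placed:
            i += 1
    return out


def brute_force_periods(s: str, min_period: int, min_identity: float,
                        min_core: int = 16, max_gap: int = 50) -> set:
    """Quadratic scan for tandem-array periods (same run semantics,
    no k-mer candidate shortcut): returns the set of detected periods."""
    found = set()
    n = len(s)
    for p in range(min_period, n // 2 + 1):
        matches = [s[i] == s[i + p] and s[i] != "N" for i in range(n - p)]
        # exact runs >= min_core, bridged up to max_gap
        runs = []
        i = 0
        while i < len(matches):
            if matches[i]:
                j = i
                while j < len(matches) and matches[j]:
                    j += 1
                if j - i >= min_core:
                    if runs and i - runs[-1][1] <= max_gap:
                        runs[-1][1] = j
                    else:
                        runs.append([i, j])
                i = j
            else:
                i += 1
        for start, end in runs:
            length = end - start
            ident = 100.0 * sum(matches[start:end]) / length
            if length >= p - 32 and ident >= min_identity:
                found.add(p)
    return found


def linear_divergence_scan(a: str, b: str, anchor_a: int, anchor_b: int,
                           direction: str) -> tuple:
    """Character-by-character scan for the first divergence point."""
    step = 1 if direction == "right" else -1
    i, j, ctx = anchor_a, anchor_b, 0
    while 0 <= i < len(a) and 0 <= j < len(b) and a[i] == b[j]:
        i += step
        j += step
        ctx += 1
    return i, j, ctx
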