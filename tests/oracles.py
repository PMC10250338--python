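"""Independent brute-force oracles used to validate the package.

These are deliberately naive implementations (full-matrix dynamic
programming, per-start enumeration, exhaustive label assignment) kept
separate from the production code paths they check.
"""

from __future__ import annotations

import itertools

NEG = -(10**9)


def sw_oracle(a, b, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Full Smith-Waterman/Gotoh with affine gaps, plain Python matrices.

    Returns (score, q_start, q_end, r_start, r_end, matches, columns) of the
    best local alignment, using diag > gap-in-a > gap-in-b tie priority and
    the first-encountered maximum cell; returns None for score 0.
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    PH = [[0] * (m + 1) for _ in range(n + 1)]
    PE = [[0] * (m + 1) for _ in range(n + 1)]
    PF = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            e_open = H[i][j - 1] + gap_open + gap_extend
            e_ext = E[i][j - 1] + gap_extend
            if e_open >= e_ext:
                E[i][j], PE[i][j] = e_open, 1
            else:
                E[i][j], PE[i][j] = e_ext, 0
            f_open = H[i - 1][j] + gap_open + gap_extend
            f_ext = F[i - 1][j] + gap_extend
            if f_open >= f_ext:
                F[i][j], PF[i][j] = f_open, 1
            else:
                F[i][j], PF[i][j] = f_ext, 0
            h, p = 0, 0
            d = H[i - 1][j - 1] + s
            if d > h:
                h, p = d, 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            H[i][j], PH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    i, j, matches, columns, state = bi, bj, 0, 0, 0
    while True:
        if state == 0:
            p = PH[i][j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            columns += 1
            opened = PE[i][j]
            j -= 1
            if opened:
                state = 0
        else:
            columns += 1
            opened = PF[i][j]
            i -= 1
            if opened:
                state = 0
    return best, i, bi, j, bj, matches, columns


def tandem_oracle(s, max_unit, min_copies=2.0):
    """Enumerate all maximal (period, phase) tandem arrays, primitive units.

    Returns a sorted list of (unit_seq, copies, (start, end)) matching the
    production detector's definition.
    """
    n = len(s)
    out = []
    for p in range(1, min(max_unit, n // 2) + 1):
        for i in range(n - p):
            if s[i] != s[i + p]:
                continue
            if i > 0 and s[i - 1] == s[i - 1 + p]:
                continue  # not a run start
            j = i
            while j < n - p and s[j] == s[j + p]:
                j += 1
            start, end = i, j + p
            copies = (end - start) / p
            if copies < min_copies:
                continue
            sub = s[start:end]
            primitive = True
            for q in range(1, p):
                if all(sub[x] == sub[x + q] for x in range(len(sub) - q)):
                    primitive = False
                    break
            if primitive:
                out.append((s[start : start + p], copies, (start, end)))
    return sorted(out, key=lambda t: (t[2], len(t[0])))


def ranksum_exact_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating every label assignment.

    The U statistic is computed directly by pair counting (ties count 1/2),
    with the two-sided p the fraction of assignments at least as far from
    the null mean as observed.
    """
    na, nb = len(a), len(b)
    pooled = list(a) + list(b)

    def u_stat(group_a_idx):
        in_a = set(group_a_idx)
        ga = [pooled[i] for i in group_a_idx]
        gb = [pooled[i] for i in range(na + nb) if i not in in_a]
        u = 0.0
        for x in ga:
            for y in gb:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(range(na))
    mean_u = na * nb / 2.0
    dev = abs(u_obs - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(na + nb), na):
        if abs(u_stat(combo) - mean_u) >= dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def levenshtein(a, b):
    """Plain O(nm) edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def least_rotation_oracle(s):
    """Smallest rotation by explicit enumeration."""
    return min(s[i:] + s[:i] for i in range(len(s)))
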