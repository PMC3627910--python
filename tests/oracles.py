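"""Independent brute-force oracles used to cross-check the detectors.

Each oracle re-derives the operation's result by naive enumeration against
the operation's declared semantics; none of them shares code with the package
implementations they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _pairs(a: str, b: str) -> bool:
    return a != "N" and _COMP[a] == b


# ---------------------------------------------------------------- motif scan


def motif_hits_oracle(s: str, spec) -> list[tuple[int, ...]]:
    """All anchor 9-tuples satisfying the signature, by nested position loops."""
    n = len(s)
    ds = [i for i, ch in enumerate(s) if ch == "D"]
    ts = [i for i, ch in enumerate(s) if ch in "TS"]
    cs = [i for i, ch in enumerate(s) if ch == "C"]
    rs = [i for i, ch in enumerate(s) if ch == "R"]
    hits = []
    for i in ds:
        for j in ts:
            if not (spec.d_ts_min <= j - i - 1 <= spec.d_ts_max):
                continue
            if j + 1 >= n or s[j + 1] not in "TS":
                continue
            for c1 in cs:
                if c1 - (j + 1) - 1 != spec.post_ts_gap:
                    continue
                for c2 in cs:
                    if not (spec.zf_gap12_min <= c2 - c1 - 1 <= spec.zf_gap12_max):
                        continue
                    for c3 in cs:
                        if not (spec.zf_gap23_min <= c3 - c2 - 1 <= spec.zf_gap23_max):
                            continue
                        for c4 in cs:
                            if not (spec.zf_gap34_min <= c4 - c3 - 1 <= spec.zf_gap34_max):
                                continue
                            for r in rs:
                                if not (spec.zf_rd_min <= r - c4 - 1 <= spec.zf_rd_max):
                                    continue
                                if r + 1 < n and s[r + 1] == "D":
                                    hits.append((i, j, j + 1, c1, c2, c3, c4, r, r + 1))
    return sorted(hits)


# ----------------------------------------------------------------- TIR search


def tir_oracle(s: str, min_len: int, max_offset: int, max_mismatch_frac: float):
    """Best terminal inverted repeat by exhaustive all-pairs arm comparison.

    Returns (arm_len, mismatches, left_offset, right_offset) or None. Arms
    must begin and end with complementary pairs (mismatches internal only).
    """
    n = len(s)
    candidates = []
    for i in range(max_offset + 1):
        for j in range(max_offset + 1):
            for L in range(min_len, n + 1):
                if i + L > n - j - L:
                    break
                left = s[i : i + L]
                right_rc = rc(s[n - j - L : n - j])
                mm = sum(1 for x, y in zip(left, right_rc) if x != y)
                if left[0] != right_rc[0] or left[-1] != right_rc[-1]:
                    continue
                if mm <= int(L * max_mismatch_frac):
                    candidates.append((-L, mm, i, j))
    if not candidates:
        return None
    L, mm, i, j = min(candidates)
    return (-L, mm, i, j)


# -------------------------------------------------------------- hairpin search


def hairpin_oracle(
    s: str,
    ws: int,
    we: int,
    stem_min: int,
    loop_min: int,
    loop_max: int,
    max_mismatches: int,
) -> list[tuple[int, int, int, int]]:
    """All maximal stem-loops as (stem_left_start, stem_len, loop_len, mismatches).

    Enumerates every (start, stem, loop) triple, keeps those whose stems begin
    and end with complementary pairs within the mismatch budget, then drops
    any hairpin whose stem arms are nested inside another's.
    """
    cands = []
    for start in range(ws, we):
        for k in range(stem_min, (we - ws) // 2 + 1):
            for g in range(loop_min, loop_max + 1):
                end = start + 2 * k + g
                if end > we:
                    continue
                left = s[start : start + k]
                right = s[start + k + g : end]
                rr = rc(right)
                mm = sum(1 for x, y in zip(left, rr) if x != y)
                if left[0] != rr[0] or left[-1] != rr[-1] or mm > max_mismatches:
                    continue
                cands.append((start, k, g, mm))
    keep = []
    for c in cands:
        s1, k1, g1, _ = c
        contained = any(
            o is not c
            and s1 >= o[0]
            and s1 + k1 <= o[0] + o[1]
            and s1 + k1 + g1 >= o[0] + o[1] + o[2]
            and s1 + 2 * k1 + g1 <= o[0] + 2 * o[1] + o[2]
            for o in cands
        )
        if not contained:
            keep.append(c)
    return sorted(keep)


# ----------------------------------------------------------------- TSD calling


def tsd_oracle(lf: str, rf: str, min_len: int, max_len: int, slack: int):
    """Best (tsd_len, left_slack, right_slack, tsd_seq) over all combinations,
    or None when no exact duplication of length >= min_len qualifies."""
    best = None
    for a in range(slack + 1):
        for b in range(slack + 1):
            for L in range(min_len, max_len + 1):
                if a + L > len(lf) or b + L > len(rf):
                    continue
                left_word = lf[len(lf) - a - L : len(lf) - a]
                right_word = rf[b : b + L]
                if left_word == right_word:
                    key = (-L, a + b, a, b)
                    if best is None or key < best:
                        best = key
    if best is None:
        return None
    L, a, b = -best[0], best[2], best[3]
    return (L, a, b, rf[b : b + L])


# ------------------------------------------------------- global alignment score


def align_score_oracle(
    a: str,
    b: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
    end_gaps_free: bool = True,
) -> float:
    """Optimal affine-gap global alignment score by an independent Gotoh DP.

    A gap of length k costs gap_open + k * gap_extend; with end_gaps_free,
    leading and trailing gaps in either sequence cost nothing.
    """
    NEG = float("-inf")
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]  # a_i aligned to b_j
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # a_i aligned to gap
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # b_j aligned to gap
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = 0.0 if end_gaps_free else gap_open + i * gap_extend
    for j in range(1, n + 1):
        Y[0][j] = 0.0 if end_gaps_free else gap_open + j * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + gap_open + gap_extend,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open + gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open + gap_extend,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open + gap_extend,
            )
    if not end_gaps_free:
        return max(M[m][n], X[m][n], Y[m][n])
    best = NEG
    for i in range(m + 1):
        best = max(best, M[i][n], X[i][n], Y[i][n])
    for j in range(n + 1):
        best = max(best, M[m][j], X[m][j], Y[m][j])
    return best
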