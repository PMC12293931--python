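"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (full-matrix dynamic
programming, exhaustive window scans, closed forms, hypergeometric
enumeration) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

COMPL = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}


def rc(seq: str) -> str:
    return "".join(COMPL[c] for c in reversed(seq))


def ora_edit_distance(a: str, b: str) -> int:
    """Textbook full-matrix Levenshtein DP."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[m]


def ora_align_score(a, b, match=1.0, mismatch=0.0, gap_open=0.0, gap_extend=0.0,
                    mode="global"):
    """Full-matrix Gotoh (affine-gap) optimal alignment score.

    gap_open is the score of a gap of length 1; each extra position adds
    gap_extend (matching the open/extend convention of common aligners).
    """
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    local_best = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = match if a[i - 1] == b[j - 1] else mismatch
                base = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if mode == "local":
                    base = max(base, 0.0)
                M[i][j] = base + s
            if i > 0:
                X[i][j] = max(X[i][j],
                              max(M[i - 1][j], Y[i - 1][j]) + gap_open,
                              X[i - 1][j] + gap_extend)
            if j > 0:
                Y[i][j] = max(Y[i][j],
                              max(M[i][j - 1], X[i][j - 1]) + gap_open,
                              Y[i][j - 1] + gap_extend)
            if mode == "local":
                local_best = max(local_best, M[i][j])
    if mode == "local":
        return local_best
    return max(M[n][m], X[n][m], Y[n][m])


def ora_pam_match(pattern: str, pam: str) -> bool:
    return len(pam) == len(pattern) and all(
        c in IUPAC_SETS[p] for p, c in zip(pattern, pam))


def ora_scan(seq: str, pam_pattern: str = "NGG"):
    """Every 20-mer window with an adjacent PAM, testing each position and
    strand independently of the package's scanner."""
    hits = []
    for p in range(len(seq)):
        window = seq[p : p + 20]
        if len(window) < 20:
            continue
        pam_fwd = seq[p + 20 : p + 23]
        if len(pam_fwd) == 3 and ora_pam_match(pam_pattern, pam_fwd):
            hits.append((p, "+", window, pam_fwd))
        if p >= 3:
            pam_rev = rc(seq[p - 3 : p])
            if ora_pam_match(pam_pattern, pam_rev):
                hits.append((p, "-", rc(window), pam_rev))
    return sorted(hits)


def ora_enumerate(members, min_score, max_ed, pam_pattern="NGG", **score_kw):
    """Naive L(i,j): members is a list of (name, amplicon_seq, guide_seq)."""
    lists = {}
    for name_i, _seq_i, guide_i in members:
        for name_j, seq_j, _guide_j in members:
            if name_j == name_i:
                continue
            kept = []
            for pos, strand, proto, pam in ora_scan(seq_j, pam_pattern):
                score = ora_align_score(proto, guide_i, **score_kw)
                ed = ora_edit_distance(proto, guide_i)
                if score >= min_score and ed <= max_ed:
                    kept.append((pos, strand, proto, pam, score, ed))
            lists[(name_i, name_j)] = sorted(kept)
    return lists


def ora_wilson(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    """Closed-form Wilson score interval."""
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    p = count / nobs
    denom = 1 + z * z / nobs
    centre = (p + z * z / (2 * nobs)) / denom
    half = z * math.sqrt(p * (1 - p) / nobs + z * z / (4 * nobs * nobs)) / denom
    return centre - half, centre + half


def ora_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact P(treatment >= observed) by hypergeometric
    enumeration over all tables with the same margins."""
    row1, col1, total = a + b, a + c, a + b + c + d

    def table_prob(x):
        return (math.comb(col1, x) * math.comb(total - col1, row1 - x)
                / math.comb(total, row1))

    return sum(table_prob(x) for x in range(a, min(row1, col1) + 1))
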