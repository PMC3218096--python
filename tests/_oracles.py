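"""Independent brute-force oracles used only by the tests."""

from __future__ import annotations


def sw_local_score(a: str, b: str, match: int = 2, mismatch: int = -3,
                   gap_open: int = -5, gap_extend: int = -2) -> float:
    """Plain O(n*m) Gotoh local alignment (affine gaps).

    A gap of length k scores ``gap_open + k * gap_extend``; independent of
    the package's aligner.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + first, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + first, F[i - 1][j] + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def window_identity(seq: str, i: int, j: int, window: int) -> float:
    """Fraction of matching bases between the windows starting at 0-based
    i and j (direct base-by-base comparison)."""
    wi, wj = seq[i:i + window], seq[j:j + window]
    return sum(x == y for x, y in zip(wi, wj)) / window
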