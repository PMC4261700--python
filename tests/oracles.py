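"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, quadratic DP) and
written against Biopython's translation table directly, so it shares no
code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import permutations, product

from Bio.Seq import Seq

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_site_count(codon: str) -> tuple[float, float]:
    """Per-codon (synonymous, nonsynonymous) sites by 9-mutant enumeration,
    excluding stop-creating mutants and rescaling each position to 1 site."""
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS:
                continue
            nonstop += 1
            if translate(mut) == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


def brute_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for a codon pair: average per-step synonymous/nonsynonymous
    labels over all orderings of the differing positions, dropping orderings
    that pass through a stop codon (keeping all if every one does)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    all_paths, clean_paths = [], []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
            steps.append(translate(cur) == translate(nxt) and nxt not in STOPS and cur not in STOPS)
            cur = nxt
        all_paths.append(steps)
        if not blocked:
            clean_paths.append(steps)
    paths = clean_paths or all_paths
    sd = sum(sum(p) for p in paths) / len(paths)
    return sd, len(diff) - sd


def sense_codons() -> list[str]:
    return ["".join(c) for c in product(BASES, repeat=3) if "".join(c) not in STOPS]


def gotoh_global_score(
    a: str, b: str, match: int = 2, mismatch: int = -3, gap_open: int = 5, gap_extend: int = 2
) -> float:
    """Quadratic-DP global alignment score with affine gaps; a length-L gap
    costs gap_open + gap_extend * L."""
    neg = float("-inf")
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - open_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - open_cost)
    return max(M[n][m], X[n][m], Y[n][m])
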