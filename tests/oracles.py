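"""Independent brute-force oracles used to check the implementation.

Deliberately written from first principles (recursion, explicit dynamic
programs, Biopython translation calls) rather than reusing any code path
from the package under test.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """'*' for stops."""
    return str(Seq(codon).translate(table=1))


def site_counts_oracle(codon: str) -> tuple[float, float]:
    """(S, N) by direct enumeration of the nine single-base mutants."""
    aa = translate_codon(codon)
    assert aa != "*"
    syn_fraction = 0.0
    for i in range(3):
        syn = sum(
            1
            for b in _BASES
            if b != codon[i] and translate_codon(codon[:i] + b + codon[i + 1 :]) == aa
        )
        syn_fraction += syn / 3.0
    return syn_fraction, 3.0 - syn_fraction


def path_diff_oracle(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over stop-free mutational paths, by recursion.

    All paths are enumerated recursively; paths visiting a stop codon are
    discarded unless every path is blocked, in which case all count.
    """
    def walk(current: str, remaining: tuple[int, ...], steps):
        if not remaining:
            yield steps, False
            return
        for idx, pos in enumerate(remaining):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            blocked = translate_codon(nxt) == "*"
            rest = remaining[:idx] + remaining[idx + 1 :]
            for tail, tail_blocked in walk(nxt, rest, steps + [(current, nxt)]):
                yield tail, blocked or tail_blocked

    diffs = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    if not diffs:
        return 0.0, 0.0
    all_paths = list(walk(codon_a, diffs, []))
    clean = [steps for steps, blocked in all_paths if not blocked]
    use = clean if clean else [steps for steps, _ in all_paths]
    syn = nonsyn = 0.0
    for steps in use:
        for frm, to in steps:
            if translate_codon(frm) == translate_codon(to):
                syn += 1
            else:
                nonsyn += 1
    return syn / len(use), nonsyn / len(use)


def local_align_score_oracle(
    a: str, b: str, matrix_name: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Smith-Waterman score with affine gaps (Gotoh), explicit O(nm) tables.

    A gap of length k costs gap_open + (k - 1) * gap_extend, matching the
    open_gap_score/extend_gap_score convention of the package aligner.
    """
    sub = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + sub[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
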