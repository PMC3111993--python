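"""Independent reference implementations used only by tests.

These deliberately share nothing with the package's dynamic program: the
frameshift oracle is a memoized forward recursion over explicit move
sequences, and the protein-level Smith-Waterman is a plain three-matrix
textbook implementation.  Both use the same published scoring convention
(first gap column = open, later columns = extend).
"""

from __future__ import annotations

from functools import lru_cache

from prokannot.core import codon_to_aa


def frameshift_oracle_score(query_nt: str, subject_aa: str, scoring) -> float:
    """Best local score by exhaustive (memoized) enumeration of alignments.

    Moves: aligned column consuming k in {1,2,3,4,5} query nt and one
    subject residue (k != 3 charged the frameshift penalty; full codons
    that are stops score the stop penalty), gap in query (one subject
    residue), gap in subject (one query codon).  Alignments may start and
    end anywhere.
    """
    n, m = len(query_nt), len(subject_aa)

    def col_score(k: int, end: int, j: int) -> float:
        if k >= 3:
            aa = codon_to_aa(query_nt[end - 3 : end])
            base = (
                scoring.stop_codon_score
                if aa == "*"
                else scoring.substitution(aa, subject_aa[j])
            )
        else:
            base = 0.0
        if k != 3:
            base += scoring.frameshift_penalty
        return base

    @lru_cache(maxsize=None)
    def rest(i: int, j: int, state: str) -> float:
        best = 0.0  # may always stop here
        for k in (1, 2, 3, 4, 5):
            if i + k <= n and j < m:
                best = max(
                    best, col_score(k, i + k, j) + rest(i + k, j + 1, "M")
                )
        if j < m:
            cost = (
                scoring.gap_extend if state == "IX" else scoring.gap_open
            )
            best = max(best, cost + rest(i, j + 1, "IX"))
        if i + 3 <= n:
            cost = (
                scoring.gap_extend if state == "IY" else scoring.gap_open
            )
            best = max(best, cost + rest(i + 3, j, "IY"))
        return best

    best = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            best = max(best, rest(i, j, "M"))
    rest.cache_clear()
    return best


def protein_sw_score(a: str, b: str, scoring) -> float:
    """Plain local protein-protein Smith-Waterman (affine gaps).

    '*' residues are unalignable: any column touching one scores the stop
    penalty, mirroring how the nucleotide-level aligner prices stop
    codons.
    """
    NEG = float("-inf")

    def sub(x: str, y: str) -> float:
        if x == "*" or y == "*":
            return scoring.stop_codon_score
        return scoring.substitution(x, y)

    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = prev + sub(a[i - 1], b[j - 1])
            Ix[i][j] = max(
                M[i][j - 1] + scoring.gap_open,
                Ix[i][j - 1] + scoring.gap_extend,
            )
            Iy[i][j] = max(
                M[i - 1][j] + scoring.gap_open,
                Iy[i - 1][j] + scoring.gap_extend,
            )
            best = max(best, M[i][j])
    return best


def best_single_frame_sw(query_nt: str, subject_aa: str, scoring) -> float:
    """Best of three independent single-frame translated SW runs."""
    best = 0.0
    for frame in range(3):
        usable = len(query_nt) - frame
        usable -= usable % 3
        aa = "".join(
            codon_to_aa(query_nt[i : i + 3])
            for i in range(frame, frame + usable, 3)
        )
        if aa:
            best = max(best, protein_sw_score(aa, subject_aa, scoring))
    return best
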