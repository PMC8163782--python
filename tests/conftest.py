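"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices


@pytest.fixture(scope="session")
def sw_oracle():
    """Independent local-alignment scorer (Biopython) with the BLAST-style
    gap model used by the package: a gap of length L costs 11 + L."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


@pytest.fixture(scope="session")
def global_dna_oracle():
    """Biopython global DNA aligner: match +1, mismatch -1, gap -2."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_dna(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    out = list(seq)
    for i in rng.choice(len(seq), size=n_sub, replace=False):
        out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)


# ---------------------------------------------------------------------------
# pure-python identity oracle: maximise (global score, matches) lexicographically

def py_identity_oracle(a: str, b: str,
                       match: int = 1, mismatch: int = -1,
                       gap: int = -2) -> tuple[int, int]:
    """Full-matrix DP returning (optimal score, max identical positions
    among score-optimal global alignments).  Plain-python reference."""
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    M = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = gap * i
    for j in range(1, m + 1):
        S[0][j] = gap * j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eq = ai == b[j - 1]
            sd = S[i - 1][j - 1] + (match if eq else mismatch)
            su = S[i - 1][j] + gap
            sl = S[i][j - 1] + gap
            s = max(sd, su, sl)
            best = -1
            if sd == s:
                best = M[i - 1][j - 1] + (1 if eq else 0)
            if su == s and M[i - 1][j] > best:
                best = M[i - 1][j]
            if sl == s and M[i][j - 1] > best:
                best = M[i][j - 1]
            S[i][j] = s
            M[i][j] = best
    return S[n][m], M[n][m]


def enumerate_identity_oracle(a: str, b: str,
                              match: int = 1, mismatch: int = -1,
                              gap: int = -2) -> tuple[int, int]:
    """Exhaustive enumeration of every global alignment of two tiny
    sequences; returns (max score, max matches among max-score alignments)."""
    best: dict[str, int] = {}

    def rec(i: int, j: int, score: int, matches: int) -> None:
        if i == len(a) and j == len(b):
            key = "done"
            if score > best.get("score", -10**9):
                best["score"], best["matches"] = score, matches
            elif score == best.get("score") and matches > best["matches"]:
                best["matches"] = matches
            return
        if i < len(a) and j < len(b):
            eq = a[i] == b[j]
            rec(i + 1, j + 1, score + (match if eq else mismatch),
                matches + (1 if eq else 0))
        if i < len(a):
            rec(i + 1, j, score + gap, matches)
        if j < len(b):
            rec(i, j + 1, score + gap, matches)

    rec(0, 0, 0, 0)
    return best["score"], best["matches"]
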