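"""Dynamic-programming alignment kernels shared across modules.

Three primitives live here:

* affine-gap local alignment (Smith-Waterman/Gotoh) over an arbitrary
  substitution matrix, optionally restricted to a diagonal band — the
  engine behind protein homology search;
* global alignment with unit match/mismatch and linear gaps, tracking the
  maximum number of identical aligned positions among score-optimal
  alignments — the engine behind nucleotide identity for clustering;
* small encoding helpers (protein -> BLOSUM62 index, DNA -> 2-bit codes,
  k-mer integer codes).

Gap convention for the local aligner follows the BLAST parameterisation:
a gap of length L costs ``gap_open + gap_extend * L`` (so the first gapped
position costs open+extend).  Kernels are numba-compiled; scores are exact
integers carried in float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
AA_ALPHABET: str = str(_BLOSUM.alphabet)
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]
BLOSUM62 = np.asarray(_BLOSUM, dtype=np.float64)

_DNA_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_protein(seq: str) -> np.ndarray:
    """Map residues to BLOSUM62 row indices; unknown letters become X."""
    return np.array([_AA_INDEX.get(c, _X_INDEX) for c in seq], dtype=np.int64)


def encode_dna(seq: str) -> np.ndarray:
    return np.array([_DNA_INDEX.get(c, 4) for c in seq], dtype=np.int64)


def revcomp(seq: str) -> str:
    return "".join(_DNA_COMP.get(c, "N") for c in reversed(seq))


@dataclass
class LocalAlignment:
    score: float
    query_start: int
    query_end: int  # half-open on the query
    target_start: int
    target_end: int  # half-open on the target
    matches: int
    aligned_len: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.aligned_len if self.aligned_len else 0.0


@njit(cache=False)
def _local_align_kernel(a, b, sub, gap_open, gap_ext, lo, hi):
    """Banded affine local alignment with pointer traceback.

    Cells (i, j) with diagonal d = j - i outside [lo, hi] are unreachable.
    Returns (score, a0, a1, b0, b1, matches, aligned_len).
    Tie-break: the highest-scoring cell with smallest (i, j) wins; traceback
    prefers diagonal moves, then gaps in the target, then the query.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    # pointers: 0 stop, 1 diag, 2 from E (gap consuming b), 3 from F (gap consuming a)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 -> opened from H
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    open_cost = gap_open + gap_ext

    best = 0.0
    bi = 0
    bj = 0
    for i in range(n + 1):
        for j in range(m + 1):
            d = j - i
            if d < lo or d > hi:
                H[i, j] = NEG
                continue
            if i == 0 or j == 0:
                H[i, j] = 0.0
                continue
            e_ext = E[i, j - 1] - gap_ext
            e_open = H[i, j - 1] - open_cost
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
            f_ext = F[i - 1, j] - gap_ext
            f_open = H[i - 1, j] - open_cost
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    # traceback
    i, j = bi, bj
    matches = 0
    alen = 0
    state = 0  # 0: in H, 2: in E, 3: in F
    a1, b1 = bi, bj
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                alen += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            alen += 1
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
        else:
            alen += 1
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
    return best, i, a1, j, b1, matches, alen


def local_align(
    query: np.ndarray | str,
    target: np.ndarray | str,
    matrix: np.ndarray = BLOSUM62,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    band: tuple[int, int] | None = None,
    protein: bool = True,
) -> LocalAlignment:
    """Local alignment of query vs target; ``band`` restricts diagonals j-i."""
    a = encode_protein(query) if isinstance(query, str) and protein else (
        encode_dna(query) if isinstance(query, str) else np.asarray(query, dtype=np.int64))
    b = encode_protein(target) if isinstance(target, str) and protein else (
        encode_dna(target) if isinstance(target, str) else np.asarray(target, dtype=np.int64))
    if band is None:
        lo, hi = -a.shape[0], b.shape[0]
    else:
        lo, hi = band
    score, a0, a1, b0, b1, matches, alen = _local_align_kernel(
        a, b, matrix, float(gap_open), float(gap_extend), lo, hi
    )
    return LocalAlignment(float(score), int(a0), int(a1), int(b0), int(b1),
                          int(matches), int(alen))


@njit(cache=False)
def _global_identity_kernel(a, b, match, mismatch, gap):
    """Global (Needleman-Wunsch) alignment score plus the maximum count of
    identical aligned positions achievable by any score-optimal alignment."""
    n = a.shape[0]
    m = b.shape[0]
    S = np.empty((n + 1, m + 1))
    M = np.zeros((n + 1, m + 1))
    for i in range(n + 1):
        S[i, 0] = gap * i
    for j in range(m + 1):
        S[0, j] = gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            sd = S[i - 1, j - 1] + sub
            su = S[i - 1, j] + gap
            sl = S[i, j - 1] + gap
            s = max(sd, su, sl)
            S[i, j] = s
            best_m = -1.0
            if sd == s:
                cand = M[i - 1, j - 1] + (1.0 if a[i - 1] == b[j - 1] else 0.0)
                if cand > best_m:
                    best_m = cand
            if su == s and M[i - 1, j] > best_m:
                best_m = M[i - 1, j]
            if sl == s and M[i, j - 1] > best_m:
                best_m = M[i, j - 1]
            M[i, j] = best_m
    return S[n, m], M[n, m]


def global_alignment_matches(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> tuple[float, int]:
    """Return (optimal global score, max identical positions among optima)."""
    score, matches = _global_identity_kernel(
        encode_dna(a), encode_dna(b), float(match), float(mismatch), float(gap)
    )
    return float(score), int(matches)


# ---------------------------------------------------------------------------
# k-mer helpers

def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i:i + k], []).append(i)
    return out


def dna_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of a 2-bit encoded sequence (N poisons
    its windows: their code is returned as -1)."""
    L = codes.shape[0]
    if L < k:
        return np.empty(0, dtype=np.int64)
    W = L - k + 1
    valid = codes < 4
    out = np.zeros(W, dtype=np.int64)
    ok = np.ones(W, dtype=bool)
    safe = np.where(valid, codes, 0)
    for t in range(k):
        out = out * 4 + safe[t:t + W]
        ok &= valid[t:t + W]
    out[~ok] = -1
    return out
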