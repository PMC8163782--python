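"""Tetranucleotide-frequency SOM verification of contig-bin membership.

Contigs are fragmented into windows, each window is reduced to its 256-dim
tetranucleotide frequency (TNF) signature, and a batch self-organizing map
is trained on all fragments of all bins jointly.  A contig genuinely
belongs to its bin when its fragments land in map regions dominated by
fragments of the same bin; the coherence statistic quantifies this and
automates what is traditionally a manual inspection of an emergent SOM
U-matrix.

The map is a toroidal grid of codebook vectors trained with the batch
algorithm: every epoch assigns each fragment to its best-matching unit
(BMU, minimal Euclidean distance, ties to the lowest unit index), then
replaces each codebook vector by the neighborhood-weighted mean of the
data, with a Gaussian neighborhood whose radius anneals linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeBin

__all__ = [
    "Fragment",
    "SomGrid",
    "PlacementReport",
    "fragment_contigs",
    "tnf",
    "train_som",
    "verify_bin_membership",
    "toroidal_distance_sq",
]

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i


@dataclass
class Fragment:
    fragment_id: str
    parent_contig: str
    parent_bin: str
    offset: int
    sequence: str
    tnf: np.ndarray | None = None


@dataclass
class SomGrid:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, 256)
    toroidal: bool = True
    epochs: int = 0
    radius_schedule: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    quantization_errors: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


@dataclass
class PlacementReport:
    bin_id: str
    contig_id: str
    coherence: float
    passed: bool
    n_fragments: int


def fragment_contigs(genome_bin: GenomeBin, window_bp: int = 5000,
                     step_bp: int | None = None,
                     min_len_bp: int = 2000) -> list[Fragment]:
    """Cut every contig into windows; the trailing remainder is kept iff it
    is at least ``min_len_bp`` long."""
    step = step_bp or window_bp
    frags: list[Fragment] = []
    for contig in genome_bin.contigs:
        L = len(contig.residues)
        for k, off in enumerate(range(0, L, step)):
            piece = contig.residues[off:off + window_bp]
            if len(piece) < min_len_bp:
                continue
            frags.append(Fragment(
                fragment_id=f"{contig.id}#{k}",
                parent_contig=contig.id,
                parent_bin=genome_bin.bin_id,
                offset=off,
                sequence=piece))
            if off + window_bp >= L:
                break
    return frags


def tnf(fragment: Fragment | str) -> np.ndarray:
    """Frequencies of overlapping 4-mers on the given strand, sliding by 1;
    windows containing N are skipped.  Normalised to sum to 1."""
    seq = fragment if isinstance(fragment, str) else fragment.sequence
    codes = _LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if codes.shape[0] < 4:
        raise ValueError("no_valid_kmers")
    W = codes.shape[0] - 3
    valid = codes < 4
    ok = valid[:W] & valid[1:W + 1] & valid[2:W + 2] & valid[3:W + 3]
    idx = (codes[:W].astype(np.int64) * 64 + codes[1:W + 1] * 16
           + codes[2:W + 2] * 4 + codes[3:W + 3])
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no_valid_kmers")
    counts = np.bincount(idx, minlength=256).astype(float)
    vec = counts / counts.sum()
    if isinstance(fragment, Fragment):
        fragment.tnf = vec
    return vec


def toroidal_distance_sq(rows: int, cols: int,
                         toroidal: bool = True) -> np.ndarray:
    """(units x units) squared grid distances; wrap-around when toroidal."""
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    # unit index u = row * cols + col
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2)
    return d2.reshape(rows * cols, rows * cols).astype(float)


def _bmu(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Best-matching unit per row of x (ties -> lowest unit index)."""
    d2 = ((x ** 2).sum(1)[:, None] + (codebook ** 2).sum(1)[None, :]
          - 2.0 * x @ codebook.T)
    return np.argmin(d2, axis=1)


def train_som(vectors: np.ndarray, rows: int = 50, cols: int = 80,
              epochs: int = 20, r0: float | None = None,
              r_final: float = 0.5, seed: int = 0,
              toroidal: bool = True) -> SomGrid:
    """Batch-train a (toroidal) SOM on the given vectors.

    Codebook is initialised by sampling input vectors with the run seed.
    The Gaussian neighborhood radius anneals linearly from ``r0`` (default
    max(rows, cols)/4) to ``r_final``.  The per-epoch quantization error
    (mean distance of each vector to its BMU after the update) is recorded
    on the returned grid.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("empty input")
    n, dim = X.shape
    units = rows * cols
    rng = np.random.default_rng(seed)
    take = rng.choice(n, size=units, replace=n < units)
    codebook = X[take].copy()
    r0 = r0 if r0 is not None else max(rows, cols) / 4.0
    d2 = toroidal_distance_sq(rows, cols, toroidal)

    qe: list[float] = []
    for epoch in range(epochs):
        t = epoch / (epochs - 1) if epochs > 1 else 1.0
        radius = r0 + (r_final - r0) * t
        bmu = _bmu(X, codebook)
        h = np.exp(-d2 / (2.0 * radius * radius))
        # per-unit sums of assigned vectors, then neighborhood smoothing
        S = np.zeros((units, dim))
        np.add.at(S, bmu, X)
        counts = np.bincount(bmu, minlength=units).astype(float)
        num = h @ S
        den = h @ counts
        good = den > 1e-12
        codebook[good] = num[good] / den[good, None]
        dist = np.linalg.norm(X - codebook[_bmu(X, codebook)], axis=1)
        qe.append(float(dist.mean()))

    return SomGrid(rows=rows, cols=cols, codebook=codebook, toroidal=toroidal,
                   epochs=epochs, radius_schedule=(float(r0), float(r_final)),
                   seed=seed, quantization_errors=qe)


def u_matrix(grid: SomGrid) -> np.ndarray:
    """(rows x cols) mean codebook distance of each unit to its grid
    neighbors — high ridges separate composition clusters."""
    cb = grid.codebook.reshape(grid.rows, grid.cols, -1)
    out = np.zeros((grid.rows, grid.cols))
    for r in range(grid.rows):
        for c in range(grid.cols):
            dists = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if grid.toroidal:
                    rr %= grid.rows
                    cc %= grid.cols
                elif not (0 <= rr < grid.rows and 0 <= cc < grid.cols):
                    continue
                dists.append(np.linalg.norm(cb[r, c] - cb[rr, cc]))
            out[r, c] = float(np.mean(dists))
    return out


def verify_bin_membership(grid: SomGrid, fragments: list[Fragment],
                          target_contig: str, k_neighborhood: int = 8,
                          threshold: float = 0.6) -> PlacementReport:
    """Coherence of one contig's placement on a trained map.

    For each fragment of the target contig, find the ``k_neighborhood``
    nearest fragments of *other* contigs in the map's codebook space
    (distance between best-matching-unit codebook vectors, ties broken by
    raw TNF distance); the fragment is coherent when more than half of
    those neighbors belong to the target's claimed bin.  Codebook-vector
    distance rather than grid distance makes the statistic robust to the
    topological folding a small map can exhibit.  Coherence is the
    fraction of coherent fragments.  With no foreign fragments on the map
    the contig is trivially coherent (coherence 1.0).
    """
    vecs = np.stack([f.tnf if f.tnf is not None else tnf(f) for f in fragments])
    bmu = _bmu(vecs, grid.codebook)
    target_idx = [i for i, f in enumerate(fragments)
                  if f.parent_contig == target_contig]
    if not target_idx:
        raise ValueError(f"contig {target_contig} contributed no fragments")
    target_bin = fragments[target_idx[0]].parent_bin
    other_idx = np.array([i for i, f in enumerate(fragments)
                          if f.parent_contig != target_contig], dtype=int)
    if other_idx.size == 0:
        return PlacementReport(target_bin, target_contig, 1.0, True,
                               len(target_idx))
    other_bmu = bmu[other_idx]
    other_same = np.array([fragments[i].parent_bin == target_bin
                           for i in other_idx])

    coherent = 0
    k = min(k_neighborhood, other_idx.size)
    for i in target_idx:
        unit_d = np.linalg.norm(grid.codebook[other_bmu]
                                - grid.codebook[bmu[i]], axis=1)
        feat_d = np.linalg.norm(vecs[other_idx] - vecs[i], axis=1)
        order = np.lexsort((feat_d, unit_d))[:k]
        if other_same[order].sum() / k > 0.5:
            coherent += 1
    coherence = coherent / len(target_idx)
    return PlacementReport(target_bin, target_contig, coherence,
                           coherence >= threshold, len(target_idx))
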