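"""Read recruitment, coverage, genome equivalents, abundance, and RPKM.

The quantification model follows the gene-centric normalisation used for
single-copy genes in metagenomes:

* reads are recruited to representative gene sequences at high identity
  (default >= 95% over >= 90% of the read);
* per-target mean depth = total aligned bases / target length;
* a sample's *genome equivalents* — how many genome copies the read set
  represents — is estimated as the mean over single-copy marker gene
  families of the family's summed mean depth (every genome carries each
  marker once, so summed marker depth counts genome copies sampled);
* relative abundance of a gene = 100 x gene depth / genome equivalents,
  interpretable as the percentage of community genomes carrying the gene
  when the gene is single-copy;
* transcript abundance = RPKM, read count normalised by gene length (kb)
  and mapped library size (millions), with per-organism expression ratios
  against the housekeeping genes rpoB and gyrB.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats

from .alignment import dna_kmer_codes
from .synthetic_community import ReadSet

__all__ = [
    "ReadAlignment",
    "CoverageSummary",
    "GenomeEquivalents",
    "AbundanceRecord",
    "ExpressionRecord",
    "DepthProfile",
    "recruit_reads",
    "coverage_summary",
    "genome_equivalents",
    "relative_abundance",
    "rpkm",
    "expression_ratio",
    "depth_profile",
]

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
_NT_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ReadAlignment:
    read_id: str
    target_id: str
    target_start: int
    aligned_len: int
    percent_identity: float
    strand: str


@dataclass
class CoverageSummary:
    target_id: str
    sample_id: str
    mean_depth: float


@dataclass
class GenomeEquivalents:
    sample_id: str
    value: float


@dataclass
class AbundanceRecord:
    target_id: str
    sample_id: str
    relative_abundance_pct: float


@dataclass
class ExpressionRecord:
    target_id: str
    sample_id: str
    rpkm: float
    ratio_rpoB: float | None = None  # None flags an undefined ratio
    ratio_gyrB: float | None = None


@dataclass
class DepthProfile:
    gene_family: str
    depth_m: int
    mean: float
    ci95_halfwidth: float | None  # None when n == 1
    n: int


# ---------------------------------------------------------------------------
# Recruitment

def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def recruit_reads(reads, targets: dict[str, str],
                  min_identity: float = 0.95,
                  min_aligned_frac: float = 0.9,
                  k: int = 15) -> list[ReadAlignment]:
    """Map reads to their single best target.

    Candidate (target, strand, diagonal) pairs come from shared k-mers
    (both read orientations against the forward target).  Each candidate is
    scored by banded edit-distance alignment of the read's overlapping part
    against the target window; reads failing the identity or aligned-
    fraction thresholds stay unmapped.  Ties go to the lexicographically
    smallest target id.
    """
    if not targets:
        raise ValueError("empty target set")
    if isinstance(reads, ReadSet):
        ids = reads.ids
        mat = reads.matrix
    else:
        ids = [r.id for r in reads]
        if not ids:
            return []
        lens = {len(r.residues) for r in reads}
        n = max(lens)
        mat = np.full((len(reads), n), 4, dtype=np.uint8)
        for i, r in enumerate(reads):
            mat[i, :len(r.residues)] = _encode(r.residues)
        if len(lens) > 1:
            raise ValueError("recruit_reads requires uniform read length")
    if mat.shape[0] == 0:
        return []
    read_len = mat.shape[1]

    # k-mer index over forward target sequences
    index: dict[int, list[tuple[str, int]]] = {}
    target_codes: dict[str, np.ndarray] = {}
    for tid in sorted(targets):
        codes = _encode(targets[tid])
        target_codes[tid] = codes
        for pos, code in enumerate(dna_kmer_codes(codes, k)):
            if code >= 0:
                index.setdefault(int(code), []).append((tid, pos))
    all_codes = np.array(sorted(index), dtype=np.int64)

    rc_mat = 3 - mat[:, ::-1]
    W = read_len - k + 1
    fwd_kmers = _batch_kmers(mat, k)
    rev_kmers = _batch_kmers(rc_mat, k)
    fwd_hits = np.isin(fwd_kmers, all_codes)
    rev_hits = np.isin(rev_kmers, all_codes)
    cand_mask = fwd_hits.any(axis=1) | rev_hits.any(axis=1)

    out: list[ReadAlignment] = []
    for ri in np.flatnonzero(cand_mask):
        best = None  # (neg_matches, tid, strand, tstart, alen, identity)
        for strand, kmers, hits, row in (("+", fwd_kmers[ri], fwd_hits[ri], mat[ri]),
                                         ("-", rev_kmers[ri], rev_hits[ri], rc_mat[ri])):
            diags: dict[tuple[str, int], None] = {}
            positions = np.flatnonzero(hits)
            if positions.size > 16:
                positions = positions[:: max(1, positions.size // 16)]
            for qpos in positions:
                code = int(kmers[qpos])
                for tid, tpos in index.get(code, ()):
                    diags[(tid, tpos - int(qpos))] = None
            for tid, d in diags:
                tcodes = target_codes[tid]
                L = tcodes.shape[0]
                q0 = max(0, -d)
                q1 = min(read_len, L - d)
                alen = q1 - q0
                if alen < min_aligned_frac * read_len:
                    continue
                pad = 4
                t0 = max(0, d + q0 - pad)
                t1 = min(L, d + q1 + pad)
                query = _NT_ARR[row[q0:q1]].tobytes().decode()
                window = _NT_ARR[tcodes[t0:t1]].tobytes().decode()
                res = edlib.align(query, window, mode="HW", task="locations")
                ed = res["editDistance"]
                identity = 1.0 - ed / alen
                if identity < min_identity:
                    continue
                matches = alen - ed
                key = (-matches, tid, strand)
                if best is None or key < best[0]:
                    loc = res["locations"][0]
                    best = (key, tid, strand, t0 + loc[0], alen, identity)
        if best is not None:
            _, tid, strand, tstart, alen, identity = best
            out.append(ReadAlignment(
                read_id=ids[int(ri)], target_id=tid, target_start=int(tstart),
                aligned_len=int(alen),
                percent_identity=100.0 * identity, strand=strand))
    return out


def _batch_kmers(mat: np.ndarray, k: int) -> np.ndarray:
    n, L = mat.shape
    W = L - k + 1
    if W <= 0:
        return np.full((n, 0), -1, dtype=np.int64)
    valid = mat < 4
    out = np.zeros((n, W), dtype=np.int64)
    ok = np.ones((n, W), dtype=bool)
    safe = np.where(valid, mat, 0).astype(np.int64)
    for t in range(k):
        out = out * 4 + safe[:, t:t + W]
        ok &= valid[:, t:t + W]
    out[~ok] = -1
    return out


# ---------------------------------------------------------------------------
# Coverage and normalisation

def effective_length(length: int, read_len: int,
                     min_aligned_frac: float = 0.9) -> float:
    """Edge-corrected denominator for mean depth.

    Reads overlapping a target by less than ``min_aligned_frac`` of their
    length are never recruited, so a target systematically collects fewer
    aligned bases near its ends.  Under uniform read starts the expected
    aligned bases per unit coverage are
    ``read_len*(L - read_len + 1) + 2*sum(o for o in [min_ov, read_len))``
    divided by ``read_len``; using this as the denominator makes mean depth
    an unbiased coverage estimate regardless of target length.
    """
    min_ov = int(np.ceil(min_aligned_frac * read_len))
    if length < read_len:
        return float(length)
    edge = sum(range(min_ov, read_len))
    return (read_len * (length - read_len + 1) + 2 * edge) / read_len


def coverage_summary(alignments: list[ReadAlignment],
                     target_lengths: dict[str, int],
                     sample_id: str,
                     read_len: int | None = None,
                     min_aligned_frac: float = 0.9
                     ) -> dict[str, CoverageSummary]:
    """Mean depth per target: total aligned bases / target length.

    When ``read_len`` is given the denominator is the edge-corrected
    :func:`effective_length` instead of the raw length.
    """
    bases: dict[str, int] = {tid: 0 for tid in target_lengths}
    for aln in alignments:
        if aln.target_id in bases:
            bases[aln.target_id] += aln.aligned_len
    denom = {
        tid: (effective_length(L, read_len, min_aligned_frac)
              if read_len else float(L))
        for tid, L in target_lengths.items()
    }
    return {tid: CoverageSummary(tid, sample_id, bases[tid] / denom[tid])
            for tid in target_lengths}


def genome_equivalents(marker_coverages: dict[str, CoverageSummary],
                       marker_family: dict[str, str],
                       sample_id: str) -> GenomeEquivalents:
    """Mean over marker families of the family's summed mean depth.

    ``marker_family`` maps each marker target id to its family; a family's
    copies across genomes are summed (genome copies add), then families are
    averaged.  Raises when no marker has signal.
    """
    fam_depth: dict[str, float] = {}
    for tid, cov in marker_coverages.items():
        fam = marker_family.get(tid)
        if fam is None:
            continue
        fam_depth[fam] = fam_depth.get(fam, 0.0) + cov.mean_depth
    if not fam_depth or all(v == 0 for v in fam_depth.values()):
        raise ValueError("no_marker_signal")
    return GenomeEquivalents(sample_id, float(np.mean(list(fam_depth.values()))))


def relative_abundance(gene_coverage: CoverageSummary,
                       ge: GenomeEquivalents) -> AbundanceRecord:
    """Percent of community genomes carrying the gene: 100 x depth / GE."""
    if ge.value <= 0:
        raise ValueError("genome equivalents must be positive")
    return AbundanceRecord(
        target_id=gene_coverage.target_id, sample_id=gene_coverage.sample_id,
        relative_abundance_pct=100.0 * gene_coverage.mean_depth / ge.value)


def rpkm(read_count: int, gene_len_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_len_bp <= 0:
        raise ValueError("gene_len_bp must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("zero library")
    return read_count / (gene_len_bp / 1000.0) / (total_mapped_reads / 1e6)


def expression_ratio(gene_rpkm: float,
                     housekeeping_rpkm: float) -> float | None:
    """Gene/housekeeping RPKM ratio; None flags an undefined ratio."""
    if housekeeping_rpkm < 0:
        raise ValueError("negative housekeeping rpkm")
    if housekeeping_rpkm == 0:
        return None
    return gene_rpkm / housekeeping_rpkm


def depth_profile(records: list[tuple[str, int, str, float]]
                  ) -> list[DepthProfile]:
    """Mean and Student-t 95% CI per (gene family, depth).

    ``records`` rows are (gene_family, depth_m, sample_id, value).  The CI
    half-width is t_{0.975, n-1} x sd / sqrt(n); undefined (None) for a
    single sample.
    """
    groups: dict[tuple[str, int], list[float]] = {}
    for fam, depth, _sid, value in records:
        groups.setdefault((fam, depth), []).append(value)
    out = []
    for (fam, depth), vals in sorted(groups.items()):
        n = len(vals)
        mean = float(np.mean(vals))
        if n >= 2:
            sd = float(np.std(vals, ddof=1))
            hw = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
        else:
            hw = None
        out.append(DepthProfile(fam, depth, mean, hw, n))
    return out
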