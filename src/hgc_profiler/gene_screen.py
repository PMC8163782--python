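"""Detection of hgcA, hgcB, hgcB-like, and merB genes in genome bins.

The screen composes four kinds of evidence, mirroring how mercury-
methylation genes are identified in MAGs:

1. ORF calling on all six frames (bacterial/archaeal code, table 11);
2. seeded, banded local-alignment homology search of each ORF against a
   curated reference protein panel (BLOSUM62, affine gaps);
3. exact degenerate-motif confirmation — the HgcA cap-helix motif
   N(V/I)WCA(A/G)(A/G)K and the HgcB ferredoxin motif CX2CX2CX3C;
4. synteny: a genuine hgcB lies just downstream of hgcA on the same strand.

HgcA-homologous ORFs that fail the cap-helix check are reported as
"paralog_like" and are never counted as hgcA: non-methylating bacteria
carry HgcA paralogues that pass homology but lack the catalytic motif.
ORFs carrying two or more ferredoxin motifs without hgcA synteny are
reported as hgcB_like candidates.  merB calls rest on homology alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from . import alignment
from .alignment import LocalAlignment, kmer_positions, kmer_set, revcomp
from .io_formats import GenomeBin

__all__ = [
    "OpenReadingFrame",
    "HomologyHit",
    "MotifMatch",
    "HgcCall",
    "ScreenParams",
    "find_orfs",
    "search_homologs",
    "match_hgcA_motif",
    "match_ferredoxin_motif",
    "check_hgcB_synteny",
    "call_hgc_genes",
    "translate",
    "CALL_TYPES",
]

CALL_TYPES = ("hgcA", "hgcB", "hgcB_like", "merB")
START_CODONS = ("ATG", "GTG", "TTG")

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    _CODON_TO_AA[_stop] = "*"

HGCA_MOTIF_RE = re.compile(r"(?=(N[VI]WCA[AG][AG]K))")
FERREDOXIN_RE = re.compile(r"(?=(C.{2}C.{2}C.{3}C))")


def translate(dna: str) -> str:
    """Translate complete codons with the bacterial/archaeal code; codons
    containing ambiguous bases become X, stops become ``*``."""
    n = len(dna) // 3
    return "".join(_CODON_TO_AA.get(dna[3 * i:3 * i + 3], "X") for i in range(n))


@dataclass
class OpenReadingFrame:
    """An ORF in forward-strand coordinates; [start, end) includes the stop
    codon, ``aa_sequence`` does not include the terminal stop."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_sequence: str

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"

    def __len__(self) -> int:
        return len(self.aa_sequence)


@dataclass
class HomologyHit:
    orf_ref: str
    reference_id: str
    raw_score: float
    percent_identity: float
    query_span: tuple[int, int]
    reference_span: tuple[int, int]
    reference_coverage: float


@dataclass
class MotifMatch:
    pattern_id: str  # {"hgcA_cap_helix", "ferredoxin_CXXCXXCXXXC"}
    position: int
    matched: str


@dataclass
class HgcCall:
    call_type: str  # CALL_TYPES or "paralog_like"
    bin_id: str
    orf: OpenReadingFrame
    best_hit: HomologyHit
    motifs: list[MotifMatch] = field(default_factory=list)
    synteny_ok: bool | None = None  # meaningful for hgcB only
    evidence_summary: str = ""

    @property
    def nt_key(self) -> tuple[str, str, int]:
        return (self.bin_id, self.orf.contig_id, self.orf.start)


@dataclass
class ScreenParams:
    """Thresholds for the homology search and synteny rules.

    The reference panel gives no printed alignment cut-offs to inherit, so
    the homology gate is deliberately permissive (it controls candidate
    volume); final calls are gated by the motif and synteny evidence.
    """

    min_aa_len: int = 30
    word_size: int = 4
    seed_min: int = 2
    band_width: int = 16
    gap_open: float = 11.0
    gap_extend: float = 1.0
    score_threshold: float = 60.0
    min_reference_coverage: float = 0.5
    max_intergenic_bp: int = 500
    max_gene_skip: int = 1


# ---------------------------------------------------------------------------
# ORF calling

def find_orfs(contig: str, min_aa_len: int = 30,
              contig_id: str = "contig") -> list[OpenReadingFrame]:
    """Scan all six frames for ORFs.

    An ORF runs from the first ATG/GTG/TTG after a stop codon (or the
    contig edge) to the next in-frame stop; reading frames without a
    terminating stop yield nothing.  Reverse-strand ORFs are reported in
    forward coordinates with strand ``-``.
    """
    seq = contig.upper()
    L = len(seq)
    orfs: list[OpenReadingFrame] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            n_codons = (L - frame) // 3
            start_codon_idx: int | None = None
            for c in range(n_codons):
                codon = s[frame + 3 * c: frame + 3 * c + 3]
                aa = _CODON_TO_AA.get(codon, "X")
                if aa == "*":
                    if start_codon_idx is not None:
                        aa_len = c - start_codon_idx
                        if aa_len >= min_aa_len:
                            nt0 = frame + 3 * start_codon_idx
                            nt1 = frame + 3 * (c + 1)  # include stop codon
                            aa_seq = translate(s[nt0:nt1 - 3])
                            if strand == "+":
                                fstart, fend = nt0, nt1
                            else:
                                fstart, fend = L - nt1, L - nt0
                            orfs.append(OpenReadingFrame(
                                contig_id, fstart, fend, strand, frame, aa_seq))
                    start_codon_idx = None
                elif start_codon_idx is None and codon in START_CODONS:
                    start_codon_idx = c
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


# ---------------------------------------------------------------------------
# Homology search

class ReferenceIndex:
    """Pre-computed k-mer sets/positions for a reference protein set."""

    def __init__(self, reference_set: dict[str, str], word_size: int):
        self.word_size = word_size
        self.refs = dict(reference_set)
        self.kmer_sets = {rid: kmer_set(seq, word_size)
                          for rid, seq in reference_set.items()}
        self.kmer_pos = {rid: kmer_positions(seq, word_size)
                         for rid, seq in reference_set.items()}


def search_homologs(orf_aa: str, reference_set: dict[str, str],
                    params: ScreenParams | None = None,
                    orf_ref: str = "query",
                    _index: ReferenceIndex | None = None) -> list[HomologyHit]:
    """Seeded banded Smith-Waterman search of one ORF against references.

    Candidates must share >= ``seed_min`` distinct k-mers with the query;
    survivors are scored by local alignment restricted to a band around the
    seed diagonals.  Hits below the score threshold or covering less than
    ``min_reference_coverage`` of the reference are dropped.  Output sorted
    by raw score (desc), ties broken by reference id.
    """
    params = params or ScreenParams()
    if not orf_aa:
        return []
    if not reference_set:
        raise ValueError("reference_set is empty")
    idx = _index or ReferenceIndex(reference_set, params.word_size)
    query_kmers = kmer_positions(orf_aa, params.word_size)
    qset = set(query_kmers)
    hits: list[HomologyHit] = []
    for rid in idx.refs:
        shared = qset & idx.kmer_sets[rid]
        if len(shared) < params.seed_min:
            continue
        diags = [rp - qp
                 for kmer in shared
                 for qp in query_kmers[kmer]
                 for rp in idx.kmer_pos[rid][kmer]]
        band = (min(diags) - params.band_width, max(diags) + params.band_width)
        aln = alignment.local_align(
            orf_aa, idx.refs[rid], gap_open=params.gap_open,
            gap_extend=params.gap_extend, band=band)
        ref_cov = (aln.target_end - aln.target_start) / len(idx.refs[rid])
        if aln.score >= params.score_threshold and ref_cov >= params.min_reference_coverage:
            hits.append(HomologyHit(
                orf_ref=orf_ref, reference_id=rid, raw_score=aln.score,
                percent_identity=aln.percent_identity,
                query_span=(aln.query_start, aln.query_end),
                reference_span=(aln.target_start, aln.target_end),
                reference_coverage=ref_cov))
    hits.sort(key=lambda h: (-h.raw_score, h.reference_id))
    return hits


# ---------------------------------------------------------------------------
# Motifs

def match_hgcA_motif(aa_sequence: str) -> list[MotifMatch]:
    """All positions matching the cap-helix motif N[VI]WCA[AG][AG]K."""
    return [MotifMatch("hgcA_cap_helix", m.start(), m.group(1))
            for m in HGCA_MOTIF_RE.finditer(aa_sequence)]


def match_ferredoxin_motif(aa_sequence: str) -> list[MotifMatch]:
    """All (overlapping) positions matching CX2CX2CX3C."""
    return [MotifMatch("ferredoxin_CXXCXXCXXXC", m.start(), m.group(1))
            for m in FERREDOXIN_RE.finditer(aa_sequence)]


# ---------------------------------------------------------------------------
# Synteny

def _downstream_candidates(hgcA_orf: OpenReadingFrame,
                           all_orfs: list[OpenReadingFrame],
                           max_intergenic_bp: int,
                           max_gene_skip: int) -> list[OpenReadingFrame]:
    """ORFs downstream of hgcA in its transcription direction, same contig
    and strand, within the intergenic limit, with at most ``max_gene_skip``
    same-strand ORFs in between."""
    same = [o for o in all_orfs
            if o.contig_id == hgcA_orf.contig_id and o.strand == hgcA_orf.strand
            and o is not hgcA_orf and (o.start, o.end) != (hgcA_orf.start, hgcA_orf.end)]
    out = []
    for o in same:
        # gap may be negative: an ORF whose fortuitous upstream start codon
        # reaches back into hgcA still counts as the adjacent downstream gene
        # provided its body extends downstream of hgcA
        if hgcA_orf.strand == "+":
            if o.end <= hgcA_orf.end:
                continue
            gap = o.start - hgcA_orf.end
            between = [x for x in same
                       if hgcA_orf.end <= x.start and x.end <= o.start]
        else:
            if o.start >= hgcA_orf.start:
                continue
            gap = hgcA_orf.start - o.end
            between = [x for x in same
                       if o.end <= x.start and x.end <= hgcA_orf.start]
        if gap > max_intergenic_bp:
            continue
        if len(between) > max_gene_skip:
            continue
        out.append(o)
    return out


def check_hgcB_synteny(hgcA_orf: OpenReadingFrame,
                       all_orfs: list[OpenReadingFrame],
                       hgcB_refs: dict[str, str],
                       max_intergenic_bp: int = 500,
                       max_gene_skip: int = 1,
                       params: ScreenParams | None = None) -> bool:
    """True iff a ferredoxin-motif-bearing, HgcB-homologous ORF lies
    downstream of hgcA on the same strand within the configured limits."""
    params = params or ScreenParams()
    for cand in _downstream_candidates(hgcA_orf, all_orfs,
                                       max_intergenic_bp, max_gene_skip):
        if not match_ferredoxin_motif(cand.aa_sequence):
            continue
        if search_homologs(cand.aa_sequence, hgcB_refs, params,
                           orf_ref=cand.orf_id):
            return True
    return False


# ---------------------------------------------------------------------------
# Composite calling

def call_hgc_genes(genome_bin: GenomeBin,
                   reference_sets: dict[str, dict[str, str]] | None = None,
                   params: ScreenParams | None = None) -> list[HgcCall]:
    """Run the full evidence chain over a bin.

    Returns calls of type hgcA / hgcB / hgcB_like / merB, plus
    "paralog_like" records for HgcA homologs lacking the cap-helix motif
    (these are informational and excluded from all hgcA accounting).
    """
    params = params or ScreenParams()
    if reference_sets is None:
        from .references import default_reference_panel
        panel = default_reference_panel()
        reference_sets = {f: panel[f] for f in ("hgcA", "hgcB", "merB")}
    indices = {fam: ReferenceIndex(refs, params.word_size)
               for fam, refs in reference_sets.items()}

    calls: list[HgcCall] = []
    for contig in genome_bin.contigs:
        orfs = find_orfs(contig.residues, params.min_aa_len, contig.id)
        hgcA_calls: list[HgcCall] = []
        hgcB_candidates: list[tuple[OpenReadingFrame, HomologyHit, list[MotifMatch]]] = []
        for orf in orfs:
            fam_hits = {}
            for fam, refs in reference_sets.items():
                hits = search_homologs(orf.aa_sequence, refs, params,
                                       orf_ref=orf.orf_id, _index=indices[fam])
                if hits:
                    fam_hits[fam] = hits[0]
            if not fam_hits:
                continue
            # strongest family wins; ties broken by family name for determinism
            fam = min(fam_hits, key=lambda f: (-fam_hits[f].raw_score, f))
            best = fam_hits[fam]
            if fam == "hgcA":
                motifs = match_hgcA_motif(orf.aa_sequence)
                if motifs:
                    hgcA_calls.append(HgcCall(
                        "hgcA", genome_bin.bin_id, orf, best, motifs,
                        evidence_summary=(
                            f"homology:{best.reference_id}"
                            f"({best.raw_score:.0f});cap_helix@"
                            f"{motifs[0].position}")))
                else:
                    calls.append(HgcCall(
                        "paralog_like", genome_bin.bin_id, orf, best, [],
                        evidence_summary=(
                            f"homology:{best.reference_id}"
                            f"({best.raw_score:.0f});cap_helix:absent")))
            elif fam == "hgcB":
                fd = match_ferredoxin_motif(orf.aa_sequence)
                if fd:
                    hgcB_candidates.append((orf, best, fd))
            elif fam == "merB":
                calls.append(HgcCall(
                    "merB", genome_bin.bin_id, orf, best, [],
                    evidence_summary=(
                        f"homology:{best.reference_id}({best.raw_score:.0f})")))

        # resolve hgcB via synteny against the contig's hgcA calls
        for acall in hgcA_calls:
            room = (len(contig.residues) - acall.orf.end
                    if acall.orf.strand == "+" else acall.orf.start)
            partner = None
            for orf, hit, fd in hgcB_candidates:
                cands = _downstream_candidates(
                    acall.orf, [orf], params.max_intergenic_bp,
                    params.max_gene_skip)
                if cands:
                    partner = (orf, hit, fd)
                    break
            if partner is None and room < params.max_intergenic_bp:
                acall.evidence_summary += ";contig_edge"
            calls.append(acall)
            if partner is not None:
                orf, hit, fd = partner
                calls.append(HgcCall(
                    "hgcB", genome_bin.bin_id, orf, hit, fd, synteny_ok=True,
                    evidence_summary=(
                        f"homology:{hit.reference_id}({hit.raw_score:.0f});"
                        f"ferredoxin x{len(fd)};downstream_of:"
                        f"{acall.orf.orf_id}")))
                hgcB_candidates = [c for c in hgcB_candidates if c[0] is not orf]

        # remaining ferredoxin carriers: hgcB_like requires tandem motifs
        for orf, hit, fd in hgcB_candidates:
            if len(fd) >= 2:
                calls.append(HgcCall(
                    "hgcB_like", genome_bin.bin_id, orf, hit, fd,
                    synteny_ok=False,
                    evidence_summary=(
                        f"homology:{hit.reference_id}({hit.raw_score:.0f});"
                        f"tandem ferredoxin x{len(fd)}")))

    calls.sort(key=lambda c: (c.orf.contig_id, c.orf.start, c.call_type))
    return calls


def extract_call_nt(call: HgcCall, genome_bin: GenomeBin,
                    include_stop: bool = False) -> str:
    """Nucleotide sequence of a call's ORF in transcription orientation."""
    contig = next(c for c in genome_bin.contigs if c.id == call.orf.contig_id)
    nt = contig.residues[call.orf.start:call.orf.end]
    if call.orf.strand == "-":
        nt = revcomp(nt)
    return nt if include_stop else nt[:-3]
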