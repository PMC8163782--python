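"""Synthetic community generator with planted loci and known ground truth.

Emulates the study system end to end: genomes with hgcA/hgcB operons,
merB, housekeeping genes and single-copy markers planted at known
coordinates; a community abundance profile over a six-depth gradient
(10, 100, 120, 135, 150, 200 m); shotgun metagenome reads drawn uniformly
per genome at prescribed coverages; and metatranscriptome reads emitted
only from annotated loci with Poisson counts proportional to per-cell
expression rate x carrier abundance (the constitutive-expression model:
the per-cell rate is depth-independent, so transcript pools scale with
carrier abundance).

Mutation model.  Planted proteins are back-translated with synonymous
codons weighted by the genome's GC bias (so planted genes share the host's
composition and cannot be spotted by tetranucleotide signature alone), then
point-mutated at a per-site rate.  Functional loci evolve under purifying
selection: substitutions at motif-encoding codons are restricted to
synonymous changes, nonsense substitutions are redirected to non-stop
alternatives, and the terminal stop codon can only mutate to another stop.
This mirrors how real homologs of these genes diverge — nucleotide identity
decays while the conserved motifs and an intact reading frame persist.

All randomness flows from one integer seed through named child streams, so
identical configurations reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_screen import (_CODON_TO_AA, match_ferredoxin_motif,
                          match_hgcA_motif, translate)
from .io_formats import GenomeBin, ReadRecord, SequenceRecord
from .references import reference_protein

__all__ = [
    "DEPTHS_M",
    "PlantRequest",
    "PlantedLocus",
    "CommunityProfile",
    "TruthTable",
    "ReadSet",
    "simulate_genome",
    "simulate_metagenome_reads",
    "simulate_transcriptome_reads",
    "carrier_plant_spec",
    "background_plant_spec",
    "default_community",
    "back_translate",
]

DEPTHS_M = (10, 100, 120, 135, 150, 200)

_NT = "ACGT"
_NT_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _v in _AA_TO_CODONS.values():
    _v.sort()
_STOP_CODONS = _AA_TO_CODONS["*"]


@dataclass
class PlantRequest:
    """One locus to plant: which family, from which reference protein, at
    what per-site nucleotide mutation rate."""

    gene_family: str
    protein_id: str | None = None
    nt_mutation_rate: float = 0.0
    contig_index: int | None = None


@dataclass
class PlantedLocus:
    gene_family: str
    contig_id: str
    start: int
    end: int  # half-open, includes the stop codon
    strand: str
    source_protein_id: str
    nt_mutation_rate: float
    nt_before_mutation: str = ""  # transcription-orientation, pre-mutation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CommunityProfile:
    """Relative abundances and per-cell expression rates at one depth."""

    depth_m: int
    taxa: list[tuple[str, float]]
    expression: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(a for _, a in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if any(a < 0 for _, a in self.taxa):
            raise ValueError("negative abundance")

    @property
    def abundance(self) -> dict[str, float]:
        return dict(self.taxa)


@dataclass
class TruthTable:
    """Ground truth for a simulated experiment."""

    loci: dict[str, list[PlantedLocus]] = field(default_factory=dict)
    abundances: dict[str, dict[str, float]] = field(default_factory=dict)
    transcript_rates: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    transcript_counts: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    genome_equivalents: dict[str, float] = field(default_factory=dict)


class ReadSet:
    """Simulated reads held as a code matrix for speed.

    Read ids encode their origin (sample|genome|contig|pos|strand|index),
    so every read is traceable to the position it was drawn from.
    """

    def __init__(self, ids: list[str], matrix: np.ndarray):
        assert len(ids) == matrix.shape[0]
        self.ids = ids
        self.matrix = matrix.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def read_len(self) -> int:
        return self.matrix.shape[1] if self.matrix.size else 0

    def sequences(self) -> list[str]:
        decoded = _NT_ARR[self.matrix]
        return [decoded[i].tobytes().decode() for i in range(decoded.shape[0])]

    def to_records(self) -> list[ReadRecord]:
        qual = [40] * self.read_len
        return [ReadRecord(id=i, residues=s, qualities=list(qual))
                for i, s in zip(self.ids, self.sequences())]

    def write_fastq(self, path) -> None:
        qual = "I" * self.read_len
        with open(path, "w") as fh:
            for i, s in zip(self.ids, self.sequences()):
                fh.write(f"@{i}\n{s}\n+\n{qual}\n")

    @classmethod
    def concatenate(cls, parts: list["ReadSet"]) -> "ReadSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls([], np.empty((0, 0), dtype=np.uint8))
        ids = [i for p in parts for i in p.ids]
        return cls(ids, np.vstack([p.matrix for p in parts]))

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        from .io_formats import read_fastq

        reads = read_fastq(path)
        if not reads:
            return cls([], np.empty((0, 0), dtype=np.uint8))
        n = max(len(r) for r in reads)
        mat = np.zeros((len(reads), n), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for i, c in enumerate("ACGT"):
            lut[ord(c)] = i
        for i, r in enumerate(reads):
            mat[i, :len(r)] = lut[np.frombuffer(r.residues.encode(), dtype=np.uint8)]
        return cls([r.id for r in reads], mat)


# ---------------------------------------------------------------------------
# Genome simulation

def back_translate(protein: str, gc_fraction: float,
                   rng: np.random.Generator) -> str:
    """Back-translate with synonymous codons weighted by the genome GC bias;
    appends a stop codon.  Codon weight is the product of per-base
    probabilities at the target GC."""
    p = {"A": (1 - gc_fraction) / 2, "T": (1 - gc_fraction) / 2,
         "G": gc_fraction / 2, "C": gc_fraction / 2}
    out = []
    for aa in protein + "*":
        codons = _AA_TO_CODONS[aa]
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out.append(codons[rng.choice(len(codons), p=w / w.sum())])
    return "".join(out)


def _protected_codons(protein: str) -> set[int]:
    """Codon indices under purifying selection: motif spans."""
    prot: set[int] = set()
    for m in match_hgcA_motif(protein):
        prot.update(range(m.position, m.position + len(m.matched)))
    for m in match_ferredoxin_motif(protein):
        prot.update(range(m.position, m.position + len(m.matched)))
    return prot


def mutate_coding(nt: str, rate: float, rng: np.random.Generator,
                  protected_codons: set[int] | None = None) -> str:
    """Point-mutate a coding sequence (stop codon included) at ``rate``.

    Protected codons accept only synonymous substitutions; elsewhere
    substitutions that would create an in-frame stop are redirected to a
    non-stop alternative; the terminal stop may only become another stop.
    Sites with no admissible substitution are skipped.
    """
    protected = protected_codons or set()
    seq = list(nt)
    n_codons = len(nt) // 3
    hit = np.flatnonzero(rng.random(len(nt)) < rate)
    for pos in hit:
        pos = int(pos)
        ci = pos // 3
        codon = "".join(seq[3 * ci:3 * ci + 3])
        off = pos % 3
        alts = []
        for b in _NT:
            if b == seq[pos]:
                continue
            cand = codon[:off] + b + codon[off + 1:]
            if ci == n_codons - 1:  # terminal stop stays a stop
                if cand in _STOP_CODONS:
                    alts.append(b)
            elif ci in protected:
                if _CODON_TO_AA[cand] == _CODON_TO_AA[codon]:
                    alts.append(b)
            else:
                if cand not in _STOP_CODONS:
                    alts.append(b)
        if alts:
            seq[pos] = alts[int(rng.integers(len(alts)))]
    return "".join(seq)


def _revcomp_str(s: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return s.translate(comp)[::-1]


def simulate_genome(seed: int, n_contigs: int, length_bp: int,
                    gc_fraction: float,
                    plant_spec: list[PlantRequest],
                    bin_id: str | None = None
                    ) -> tuple[GenomeBin, list[PlantedLocus]]:
    """Generate a genome of iid background nucleotides at the stated GC with
    the requested loci planted at non-overlapping positions.

    hgcA and hgcB requests are laid out as an operon: hgcB immediately
    downstream of hgcA on the same strand with an intergenic gap drawn
    uniformly from [0, 50] bp.
    """
    if not 0.2 <= gc_fraction <= 0.8:
        raise ValueError("gc_fraction outside [0.2, 0.8]")
    ss = np.random.SeedSequence(seed)
    rng_bg, rng_codon, rng_place, rng_mut = (
        np.random.default_rng(s) for s in ss.spawn(4))
    bin_id = bin_id or f"synth_{seed}"

    # background contigs
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    contigs = [rng_bg.choice(4, size=length_bp, p=p).astype(np.uint8)
               for _ in range(n_contigs)]

    # build locus blocks (operon pairing for hgcA+hgcB)
    reqs = list(plant_spec)
    hgcA_req = next((r for r in reqs if r.gene_family == "hgcA"), None)
    hgcB_req = next((r for r in reqs if r.gene_family == "hgcB"), None)
    blocks: list[list[PlantRequest]] = []
    if hgcA_req is not None and hgcB_req is not None:
        blocks.append([hgcA_req, hgcB_req])
        reqs = [r for r in reqs if r not in (hgcA_req, hgcB_req)]
    blocks.extend([r] for r in reqs)

    # materialise nucleotide sequences per block
    built = []
    for block in blocks:
        muts, raws, srcs, gaps = [], [], [], []
        for k, req in enumerate(block):
            rid, protein = reference_protein(req.gene_family, req.protein_id)
            raw = back_translate(protein, gc_fraction, rng_codon)
            mut = mutate_coding(raw, req.nt_mutation_rate, rng_mut,
                                _protected_codons(protein))
            muts.append(mut)
            raws.append(raw)
            srcs.append(rid)
            gaps.append(int(rng_place.integers(0, 51)) if k > 0 else 0)
        built.append((block, muts, srcs, gaps, raws))

    # place blocks on contigs
    edge_margin = 60
    cursors = [edge_margin] * n_contigs
    loci: list[PlantedLocus] = []
    for bi, (block, nts, srcs, gaps, raws) in enumerate(built):
        ci = block[0].contig_index if block[0].contig_index is not None else bi % n_contigs
        strand = "+" if rng_place.random() < 0.5 else "-"
        width = sum(len(s) for s in nts) + sum(gaps)
        spacing = int(rng_place.integers(80, 201))
        start = cursors[ci] + spacing
        if start + width + edge_margin > length_bp:
            raise ValueError(
                f"contig {ci} too short for requested loci "
                f"(need {start + width + edge_margin}, have {length_bp})")
        # block laid out in transcription order at `start`
        offsets = []
        off = 0
        for s, g in zip(nts, gaps):
            off += g
            offsets.append(off)
            off += len(s)
        for req, nt, raw, src, rel in zip(block, nts, raws, srcs, offsets):
            if strand == "+":
                lo = start + rel
                contigs[ci][lo:lo + len(nt)] = [_NT.index(c) for c in nt]
            else:
                # transcription right-to-left: first block member occupies the
                # rightmost slot in forward coordinates
                lo = start + width - rel - len(nt)
                rc = _revcomp_str(nt)
                contigs[ci][lo:lo + len(nt)] = [_NT.index(c) for c in rc]
            loci.append(PlantedLocus(
                gene_family=req.gene_family, contig_id=f"{bin_id}_c{ci}",
                start=lo, end=lo + len(nt), strand=strand,
                source_protein_id=src,
                nt_mutation_rate=req.nt_mutation_rate,
                nt_before_mutation=raw))
        cursors[ci] = start + width

    records = [SequenceRecord(id=f"{bin_id}_c{i}",
                              residues=_NT_ARR[c].tobytes().decode())
               for i, c in enumerate(contigs)]
    return GenomeBin(bin_id=bin_id, contigs=records), loci


def carrier_plant_spec(mutation_rate: float = 0.0,
                       merB: bool = False,
                       hgcA_ref: str | None = None) -> list[PlantRequest]:
    """Standard hgcA-carrier layout: hgcA+hgcB operon, housekeeping genes,
    and the five single-copy markers."""
    spec = [
        PlantRequest("hgcA", hgcA_ref, mutation_rate),
        PlantRequest("hgcB", None, mutation_rate),
        PlantRequest("rpoB", None, mutation_rate),
        PlantRequest("gyrB", None, mutation_rate),
    ]
    if merB:
        spec.append(PlantRequest("merB", None, mutation_rate))
    spec += [PlantRequest(m, None, mutation_rate)
             for m in ("marker_1", "marker_2", "marker_3", "marker_4", "marker_5")]
    return spec


def background_plant_spec(mutation_rate: float = 0.0,
                          merB: bool = False) -> list[PlantRequest]:
    """Non-carrier layout: housekeeping + markers only (optionally merB)."""
    spec = [
        PlantRequest("rpoB", None, mutation_rate),
        PlantRequest("gyrB", None, mutation_rate),
    ]
    if merB:
        spec.append(PlantRequest("merB", None, mutation_rate))
    spec += [PlantRequest(m, None, mutation_rate)
             for m in ("marker_1", "marker_2", "marker_3", "marker_4", "marker_5")]
    return spec


# ---------------------------------------------------------------------------
# Read simulation

def _apply_errors(mat: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    if error_rate <= 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
    mat = mat.copy()
    mat[mask] = (mat[mask] + shift[mask]) % 4
    return mat


def simulate_metagenome_reads(genomes: dict[str, GenomeBin],
                              depth_of_coverage_map: dict[str, float],
                              read_len: int = 100,
                              error_rate: float = 0.0,
                              seed: int = 0,
                              sample_id: str = "s0") -> ReadSet:
    """Uniform shotgun reads per genome at the prescribed coverages.

    Per-genome read count is round(coverage x genome_length / read_len);
    start positions are uniform over valid positions across contigs; strand
    is random; substitution errors are iid at ``error_rate``.
    """
    if read_len < 50:
        raise ValueError("read_len must be >= 50")
    if error_rate >= 0.05:
        raise ValueError("error_rate must be < 0.05")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parts: list[ReadSet] = []
    lut = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    for gid in sorted(depth_of_coverage_map):
        cov = depth_of_coverage_map[gid]
        gb = genomes[gid]
        n_reads = int(round(cov * gb.total_length / read_len))
        if n_reads == 0:
            continue
        contig_codes = [lut[np.frombuffer(c.residues.encode(), dtype=np.uint8)]
                        for c in gb.contigs]
        valid = np.array([max(0, len(c) - read_len + 1) for c in contig_codes])
        if valid.sum() == 0:
            raise ValueError(f"genome {gid}: all contigs shorter than read_len")
        ci = rng.choice(len(contig_codes), size=n_reads, p=valid / valid.sum())
        ids = []
        rows = np.empty((n_reads, read_len), dtype=np.uint8)
        pos_all = np.empty(n_reads, dtype=np.int64)
        for k in range(len(contig_codes)):
            sel = np.flatnonzero(ci == k)
            if sel.size == 0:
                continue
            pos = rng.integers(0, valid[k], size=sel.size)
            pos_all[sel] = pos
            rows[sel] = contig_codes[k][pos[:, None] + np.arange(read_len)]
        minus = rng.random(n_reads) < 0.5
        rows[minus] = 3 - rows[minus][:, ::-1]
        rows = _apply_errors(rows, error_rate, rng)
        ids = [f"{sample_id}|{gid}|{gb.contigs[int(c)].id}|{int(p)}|"
               f"{'-' if m else '+'}|{j}"
               for j, (c, p, m) in enumerate(zip(ci, pos_all, minus))]
        parts.append(ReadSet(ids, rows))
    return ReadSet.concatenate(parts)


def simulate_transcriptome_reads(profile: CommunityProfile,
                                 genomes: dict[str, GenomeBin],
                                 loci: dict[str, list[PlantedLocus]],
                                 library_size_factor: float,
                                 read_len: int = 100,
                                 error_rate: float = 0.0,
                                 seed: int = 0,
                                 sample_id: str = "t0"
                                 ) -> tuple[ReadSet, dict[tuple[str, str], int]]:
    """Transcript reads from annotated loci only.

    For genome g at abundance a_g and gene family f with per-cell rate
    r_{g,f}, the read count is Poisson(r_{g,f} x a_g x library_size_factor);
    positions are uniform within the transcript (sense strand).  Returns
    the reads and the true per-(genome, family) counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    abund = profile.abundance
    parts: list[ReadSet] = []
    counts: dict[tuple[str, str], int] = {}
    lut = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    for gid in sorted(genomes):
        rates = profile.expression.get(gid, {})
        a = abund.get(gid, 0.0)
        for locus in loci.get(gid, []):
            rate = rates.get(locus.gene_family)
            if rate is None:
                continue
            lam = rate * a * library_size_factor
            n = int(rng.poisson(lam)) if lam > 0 else 0
            counts[(gid, locus.gene_family)] = counts.get(
                (gid, locus.gene_family), 0) + n
            if n == 0:
                continue
            contig = next(c for c in genomes[gid].contigs
                          if c.id == locus.contig_id)
            nt = contig.residues[locus.start:locus.end]
            if locus.strand == "-":
                nt = _revcomp_str(nt)
            codes = lut[np.frombuffer(nt.encode(), dtype=np.uint8)]
            if len(codes) < read_len:
                raise ValueError(
                    f"locus {locus.gene_family} in {gid} shorter than read_len")
            pos = rng.integers(0, len(codes) - read_len + 1, size=n)
            rows = codes[pos[:, None] + np.arange(read_len)]
            rows = _apply_errors(rows, error_rate, rng)
            ids = [f"{sample_id}|{gid}|{locus.gene_family}|{int(p)}|+|{j}"
                   for j, p in enumerate(pos)]
            parts.append(ReadSet(ids, rows))
    return ReadSet.concatenate(parts), counts


# ---------------------------------------------------------------------------
# Default study conditions

#: per-depth relative abundances of the five default genomes.  Carriers and
#: the merB genome increase with depth and peak at 200 m, the observed
#: pattern for methylator/demethylator abundance across the redoxcline.
_DEFAULT_ABUNDANCE: dict[int, tuple[float, ...]] = {
    # depth: (methylator_marini, methylator_delta, demethylator, bg_low_gc, bg_high_gc)
    10:  (0.005, 0.005, 0.002, 0.600, 0.388),
    100: (0.010, 0.008, 0.004, 0.550, 0.428),
    120: (0.015, 0.010, 0.005, 0.500, 0.470),
    135: (0.018, 0.012, 0.005, 0.480, 0.485),
    150: (0.020, 0.014, 0.006, 0.450, 0.510),
    200: (0.025, 0.018, 0.008, 0.400, 0.549),
}

_DEFAULT_GENOME_SPECS = (
    # (genome_id, gc, carrier, merB)
    ("methylator_marini", 0.42, True, False),
    ("methylator_delta", 0.55, True, False),
    ("demethylator", 0.48, False, True),
    ("bg_low_gc", 0.38, False, False),
    ("bg_high_gc", 0.62, False, False),
)

#: constitutive per-cell expression: hgcA and merB transcribed at a fixed
#: rate wherever expressed, but silent at 10 m (no transcripts are recovered
#: from the oxygenated surface); housekeeping genes always on.
_HGCA_RATE = 0.5
_MERB_RATE = 0.5
_HOUSEKEEPING_RATE = 1.0


def default_community(seed: int = 0, length_bp: int = 20000,
                      mutation_rate: float = 0.02
                      ) -> tuple[dict[str, GenomeBin],
                                 dict[str, list[PlantedLocus]],
                                 list[CommunityProfile]]:
    """Build the default five-genome community and its six-depth profiles."""
    ss = np.random.SeedSequence(seed).spawn(len(_DEFAULT_GENOME_SPECS))
    genomes: dict[str, GenomeBin] = {}
    loci: dict[str, list[PlantedLocus]] = {}
    for child, (gid, gc, carrier, merB) in zip(ss, _DEFAULT_GENOME_SPECS):
        spec = (carrier_plant_spec(mutation_rate)
                if carrier else background_plant_spec(mutation_rate, merB=merB))
        gseed = int(child.generate_state(1)[0] % (2**31))
        gb, gl = simulate_genome(gseed, 1, length_bp, gc, spec, bin_id=gid)
        genomes[gid] = gb
        loci[gid] = gl

    profiles = []
    for depth, fracs in _DEFAULT_ABUNDANCE.items():
        taxa = [(gid, f) for (gid, *_), f in zip(_DEFAULT_GENOME_SPECS, fracs)]
        expression = {}
        for gid, _, carrier, merB in _DEFAULT_GENOME_SPECS:
            e = {"rpoB": _HOUSEKEEPING_RATE, "gyrB": _HOUSEKEEPING_RATE}
            if carrier:
                e["hgcA"] = 0.0 if depth == 10 else _HGCA_RATE
                e["hgcB"] = 0.0 if depth == 10 else _HGCA_RATE
            if merB:
                e["merB"] = 0.0 if depth == 10 else _MERB_RATE
            expression[gid] = e
        profiles.append(CommunityProfile(depth_m=depth, taxa=taxa,
                                         expression=expression))
    return genomes, loci, profiles
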