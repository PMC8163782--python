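"""Simulator contracts: determinism, mutation statistics, read models."""

import numpy as np
import pytest
from scipy import stats

from hgc_profiler.gene_screen import match_hgcA_motif, revcomp, translate
from hgc_profiler.synthetic_community import (CommunityProfile, PlantRequest,
                                              background_plant_spec,
                                              carrier_plant_spec,
                                              default_community,
                                              simulate_genome,
                                              simulate_metagenome_reads,
                                              simulate_transcriptome_reads)


def _locus_nt(gb, locus):
    contig = next(c for c in gb.contigs if c.id == locus.contig_id)
    nt = contig.residues[locus.start:locus.end]
    return revcomp(nt) if locus.strand == "-" else nt


class TestSimulateGenome:
    def test_same_seed_identical(self):
        a = simulate_genome(3, 2, 6000, 0.45, carrier_plant_spec(0.02))
        b = simulate_genome(3, 2, 6000, 0.45, carrier_plant_spec(0.02))
        assert [c.residues for c in a[0].contigs] == [c.residues for c in b[0].contigs]
        assert a[1] == b[1]

    def test_rate_zero_preserves_motif_and_frame(self):
        gb, loci = simulate_genome(4, 1, 8000, 0.35, carrier_plant_spec(0.0))
        hgcA = next(l for l in loci if l.gene_family == "hgcA")
        nt = _locus_nt(gb, hgcA)
        aa = translate(nt)
        assert aa.endswith("*")
        assert match_hgcA_motif(aa)
        assert nt == hgcA.nt_before_mutation
        assert (hgcA.end - hgcA.start) % 3 == 0

    def test_operon_layout(self):
        for seed in range(6):
            _, loci = simulate_genome(20 + seed, 1, 8000, 0.5,
                                      carrier_plant_spec(0.0))
            a = next(l for l in loci if l.gene_family == "hgcA")
            b = next(l for l in loci if l.gene_family == "hgcB")
            assert a.strand == b.strand and a.contig_id == b.contig_id
            gap = b.start - a.end if a.strand == "+" else a.start - b.end
            assert 0 <= gap <= 50

    def test_substitution_count_binomial(self):
        """rpoB locus (903 nt) at rate 0.02: total substitutions over 100
        seeds must fall in the binomial 99% interval."""
        rate, n_seeds = 0.02, 100
        total = 0
        L = None
        for s in range(n_seeds):
            gb, loci = simulate_genome(900 + s, 1, 2000, 0.5,
                                       [PlantRequest("rpoB", None, rate)])
            locus = loci[0]
            nt = _locus_nt(gb, locus)
            L = len(nt)
            total += sum(x != y for x, y in zip(nt, locus.nt_before_mutation))
        lo, hi = stats.binom.interval(0.99, n_seeds * L, rate)
        assert lo <= total <= hi

    def test_functional_locus_stays_callable_under_mutation(self):
        gb, loci = simulate_genome(7, 1, 8000, 0.45, carrier_plant_spec(0.04))
        hgcA = next(l for l in loci if l.gene_family == "hgcA")
        aa = translate(_locus_nt(gb, hgcA))
        assert aa.endswith("*")
        assert "*" not in aa[:-1]          # purifying selection: no nonsense
        assert match_hgcA_motif(aa)        # motif conserved

    def test_contig_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(1, 1, 900, 0.5, carrier_plant_spec(0.0))

    def test_gc_bounds(self):
        with pytest.raises(ValueError, match="gc_fraction"):
            simulate_genome(1, 1, 5000, 0.1, [])


class TestMetagenomeReads:
    def test_coverage_read_count_identity(self):
        gb, _ = simulate_genome(2, 1, 6000, 0.5, [])
        rs = simulate_metagenome_reads({"g": gb}, {"g": 10.0}, read_len=150,
                                       seed=1)
        assert len(rs) == round(10.0 * gb.total_length / 150)

    def test_error_free_reads_are_substrings(self):
        gb, _ = simulate_genome(2, 1, 6000, 0.5, [])
        genome = gb.contigs[0].residues
        rs = simulate_metagenome_reads({"g": gb}, {"g": 2.0}, read_len=100,
                                       error_rate=0.0, seed=5)
        for seq in rs.sequences()[:50]:
            assert seq in genome or revcomp(seq) in genome

    def test_reads_traceable_to_position(self):
        gb, _ = simulate_genome(2, 1, 6000, 0.5, [])
        genome = gb.contigs[0].residues
        rs = simulate_metagenome_reads({"g": gb}, {"g": 1.0}, read_len=100,
                                       error_rate=0.0, seed=6, sample_id="sx")
        for rid, seq in zip(rs.ids[:20], rs.sequences()[:20]):
            _, gid, contig, pos, strand, _ = rid.split("|")
            piece = genome[int(pos):int(pos) + 100]
            assert seq == (piece if strand == "+" else revcomp(piece))

    def test_determinism(self):
        gb, _ = simulate_genome(2, 1, 6000, 0.5, [])
        a = simulate_metagenome_reads({"g": gb}, {"g": 3.0}, seed=9)
        b = simulate_metagenome_reads({"g": gb}, {"g": 3.0}, seed=9)
        assert a.ids == b.ids and np.array_equal(a.matrix, b.matrix)

    def test_config_validation(self):
        gb, _ = simulate_genome(2, 1, 6000, 0.5, [])
        with pytest.raises(ValueError):
            simulate_metagenome_reads({"g": gb}, {"g": 1.0}, read_len=30)
        with pytest.raises(ValueError):
            simulate_metagenome_reads({"g": gb}, {"g": 1.0}, error_rate=0.1)


def _toy_expression_setup(seed=0):
    gb, loci = simulate_genome(seed, 1, 4000, 0.5,
                               [PlantRequest("rpoB", None, 0.0)])
    genomes = {"g": gb}
    all_loci = {"g": loci}
    return genomes, all_loci


class TestTranscriptomeReads:
    def test_zero_rate_zero_reads(self):
        """A silenced gene yields no transcript reads (as at 10 m depth)."""
        genomes, loci = _toy_expression_setup()
        prof = CommunityProfile(10, [("g", 1.0)],
                                {"g": {"rpoB": 0.0}})
        rs, counts = simulate_transcriptome_reads(prof, genomes, loci, 1e4,
                                                  seed=1)
        assert len(rs) == 0 and counts[("g", "rpoB")] == 0

    def test_expected_count_linear_in_rate_and_abundance(self):
        genomes, loci = _toy_expression_setup()
        def count(rate, abund, seed):
            taxa = [("g", abund)] if abund == 1.0 else [("g", abund),
                                                        ("pad", 1 - abund)]
            prof = CommunityProfile(100, taxa, {"g": {"rpoB": rate}})
            _, c = simulate_transcriptome_reads(prof, genomes, loci, 4e3,
                                                seed=seed)
            return c[("g", "rpoB")]
        base = count(1.0, 0.5, 3)
        double_rate = count(2.0, 0.5, 4)
        double_abund = count(1.0, 1.0, 5)
        assert 1.8 <= double_rate / base <= 2.2
        assert 1.8 <= double_abund / base <= 2.2

    def test_poisson_dispersion(self):
        """Across 200 seeds the per-replicate count index of dispersion
        (var/mean) is ~1."""
        genomes, loci = _toy_expression_setup()
        prof = CommunityProfile(100, [("g", 1.0)], {"g": {"rpoB": 1.0}})
        counts = [simulate_transcriptome_reads(prof, genomes, loci, 5.0,
                                               seed=s)[1][("g", "rpoB")]
                  for s in range(200)]
        counts = np.array(counts, dtype=float)
        iod = counts.var(ddof=1) / counts.mean()
        assert 0.72 <= iod <= 1.35


class TestDefaultCommunity:
    def test_six_depths_and_profiles(self):
        genomes, loci, profiles = default_community(seed=1, length_bp=16000)
        assert [p.depth_m for p in profiles] == [10, 100, 120, 135, 150, 200]
        for p in profiles:
            assert abs(sum(a for _, a in p.taxa) - 1.0) < 1e-9
        # carriers silent at 10 m, constitutive elsewhere
        surface = profiles[0]
        assert surface.expression["methylator_marini"]["hgcA"] == 0.0
        deep = profiles[-1]
        assert deep.expression["methylator_marini"]["hgcA"] > 0
        # carrier abundance peaks at 200 m
        marini = {p.depth_m: dict(p.taxa)["methylator_marini"]
                  for p in profiles}
        assert marini[200] == max(marini.values())
        # exactly one hgcA per carrier genome
        for gid, gl in loci.items():
            n_hgcA = sum(1 for l in gl if l.gene_family == "hgcA")
            assert n_hgcA == (1 if gid.startswith("methylator") else 0)
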