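"""Gene screening: ORFs, homology search, motifs, synteny, composite calls."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from hgc_profiler import alignment
from hgc_profiler.gene_screen import (ScreenParams, call_hgc_genes,
                                      check_hgcB_synteny, find_orfs,
                                      match_ferredoxin_motif,
                                      match_hgcA_motif, search_homologs)
from hgc_profiler.io_formats import GenomeBin, SequenceRecord
from hgc_profiler.references import default_reference_panel, reference_protein
from hgc_profiler.synthetic_community import (back_translate,
                                              background_plant_spec,
                                              carrier_plant_spec,
                                              simulate_genome)

from conftest import random_dna, random_protein


class TestOrfs:
    def test_minimal_gene(self):
        orfs = find_orfs("ATGAAATAA", min_aa_len=2)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.strand, o.aa_sequence) == (0, 9, "+", "MK")

    def test_strand_symmetry(self):
        rc = str(Seq("ATGAAATAA").reverse_complement())
        orfs = find_orfs(rc, min_aa_len=2)
        assert len(orfs) == 1
        o = orfs[0]
        assert o.strand == "-" and o.aa_sequence == "MK"
        assert (o.start, o.end) == (0, 9)

    def test_coordinates_retranslate_to_aa(self):
        rng = np.random.default_rng(42)
        contig = random_dna(rng, 10000)
        for o in find_orfs(contig, min_aa_len=30):
            nt = contig[o.start:o.end]
            if o.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            # independent translation oracle (table 11)
            aa = str(Seq(nt).translate(table=11))
            assert aa == o.aa_sequence + "*"
            assert "*" not in o.aa_sequence
            assert (o.end - o.start) % 3 == 0
            assert len(o.aa_sequence) >= 30


class TestMotifs:
    @pytest.mark.parametrize("seq,expected", [
        ("NVWCAAGK", [0]),
        ("NIWCGAGK", []),          # position 4 must be A
        ("XXNVWCAAGKXXNIWCAGGK", [2, 12]),
    ])
    def test_cap_helix_examples(self, seq, expected):
        assert [m.position for m in match_hgcA_motif(seq)] == expected

    def test_cap_helix_exact_degenerate_set(self):
        expansions = ["".join(t) for t in itertools.product(
            "N", "VI", "W", "C", "A", "AG", "AG", "K")]
        assert len(expansions) == 8
        assert all(len(match_hgcA_motif(e)) == 1 for e in expansions)
        # every single-position violation is rejected
        allowed = ["N", "VI", "W", "C", "A", "AG", "AG", "K"]
        for e in expansions:
            for pos, ok in enumerate(allowed):
                for sub in "LNVIWCAGK":
                    if sub in ok:
                        continue
                    bad = e[:pos] + sub + e[pos + 1:]
                    assert match_hgcA_motif(bad) == [], bad

    @pytest.mark.parametrize("seq,expected", [
        ("CAACDDCAAAC", [0]),
        ("CAACDDCAAC", []),        # final gap is 2, needs 3
        ("CAACAACAAAC" + "CAACAACAAAC", [0, 11]),
    ])
    def test_ferredoxin_examples(self, seq, expected):
        assert [m.position for m in match_ferredoxin_motif(seq)] == expected

    def test_ferredoxin_matches_brute_force(self):
        # exhaustive over all length-11 strings on {C, A, D}
        def naive(s):
            hits = []
            for i in range(len(s) - 10):
                w = s[i:i + 11]
                if w[0] == w[3] == w[6] == w[10] == "C":
                    hits.append(i)
            return hits

        for t in itertools.product("CAD", repeat=11):
            s = "".join(t)
            assert [m.position for m in match_ferredoxin_motif(s)] == naive(s)

    def test_overlapping_matches_reported(self):
        s = "CCAACCACAAACAAC"  # motifs starting at 1 and 4 overlap
        naive = [i for i in range(len(s) - 10)
                 if s[i] == s[i + 3] == s[i + 6] == s[i + 10] == "C"]
        assert [m.position for m in match_ferredoxin_motif(s)] == naive


class TestHomologySearch:
    def test_self_hit_score_is_blosum_diagonal_sum(self, sw_oracle):
        # "NVWCAAGK" against itself: 6+4+11+9+4+4+6+5 = 49
        q = "NVWCAAGK"
        params = ScreenParams(score_threshold=20, min_reference_coverage=0.5)
        hits = search_homologs(q, {"ref": q}, params)
        assert len(hits) == 1
        assert hits[0].raw_score == 49
        assert hits[0].raw_score == sw_oracle.score(q, q)
        assert hits[0].percent_identity == 100.0

    def test_seed_filter_rejects_unrelated(self):
        hits = search_homologs("AAAAAAAAAA", {"ref": "WWWWWWWWWW"},
                               ScreenParams(score_threshold=0))
        assert hits == []

    def test_banded_equals_full_matrix_on_short_pairs(self, sw_oracle):
        rng = np.random.default_rng(7)
        params = ScreenParams(score_threshold=1, min_reference_coverage=0.0)
        for _ in range(60):
            ref = random_protein(rng, int(rng.integers(12, 26)))
            # query: reference with a couple of substitutions, so seeds exist
            q = list(ref)
            for i in rng.choice(len(ref), size=2, replace=False):
                q[i] = random_protein(rng, 1)
            q = "".join(q)
            hits = search_homologs(q, {"r": ref}, params)
            full = alignment.local_align(q, ref)
            if hits:
                assert hits[0].raw_score == full.score == sw_oracle.score(q, ref)

    def test_empty_query(self):
        assert search_homologs("", {"r": "MKW"}) == []

    def test_sorting_deterministic(self):
        q = reference_protein("hgcA")[1]
        panel = default_reference_panel()["hgcA"]
        hits = search_homologs(q, panel, ScreenParams(score_threshold=30))
        scores = [h.raw_score for h in hits]
        assert scores == sorted(scores, reverse=True)


def _operon_contig(gap: int, hgcB_strand_flip: bool = False,
                   hgcB_offset: int | None = None, seed: int = 0) -> str:
    """Contig with a forward hgcA and an hgcB placed ``gap`` bp after it."""
    rng = np.random.default_rng(seed)
    a_nt = back_translate(reference_protein("hgcA")[1], 0.5, rng)
    b_nt = back_translate(reference_protein("hgcB")[1], 0.5, rng)
    if hgcB_strand_flip:
        b_nt = alignment.revcomp(b_nt)
    left = random_dna(rng, 120)
    spacer = random_dna(rng, gap)
    right = random_dna(rng, 150)
    if hgcB_offset is not None:
        spacer = random_dna(rng, hgcB_offset)
    return left + a_nt + spacer + b_nt + right


class TestSynteny:
    def _hgcA_orf(self, orfs):
        return next(o for o in orfs if match_hgcA_motif(o.aa_sequence))

    def test_operon_detected(self):
        contig = _operon_contig(gap=25)
        orfs = find_orfs(contig)
        refs = default_reference_panel()["hgcB"]
        assert check_hgcB_synteny(self._hgcA_orf(orfs), orfs, refs)

    def test_opposite_strand_rejected(self):
        contig = _operon_contig(gap=25, hgcB_strand_flip=True)
        orfs = find_orfs(contig)
        refs = default_reference_panel()["hgcB"]
        assert not check_hgcB_synteny(self._hgcA_orf(orfs), orfs, refs)

    def test_distance_threshold_semantics(self):
        contig = _operon_contig(gap=0, hgcB_offset=10000)
        orfs = find_orfs(contig)
        refs = default_reference_panel()["hgcB"]
        hgcA = self._hgcA_orf(orfs)
        assert not check_hgcB_synteny(hgcA, orfs, refs)  # default 500 bp
        assert check_hgcB_synteny(hgcA, orfs, refs, max_intergenic_bp=20000,
                                  max_gene_skip=1000)


class TestCompositeCalls:
    def test_carrier_positive_control(self):
        gb, _ = simulate_genome(5, 1, 8000, 0.45, carrier_plant_spec(0.0))
        calls = call_hgc_genes(gb)
        types = sorted(c.call_type for c in calls)
        assert types == ["hgcA", "hgcB"]
        hgcA = next(c for c in calls if c.call_type == "hgcA")
        assert hgcA.motifs and hgcA.motifs[0].pattern_id == "hgcA_cap_helix"
        hgcB = next(c for c in calls if c.call_type == "hgcB")
        assert hgcB.synteny_ok is True

    @pytest.mark.parametrize("seed", range(5))
    def test_non_carrier_yields_no_calls(self, seed):
        gb, _ = simulate_genome(1000 + seed, 1, 8000, 0.45,
                                background_plant_spec(0.0))
        assert [c for c in call_hgc_genes(gb)
                if c.call_type in ("hgcA", "hgcB", "hgcB_like", "merB")] == []

    def test_lone_tandem_ferredoxin_is_hgcB_like(self):
        from hgc_profiler.synthetic_community import PlantRequest
        gb, _ = simulate_genome(6, 1, 6000, 0.45,
                                [PlantRequest("hgcB", None, 0.0)])
        calls = call_hgc_genes(gb)
        assert [c.call_type for c in calls] == ["hgcB_like"]
        assert len(calls[0].motifs) >= 2

    def test_merB_called_on_homology_alone(self):
        gb, _ = simulate_genome(8, 1, 8000, 0.5,
                                background_plant_spec(0.01, merB=True))
        calls = call_hgc_genes(gb)
        assert [c.call_type for c in calls] == ["merB"]
        assert calls[0].motifs == []
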