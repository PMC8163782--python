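# Methods

This note documents the models implemented in hgc-profiler, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that affect edge cases.

## Gene screening

**ORF model.** All six frames are scanned; an ORF runs from the first
ATG/GTG/TTG start codon after an in-frame stop (or the contig edge) to the
next in-frame stop, which is included in the reported 0-based half-open
interval; reading frames that never terminate yield nothing. Translation
uses the bacterial/archaeal code (table 11); ambiguous codons translate to
X. There is no ribosome-binding-site model: exact gene boundaries do not
drive any downstream arithmetic, only coordinates and protein content do.
A consequence worth knowing: a fortuitous in-frame start upstream of a
planted gene can extend an ORF's N-terminus; homology coverage and motif
detection are insensitive to this. Minimum ORF length is 30 aa (below the
length of the shortest target family, HgcB at ~95 aa, with margin for
truncated genes).

**Homology search.** Candidate references must share ≥ 2 distinct protein
4-mers with the query; survivors are scored by Smith–Waterman with BLOSUM62
and affine gaps costing 11 + L for a gap of length L, restricted to a band
around the seed diagonals (± 16). Hits require raw score ≥ 60 and ≥ 50%
reference coverage. These two thresholds mainly control candidate volume:
final calls are gated by motif and synteny evidence, so the pipeline is not
sensitive to their exact values. Ties are always broken score-descending
then lexicographically by reference id, making output order reproducible.

**Motif confirmation.** The HgcA cap-helix motif N[VI]WCA[AG][AG]K (8
degenerate expansions) and the HgcB ferredoxin motif C.{2}C.{2}C.{3}C are
matched exactly, all overlapping occurrences reported. An HgcA-homologous
ORF without the cap-helix motif is recorded as `paralog_like` — known
paralogs in non-methylating organisms pass homology but lack the catalytic
cysteine context — and never counts as *hgcA*.

**Synteny.** A *hgcB* call requires a ferredoxin-motif-bearing,
HgcB-homologous ORF downstream of *hgcA* on the same strand within 500 bp
and at most one intervening ORF. "Downstream" tolerates ORFs whose
(possibly fortuitous) start codon reaches back into *hgcA*, as long as the
body extends downstream. ORFs with ≥ 2 ferredoxin motifs ("tandem") but no
*hgcA* context are classified `hgcB_like`; we interpret "tandem" as
co-occurrence within one ORF, not strict adjacency. A single-motif,
non-syntenic HgcB homolog is dropped as insufficient evidence. *merB* is
called on homology alone — the lyase has no short diagnostic motif in this
framework.

## Reference panel

The curated reference protein sets behind the homology search are
pluggable (any protein FASTA with `family=` header tags). The built-in
panel (`references.py`) is synthetic: deterministic random proteins with
the conserved features embedded where biology puts them — cap-helix motif
in HgcA's N-terminal globular half, two tandem ferredoxin motifs plus a
C-terminal CC tail in HgcB — with ~15% within-family divergence so that
homology search operates in a realistic regime. It is a stand-in, not a
curated database; real analyses should supply experimentally validated
sequences.

## Synthetic community generator

The generator is the package's instrument for validating every stage, and
its defaults encode the study conditions it emulates:

* a six-depth gradient (10, 100, 120, 135, 150, 200 m) in which carriers
  and the *merB* genome increase with depth and peak at 200 m;
* exactly one *hgcA* copy per carrier genome, with *hgcB* planted
  immediately downstream (intergenic gap uniform on [0, 50] bp, same
  strand);
* constitutive expression: per-cell transcription rates are
  depth-independent (hgcA and merB rates 0.5, housekeeping 1.0, in
  arbitrary per-cell units), except at 10 m where *hgcA* and *merB* are
  silent — mirroring the absence of recovered transcripts at the
  oxygenated surface;
* five single-copy marker families per genome backing the
  genome-equivalents estimator.

**Back-translation.** Planted proteins are reverse-translated choosing
synonymous codons weighted by the genome's GC content (codon weight =
product of per-base probabilities at the target GC). This keeps planted
genes compositionally similar to their host, so the TNF/SOM verification
test is not trivially passed by composition contrast between gene and
background.

**Mutation model (purifying selection).** Each planted locus is
point-mutated at its per-site rate, with three constraints that mirror how
real homologs of functional genes diverge: substitutions at motif-encoding
codons must be synonymous (the conserved motifs are under strong
purifying selection — an *hgcA* with a broken cap-helix is not an *hgcA*
gene, it is a pseudogene); substitutions that would create a premature
in-frame stop are redirected to a non-stop alternative; and the terminal
stop codon may only become another stop. Sites with no admissible change
are skipped. The realized substitution count therefore tracks the nominal
Binomial(L, rate) closely (verified against the binomial 99% interval in
the tests); the skipped-site deficit is well under 1%. Without these
constraints a detection-recall experiment at rates near 0.05 would mostly
measure the rate of simulated pseudogenization (≈ 70% motif loss and ≈ 2
expected nonsense mutations per kb), not detector performance.

**Read models.** Metagenome reads: per-genome count = round(coverage ×
genome length / read length), uniform start positions, random strand, iid
substitution errors (no indels). Transcriptome reads are emitted only from
annotated loci: counts are Poisson(per-cell rate × carrier abundance ×
library size factor), positions uniform within the transcript, sense
strand. There is no overdispersion knob, no paired-end insert model, and
no strain microdiversity; these are deliberate non-goals of v1. Read ids
encode (sample, genome, contig, position, strand), so every read is
traceable. All randomness flows from a single seed through named child
streams; identical configurations reproduce byte-identical FASTQ.

What passing tests on this generator do **not** show about real data:
real communities have thousands of genomes, uneven coverage (GC bias,
edge effects at repeats), indel-bearing reads, partial and contaminated
bins, and reference databases that are incomplete for novel clades. The
generator validates the arithmetic and the evidence logic, not robustness
to those factors.

## SOM verification

Fragments are 5 kb non-overlapping windows (trailing piece kept if ≥ 2 kb);
each is reduced to frequencies of overlapping 4-mers on the given strand
(no reverse-complement collapsing, matching the single-strand TNF
convention of emergent-SOM binning workflows; collapsing is available via
the matcher's caller). Windows containing N are skipped; a fragment with no
valid window is an error, never a silent zero.

The map is a toroidal grid trained with the batch algorithm: per epoch,
assign every vector to its best-matching unit (Euclidean; ties to the
lowest unit index), then replace each codebook vector with the Gaussian-
neighborhood-weighted mean of the data. The radius anneals linearly from
max(rows, cols)/4 to 0.5. The codebook is initialised by sampling input
vectors with the run seed. The per-epoch quantization error (mean distance
to the BMU after the update) is recorded and is non-increasing in practice;
the tests assert it per epoch.

**Coherence.** For each fragment of the contig under test, take the k = 8
nearest fragments of *other* contigs, measured by distance between BMU
codebook vectors (ties broken by raw TNF distance); the fragment is
coherent if > 50% of those neighbors belong to the contig's claimed bin.
Coherence is the fraction of coherent fragments; the default pass
threshold is 0.6. Codebook-vector distance is used rather than toroidal
grid distance deliberately: small maps can fold topologically, placing
compositionally distant units on adjacent grid nodes, and the
codebook-space neighborhood is immune to that. A contig with no foreign
fragments on the map is trivially coherent (1.0). Excluding the target
contig's own fragments from the vote is essential — otherwise a
foreign-spliced contig would vouch for itself.

The grid size, window, neighborhood and coherence statistic are this
package's choices (the workflow it automates relies on an external GUI
tool and a manual check); all are configurable.

## Clustering

Identity = identical aligned positions / length of the shorter sequence,
from a global alignment with match +1, mismatch −1, gap −2; among
score-optimal alignments the one maximising identical positions defines
the count, which makes identity a well-defined function of the pair (the
DP tracks max matches over optimal paths). Greedy clustering visits
sequences longest-first (ties by id) and joins the first cluster whose
representative matches at ≥ threshold (default 0.99). The representative
is therefore always the longest member — a deliberate departure from
arbitrary selection, for determinism — and re-clustering representatives
yields singletons (asserted).

## Quantification

**Recruitment.** Shared 15-mers (both read orientations vs forward
targets) propose (target, strand, diagonal) candidates; the read's
overlapping part is aligned to the target window by edit distance
(edlib), requiring identity ≥ 0.95 over ≥ 90% of the read; each read
counts once for its single best target (ties lexicographic). Mates are
treated independently.

**Edge-corrected mean depth.** Because reads overlapping a target by less
than 90% of their length are never recruited, a target's ends
systematically collect fewer aligned bases, and the deficit is larger for
shorter targets. Mean depth therefore divides total aligned bases by an
*effective length* — the expected aligned bases per unit coverage under
uniform read starts — rather than the raw length. This removes a
length-dependent bias of up to ~20% (600 bp marker, 150 bp reads) and
makes gene-vs-marker depth ratios unbiased; it is asserted by the
genome-equivalents recovery tests.

**Genome equivalents.** Mean over single-copy marker families of the
family's summed depth across per-genome marker targets. Each genome
carries each marker once, so summed marker depth counts genome copies
sampled; genome copies add (two genomes at 4× and 6× give 10). This is a
marker-based estimator standing in for average-genome-size tools, chosen
because it needs nothing but the marker targets and validates directly on
simulations; it shares the same invariance purpose (abundance becomes
independent of sequencing depth).

**Abundance and expression.** Relative abundance = 100 × gene depth /
genome equivalents — under the single-copy assumption, the percentage of
community genomes carrying the gene. RPKM uses the reads mapped to the
full target panel as the library size (the panel should therefore include
the community's housekeeping targets; a whole-library denominator is a
caller choice — pass total reads instead). Expression ratios pair each
gene with its own genome's *rpoB*/*gyrB* (per-organism normalisation);
a zero housekeeping RPKM flags the ratio undefined (None) rather than
returning infinity. Depth profiles report per-(family, depth) means with
Student-t 95% CIs; a single sample yields a flagged undefined CI.

## Problem sizes used in the tests and acceptance script

Desk-scale by design: genomes of 8–15 kb with one locus per family,
communities of 4–5 genomes, 100 bp reads. Detection recall/specificity
use 100 carriers (mutation rates 0–0.05) and 100 non-carriers; SOM
verification uses two genomes at GC 0.35 vs 0.60 (six 15 kb contigs each)
over five seeds; abundance recovery plants carriers at 0.5/2/10% in a
sample of 2000 genome copies (≈ 240k reads) so the rarest carrier's
markers see ≥ 10× coverage; the constitutive-expression experiment raises
carrier abundance 2→10% over five mock depths at a fixed per-cell rate
(≈ 50k transcript reads per sample). These sizes make every experiment
reproducible in minutes on one CPU while keeping counting noise small
relative to the tolerances tested.

## Known limitations

* The mapper is substitution-oriented; indel-rich platforms would need
  looser banding and an indel-aware identity definition.
* Genome equivalents assume the marker panel is complete and single-copy
  in every community member; real data needs curated universal markers.
* The ORF caller does not model frameshifts or pseudogenes; a frameshifted
  *hgcA* is reported (at most) as paralog-like or missed.
* SOM verification needs multi-contig bins: a single-contig bin has no
  same-bin voters and the coherence question is undecidable there.
* The constitutive-expression analysis assumes the housekeeping targets of
  each organism are detectable at ≥ 95% nucleotide identity; highly
  conserved housekeeping genes from close relatives could cross-recruit.
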