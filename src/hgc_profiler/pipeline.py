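"""End-to-end orchestration: simulate -> screen -> esom -> cluster -> quantify.

Stages communicate only through files with documented schemas, so every
stage can be rerun, inspected, or replaced independently:

    out/
      config.yaml               echo of the run configuration
      genomes/<bin>.fasta       simulated bins
      truth/<bin>.gff           planted loci (ground truth)
      truth/markers.fasta       single-copy marker targets (nt, per genome)
      truth/housekeeping.fasta  rpoB/gyrB targets (nt, per genome)
      manifest.tsv              sample_id, depth_m, omic_type, reads_path
      reads/<sample>.fastq      simulated read sets
      screen/calls.tsv|.gff     gene calls with evidence columns
      screen/<family>.fasta     called gene nucleotide sequences
      esom/placement.tsv        contig coherence reports
      esom/umatrix.tsv          U-matrix of the trained map
      cluster/<family>_reps.fasta, cluster/clusters.tsv
      quantify/abundance.tsv    per representative x metagenome sample
      quantify/rpkm.tsv         per representative x metatranscriptome sample
      quantify/profiles.tsv     per-family depth profiles with 95% CI
      report.json               RunReport

merB flows through the identical cluster/quantify path as hgcA, gated by
homology evidence only.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_reps, esom_verify, gene_screen, quantify
from .io_formats import (GenomeBin, ParseError, RunConfig, SequenceRecord,
                         read_fasta, read_tsv, write_fasta, write_gff3,
                         write_tsv)
from .synthetic_community import (CommunityProfile, ReadSet,
                                  background_plant_spec, carrier_plant_spec,
                                  simulate_genome, simulate_metagenome_reads,
                                  simulate_transcriptome_reads)

__all__ = ["RunReport", "run_pipeline", "demo_config", "default_params"]


@dataclass
class RunReport:
    seed: int
    params: dict
    counts: dict = field(default_factory=dict)
    wallclock_s: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def default_params() -> dict:
    return {
        "n_genomes": 2,
        "n_carriers": 1,
        "n_merB": 0,
        "n_contigs": 3,
        "contig_length_bp": 6000,
        "gc_values": [0.40, 0.58, 0.35, 0.62, 0.47],
        "mutation_rate": 0.01,
        "depths_m": [100, 150, 200],
        "total_genome_copies": 100.0,
        "read_len": 100,
        "error_rate": 0.002,
        "library_size_factor": 10000.0,
        "hgcA_rate": 0.5,
        "housekeeping_rate": 1.0,
        "merB_rate": 0.5,
        "carrier_base_fraction": 0.02,
        "window_bp": 2000,
        "som_rows": 8,
        "som_cols": 10,
        "som_epochs": 10,
        "coherence_threshold": 0.6,
        "cluster_identity": 0.99,
        "min_identity": 0.95,
        "min_aligned_frac": 0.9,
    }


def demo_config(seed: int = 7, out_dir: str | Path = "demo_out") -> RunConfig:
    """Two genomes, one hgcA carrier, three depths — the worked example."""
    return RunConfig(seed=seed, params=default_params(),
                     paths={"out": str(out_dir)})


def _carrier_fraction(params: dict, carrier_idx: int, depth_idx: int) -> float:
    base = params["carrier_base_fraction"]
    return base * (1 + depth_idx) * (1 + 0.5 * carrier_idx)


def _profiles(params: dict, genome_roles: list[tuple[str, str]]
              ) -> list[CommunityProfile]:
    profiles = []
    carriers = [g for g, role in genome_roles if role == "carrier"]
    merBs = [g for g, role in genome_roles if role == "merB"]
    bgs = [g for g, role in genome_roles if role == "background"]
    for di, depth in enumerate(params["depths_m"]):
        fracs = {}
        for i, g in enumerate(carriers):
            fracs[g] = _carrier_fraction(params, i, di)
        for g in merBs:
            fracs[g] = 0.5 * _carrier_fraction(params, 0, di)
        rest = 1.0 - sum(fracs.values())
        for g in bgs:
            fracs[g] = rest / len(bgs) if bgs else 0.0
        expression = {}
        for g, role in genome_roles:
            e = {"rpoB": params["housekeeping_rate"],
                 "gyrB": params["housekeeping_rate"]}
            if role == "carrier":
                rate = 0.0 if depth == 10 else params["hgcA_rate"]
                e["hgcA"] = rate
                e["hgcB"] = rate
            if role == "merB":
                e["merB"] = 0.0 if depth == 10 else params["merB_rate"]
            expression[g] = e
        profiles.append(CommunityProfile(
            depth_m=depth, taxa=sorted(fracs.items()), expression=expression))
    return profiles


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: RunConfig) -> dict:
    p = cfg.params
    out = Path(cfg.paths["out"])
    for sub in ("genomes", "truth", "reads"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    roles = (["carrier"] * p["n_carriers"] + ["merB"] * p["n_merB"]
             + ["background"] * (p["n_genomes"] - p["n_carriers"] - p["n_merB"]))
    genome_roles = [(f"g{i}_{role}", role) for i, role in enumerate(roles)]
    ss = np.random.SeedSequence(cfg.seed).spawn(len(genome_roles) + 1)

    genomes, loci = {}, {}
    for (gid, role), child in zip(genome_roles, ss[:-1]):
        spec = (carrier_plant_spec(p["mutation_rate"]) if role == "carrier"
                else background_plant_spec(p["mutation_rate"],
                                           merB=role == "merB"))
        gseed = int(child.generate_state(1)[0] % (2**31))
        gc = p["gc_values"][len(genomes) % len(p["gc_values"])]
        gb, gl = simulate_genome(gseed, p["n_contigs"], p["contig_length_bp"],
                                 gc, spec, bin_id=gid)
        genomes[gid] = gb
        loci[gid] = gl
        write_fasta(gb.contigs, out / "genomes" / f"{gid}.fasta")
        write_gff3([{"seqid": l.contig_id, "start": l.start, "end": l.end,
                     "strand": l.strand, "id": f"{gid}_{l.gene_family}",
                     "product": l.gene_family,
                     "evidence": f"planted;src={l.source_protein_id}"}
                    for l in gl], out / "truth" / f"{gid}.gff")

    # marker and housekeeping nucleotide targets, one per genome copy
    markers, housekeeping = [], []
    for gid, gl in loci.items():
        gb = genomes[gid]
        for l in gl:
            contig = next(c for c in gb.contigs if c.id == l.contig_id)
            nt = contig.residues[l.start:l.end - 3]
            if l.strand == "-":
                nt = gene_screen.revcomp(contig.residues[l.start + 3:l.end])
            rec = SequenceRecord(id=f"{l.gene_family}__{gid}", residues=nt,
                                 description=f"family={l.gene_family}")
            if l.gene_family.startswith("marker"):
                markers.append(rec)
            elif l.gene_family in ("rpoB", "gyrB"):
                housekeeping.append(rec)
    write_fasta(markers, out / "truth" / "markers.fasta")
    write_fasta(housekeeping, out / "truth" / "housekeeping.fasta")

    profiles = _profiles(p, genome_roles)
    rows = []
    sample_ss = ss[-1].spawn(2 * len(profiles))
    for i, prof in enumerate(profiles):
        meta_id = f"MG_{prof.depth_m}m"
        tx_id = f"MT_{prof.depth_m}m"
        cov = {g: a * p["total_genome_copies"] for g, a in prof.taxa}
        rs = simulate_metagenome_reads(
            genomes, cov, p["read_len"], p["error_rate"],
            seed=int(sample_ss[2 * i].generate_state(1)[0] % (2**31)),
            sample_id=meta_id)
        rs.write_fastq(out / "reads" / f"{meta_id}.fastq")
        rows.append([meta_id, prof.depth_m, "metagenome",
                     str(out / "reads" / f"{meta_id}.fastq")])
        tx, _ = simulate_transcriptome_reads(
            prof, genomes, loci, p["library_size_factor"], p["read_len"],
            p["error_rate"],
            seed=int(sample_ss[2 * i + 1].generate_state(1)[0] % (2**31)),
            sample_id=tx_id)
        tx.write_fastq(out / "reads" / f"{tx_id}.fastq")
        rows.append([tx_id, prof.depth_m, "metatranscriptome",
                     str(out / "reads" / f"{tx_id}.fastq")])
    write_tsv(rows, out / "manifest.tsv",
              header=["sample_id", "depth_m", "omic_type", "reads_path"],
              config=cfg)
    return {"n_genomes": len(genomes), "n_samples": len(rows)}


def stage_screen(cfg: RunConfig) -> dict:
    out = Path(cfg.paths["out"])
    gdir = out / "genomes"
    if not gdir.exists():
        raise ParseError(f"missing input directory: {gdir}")
    (out / "screen").mkdir(exist_ok=True)
    params = gene_screen.ScreenParams()
    rows, feats = [], []
    fam_seqs: dict[str, list[SequenceRecord]] = {}
    for fasta in sorted(gdir.glob("*.fasta")):
        gb = GenomeBin(bin_id=fasta.stem, contigs=read_fasta(fasta))
        for call in gene_screen.call_hgc_genes(gb, params=params):
            rows.append([call.bin_id, call.orf.contig_id, call.call_type,
                         call.orf.start, call.orf.end, call.orf.strand,
                         round(call.best_hit.raw_score, 1),
                         round(call.best_hit.percent_identity, 2),
                         len(call.motifs),
                         call.synteny_ok if call.synteny_ok is not None else "",
                         call.evidence_summary])
            feats.append({"seqid": call.orf.contig_id, "start": call.orf.start,
                          "end": call.orf.end, "strand": call.orf.strand,
                          "id": f"{call.bin_id}_{call.call_type}_{call.orf.start}",
                          "product": call.call_type,
                          "evidence": call.evidence_summary})
            if call.call_type in gene_screen.CALL_TYPES:
                nt = gene_screen.extract_call_nt(call, gb)
                fam_seqs.setdefault(call.call_type, []).append(
                    SequenceRecord(id=f"{call.bin_id}|{call.orf.orf_id}",
                                   residues=nt))
    write_tsv(rows, out / "screen" / "calls.tsv",
              header=["bin_id", "contig", "call_type", "start", "end",
                      "strand", "score", "identity", "n_motifs", "synteny_ok",
                      "evidence"], config=cfg)
    write_gff3(feats, out / "screen" / "calls.gff")
    for fam, seqs in fam_seqs.items():
        write_fasta(seqs, out / "screen" / f"{fam}.fasta")
    return {"n_calls": len(rows)}


def stage_esom(cfg: RunConfig) -> dict:
    p = cfg.params
    out = Path(cfg.paths["out"])
    calls_path = out / "screen" / "calls.tsv"
    if not calls_path.exists():
        raise ParseError(f"missing input: {calls_path}")
    (out / "esom").mkdir(exist_ok=True)
    frags = []
    for fasta in sorted((out / "genomes").glob("*.fasta")):
        gb = GenomeBin(bin_id=fasta.stem, contigs=read_fasta(fasta))
        frags.extend(esom_verify.fragment_contigs(
            gb, window_bp=p["window_bp"], min_len_bp=min(2000, p["window_bp"])))
    for f in frags:
        esom_verify.tnf(f)
    grid = esom_verify.train_som(
        np.stack([f.tnf for f in frags]), rows=p["som_rows"],
        cols=p["som_cols"], epochs=p["som_epochs"], seed=cfg.seed)
    calls = read_tsv(calls_path)
    hgc_contigs = sorted(set(calls.loc[
        calls.call_type.isin(gene_screen.CALL_TYPES), "contig"]))
    rows = []
    for contig in hgc_contigs:
        rep = esom_verify.verify_bin_membership(
            grid, frags, contig, threshold=p["coherence_threshold"])
        rows.append([rep.bin_id, rep.contig_id, round(rep.coherence, 4),
                     rep.passed, rep.n_fragments])
    write_tsv(rows, out / "esom" / "placement.tsv",
              header=["bin_id", "contig_id", "coherence", "pass",
                      "n_fragments"], config=cfg)
    um = esom_verify.u_matrix(grid)
    pd.DataFrame(um).to_csv(out / "esom" / "umatrix.tsv", sep="\t",
                            index=False, header=False)
    return {"n_verified": len(rows),
            "n_passed": sum(1 for r in rows if r[3])}


def stage_cluster(cfg: RunConfig) -> dict:
    p = cfg.params
    out = Path(cfg.paths["out"])
    (out / "cluster").mkdir(exist_ok=True)
    counts = {}
    rows = []
    for fam in ("hgcA", "merB"):
        fasta = out / "screen" / f"{fam}.fasta"
        if not fasta.exists():
            continue
        seqs = {r.id: r.residues for r in read_fasta(fasta)}
        clusters = cluster_reps.greedy_cluster(seqs, p["cluster_identity"])
        write_fasta([SequenceRecord(id=c.representative_id,
                                    residues=seqs[c.representative_id])
                     for c in clusters],
                    out / "cluster" / f"{fam}_reps.fasta")
        for c in clusters:
            for m in c.member_ids:
                rows.append([fam, c.representative_id, m, c.threshold])
        counts[f"n_{fam}_clusters"] = len(clusters)
    write_tsv(rows, out / "cluster" / "clusters.tsv",
              header=["family", "representative", "member", "threshold"],
              config=cfg)
    return counts


def stage_quantify(cfg: RunConfig) -> dict:
    p = cfg.params
    out = Path(cfg.paths["out"])
    manifest_path = out / "manifest.tsv"
    if not manifest_path.exists():
        raise ParseError(f"missing input: {manifest_path}")
    (out / "quantify").mkdir(exist_ok=True)
    manifest = read_tsv(manifest_path)

    gene_targets: dict[str, str] = {}
    gene_family: dict[str, str] = {}
    for fam in ("hgcA", "merB"):
        reps = out / "cluster" / f"{fam}_reps.fasta"
        if reps.exists():
            for r in read_fasta(reps):
                gene_targets[r.id] = r.residues
                gene_family[r.id] = fam
    markers = {r.id: r.residues
               for r in read_fasta(out / "truth" / "markers.fasta")}
    marker_family = {tid: tid.split("__")[0] for tid in markers}
    hk = {r.id: r.residues
          for r in read_fasta(out / "truth" / "housekeeping.fasta")}

    abundance_rows, rpkm_rows, profile_records = [], [], []
    p_read_len = p["read_len"]
    for _, sample in manifest.iterrows():
        rs = ReadSet.from_fastq(sample.reads_path)
        if sample.omic_type == "metagenome":
            targets = {**gene_targets, **markers}
            alns = quantify.recruit_reads(rs, targets, p["min_identity"],
                                          p["min_aligned_frac"])
            covs = quantify.coverage_summary(
                alns, {t: len(s) for t, s in targets.items()},
                sample.sample_id, read_len=p_read_len,
                min_aligned_frac=p["min_aligned_frac"])
            ge = quantify.genome_equivalents(
                {t: covs[t] for t in markers}, marker_family,
                sample.sample_id)
            for tid in sorted(gene_targets):
                rec = quantify.relative_abundance(covs[tid], ge)
                abundance_rows.append([
                    tid, sample.sample_id, sample.depth_m,
                    round(covs[tid].mean_depth, 4), round(ge.value, 4),
                    round(rec.relative_abundance_pct, 4)])
                profile_records.append(
                    (gene_family[tid] + "_dna", int(sample.depth_m),
                     sample.sample_id, rec.relative_abundance_pct))
        else:
            targets = {**gene_targets, **hk}
            alns = quantify.recruit_reads(rs, targets, p["min_identity"],
                                          p["min_aligned_frac"])
            n_mapped = len(alns)
            counts: dict[str, int] = {}
            for a in alns:
                counts[a.target_id] = counts.get(a.target_id, 0) + 1
            rpkms = {tid: (quantify.rpkm(counts.get(tid, 0), len(seq),
                                         n_mapped) if n_mapped else 0.0)
                     for tid, seq in targets.items()}
            for tid in sorted(gene_targets):
                gid = tid.split("|")[0]
                ratios = {}
                for hk_fam in ("rpoB", "gyrB"):
                    hk_tid = f"{hk_fam}__{gid}"
                    ratios[hk_fam] = (quantify.expression_ratio(
                        rpkms[tid], rpkms[hk_tid])
                        if hk_tid in rpkms else None)
                rpkm_rows.append([
                    tid, sample.sample_id, sample.depth_m,
                    counts.get(tid, 0), round(rpkms[tid], 4),
                    "" if ratios["rpoB"] is None else round(ratios["rpoB"], 4),
                    "" if ratios["gyrB"] is None else round(ratios["gyrB"], 4)])
                profile_records.append(
                    (gene_family[tid] + "_rna", int(sample.depth_m),
                     sample.sample_id, rpkms[tid]))

    write_tsv(abundance_rows, out / "quantify" / "abundance.tsv",
              header=["target_id", "sample_id", "depth_m", "mean_depth",
                      "genome_equivalents", "relative_abundance_pct"],
              config=cfg)
    write_tsv(rpkm_rows, out / "quantify" / "rpkm.tsv",
              header=["target_id", "sample_id", "depth_m", "read_count",
                      "rpkm", "ratio_rpoB", "ratio_gyrB"], config=cfg)
    profiles = quantify.depth_profile(profile_records)
    write_tsv([[pr.gene_family, pr.depth_m, round(pr.mean, 4),
                "" if pr.ci95_halfwidth is None else round(pr.ci95_halfwidth, 4),
                pr.n] for pr in profiles],
              out / "quantify" / "profiles.tsv",
              header=["gene_family", "depth_m", "mean", "ci95_halfwidth", "n"],
              config=cfg)
    return {"n_abundance_rows": len(abundance_rows),
            "n_rpkm_rows": len(rpkm_rows)}


_STAGES = (("simulate", stage_simulate), ("screen", stage_screen),
           ("esom", stage_esom), ("cluster", stage_cluster),
           ("quantify", stage_quantify))


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run all stages in order; raises on the first stage error."""
    out = Path(cfg.paths["out"])
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report = RunReport(seed=cfg.seed, params=dict(cfg.params))
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        counts = fn(cfg)
        report.wallclock_s[name] = round(time.perf_counter() - t0, 3)
        report.counts.update(counts)
    report.outputs = sorted(
        str(f.relative_to(out)) for f in out.rglob("*") if f.is_file())
    report.to_json(out / "report.json")
    return report
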