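"""Sequence and tabular I/O shared by every pipeline stage.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; this module wraps it
with the strict validation the pipeline relies on (uppercase residues,
alphabet checks, Phred+33 only) and with error messages that name the
offending file and, where recoverable, the line.

Coordinate convention throughout the package: 0-based, half-open intervals
on the forward strand, strand encoded as ``+`` / ``-``.  The GFF3 writer
converts to the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "ParseError",
    "SequenceRecord",
    "ReadRecord",
    "GenomeBin",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_tsv",
    "write_tsv",
    "write_gff3",
]

DNA_ALPHABET = set("ACGTN")
# 20 standard residues plus X (unknown) and * (stop)
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named sequence, DNA or protein.

    ``alphabet`` is ``"dna"`` or ``"protein"``; content is validated against
    it on construction so a protein sequence can never masquerade as DNA.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"sequence id must be a non-empty token, got {self.id!r}")
        self.residues = self.residues.upper()
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    residues: str
    qualities: list[int]
    mate: str = "unpaired"  # {"1", "2", "unpaired"}

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.qualities) != len(self.residues):
            raise ParseError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} bases"
            )
        if any(q < 0 for q in self.qualities):
            raise ParseError(f"read {self.id!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeBin:
    """A MAG: a set of contigs treated as one putative genome."""

    bin_id: str
    contigs: list[SequenceRecord]
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ParseError(f"bin {self.bin_id!r}: duplicate contig ids")
        if sum(len(c) for c in self.contigs) == 0:
            raise ParseError(f"bin {self.bin_id!r}: total length is zero")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class RunConfig:
    """Seed plus the named thresholds/paths a pipeline run is defined by.

    The config hash (stable across key order) is stamped into every output
    TSV header so results remain attributable to their parameters.
    """

    seed: int
    params: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def hash(self) -> str:
        # paths excluded: where outputs land must not change what they contain
        blob = json.dumps({"seed": self.seed, "params": self.params},
                          sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"seed": self.seed, "params": self.params, "paths": self.paths}, fh
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "seed" not in d:
            raise ParseError(f"{path}: config missing required key 'seed'")
        return cls(seed=int(d["seed"]), params=d.get("params", {}),
                   paths=d.get("paths", {}))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (residues uppercased).

    Raises ParseError naming the file (and line where determinable) on
    malformed headers or characters outside the declared alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    _validate_fasta_layout(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                records.append(
                    SequenceRecord(
                        id=rec.id,
                        residues=str(rec.seq),
                        description=_strip_id(rec.description, rec.id),
                        alphabet=alphabet,
                    )
                )
            except ParseError as exc:
                line = _line_of_header(path, rec.id)
                raise ParseError(f"{path}:{line}: {exc}") from exc
    except ValueError as exc:  # Biopython-level failure
        raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records in canonical form: uppercase, fixed line width."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _validate_fasta_layout(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.rstrip("\n")
            if lineno == 1 and s and not s.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected '>' header, got {s[:30]!r}")
            if s.startswith(">") and len(s) == 1:
                raise ParseError(f"{path}:{lineno}: empty FASTA header")


def _line_of_header(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
                return lineno
    return 0


def _strip_id(description: str, rec_id: str) -> str:
    if description.startswith(rec_id):
        return description[len(rec_id):].strip()
    return description


# ---------------------------------------------------------------------------
# FASTQ (Phred+33 only)

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read 4-line-block FASTQ with Phred+33 qualities.

    Sequence/quality length mismatches and non-ASCII33 dialects fail loudly.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = list(rec.letter_annotations["phred_quality"])
            rid, mate = _split_mate(rec.id)
            reads.append(ReadRecord(id=rid, residues=str(rec.seq),
                                    qualities=quals, mate=mate))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            rid = r.id if r.mate == "unpaired" else f"{r.id}/{r.mate}"
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{rid}\n{r.residues}\n+\n{qual}\n")


def _split_mate(rec_id: str) -> tuple[str, str]:
    if rec_id.endswith("/1"):
        return rec_id[:-2], "1"
    if rec_id.endswith("/2"):
        return rec_id[:-2], "2"
    return rec_id, "unpaired"


# ---------------------------------------------------------------------------
# TSV

def write_tsv(table: pd.DataFrame | Sequence[Sequence], path: str | Path,
              header: Sequence[str] | None = None,
              config: RunConfig | None = None) -> None:
    """Write a rectangular table as TSV ('.' decimal, no trailing whitespace).

    A comment header records tool version, config hash, and seed when a
    RunConfig is supplied.
    """
    if not isinstance(table, pd.DataFrame):
        rows = [list(r) for r in table]
        if header is None:
            raise ParseError("header required for list-of-rows tables")
        widths = {len(r) for r in rows} | {len(header)}
        if len(widths) > 1:
            raise ParseError(f"ragged table: row widths {sorted(widths)}")
        table = pd.DataFrame(rows, columns=list(header))
    with open(path, "w") as fh:
        if config is not None:
            from . import __version__
            fh.write(f"# hgc-profiler {__version__}\n")
            fh.write(f"# config_hash={config.hash()} seed={config.seed}\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# GFF3 subset (CDS features only)

def write_gff3(features: Iterable[dict], path: str | Path) -> None:
    """Write gene features as a GFF3 subset.

    Each feature dict needs: seqid, start, end (0-based half-open; converted
    to GFF 1-based inclusive), strand, id, and optionally product/evidence
    attribute strings and source.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f['id']}"]
            if f.get("product"):
                attrs.append(f"product={f['product']}")
            if f.get("evidence"):
                attrs.append(f"evidence={f['evidence']}")
            fh.write(
                "\t".join(
                    [
                        f["seqid"],
                        f.get("source", "hgc-profiler"),
                        "CDS",
                        str(f["start"] + 1),
                        str(f["end"]),
                        f.get("score", "."),
                        f["strand"],
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
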