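"""Synthetic reference protein panel for homology search and simulation.

The screening stage needs curated reference proteins for HgcA, HgcB, MerB,
the housekeeping genes (RpoB, GyrB), and a set of universal single-copy
marker genes.  No such curated set ships with this package; instead a
deterministic synthetic panel is generated here, with the biologically
conserved features embedded where they belong:

* every HgcA reference carries the cap-helix motif N(V/I)WCA(A/G)(A/G)K in
  its N-terminal (globular-domain) half;
* every HgcB reference carries two tandem ferredoxin motifs CX2CX2CX3C near
  the N-terminus and a C-terminal ...CC tail;
* MerB, RpoB, GyrB and the markers are motif-free random proteins.

Family variants are derived from a family base sequence by substituting a
fixed fraction of non-motif positions, so within-family homology is strong
(~85% identity) while between-family homology is absent.  The panel is a
stand-in for an experimentally curated database and is pluggable: any
protein FASTA with the same family naming can be used in its place.

Everything is derived from one hard-coded seed, so the panel is identical
across processes and versions of this module's callers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .io_formats import SequenceRecord, write_fasta

_PANEL_SEED = 714025
# residues weighted roughly like an average globular protein; no C by default
# so cysteine placement is fully controlled by the motif templates
_AA = np.array(list("ADEFGHIKLMNPQRSTVWY"))

CAP_HELIX_VARIANTS = ("NVWCAAGK", "NIWCAAGK", "NVWCAGGK", "NVWCGAGK")
FAMILIES = ("hgcA", "hgcB", "merB", "rpoB", "gyrB",
            "marker_1", "marker_2", "marker_3", "marker_4", "marker_5")
HOUSEKEEPING = ("rpoB", "gyrB")
MARKERS = ("marker_1", "marker_2", "marker_3", "marker_4", "marker_5")


def _random_protein(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(_AA, size=length))


def _ferredoxin_block(rng: np.random.Generator) -> list[str]:
    # CX2CX2CX3C rendered with random spacer residues
    x = lambda n: list(rng.choice(_AA, size=n))
    return ["C"] + x(2) + ["C"] + x(2) + ["C"] + x(3) + ["C"]


def _mutate(rng: np.random.Generator, base: list[str], frac: float,
            protected: set[int]) -> list[str]:
    seq = list(base)
    for i in rng.permutation(len(seq))[: int(frac * len(seq))]:
        if int(i) in protected:
            continue
        choices = [c for c in _AA if c != seq[i]]
        seq[int(i)] = choices[int(rng.integers(len(choices)))]
    return seq


def _build_panel() -> dict[str, dict[str, str]]:
    rng = np.random.default_rng(_PANEL_SEED)
    panel: dict[str, dict[str, str]] = {}

    # --- HgcA: 320 aa, cap-helix at position 85
    base = _random_protein(rng, 320)
    base[0] = "M"
    cap_pos = 85
    protected = set(range(cap_pos, cap_pos + 8)) | {0}
    panel["hgcA"] = {}
    for i, cap in enumerate(CAP_HELIX_VARIANTS[:3], 1):
        var = _mutate(rng, base, 0.15, protected)
        var[cap_pos:cap_pos + 8] = list(cap)
        panel["hgcA"][f"HgcA_ref{i}"] = "".join(var)

    # --- HgcB: 95 aa, tandem ferredoxin motifs at 3 and 33, CC tail
    fd1 = _ferredoxin_block(rng)
    fd2 = _ferredoxin_block(rng)
    base = _random_protein(rng, 95)
    base[0] = "M"
    base[3:3 + 11] = fd1
    base[33:33 + 11] = fd2
    base[-2:] = ["C", "C"]
    protected = set(range(3, 14)) | set(range(33, 44)) | {0, 93, 94}
    panel["hgcB"] = {
        f"HgcB_ref{i}": "".join(_mutate(rng, base, 0.15, protected))
        for i in (1, 2)
    }

    # --- MerB: 212 aa, homology evidence only
    base = _random_protein(rng, 212)
    base[0] = "M"
    panel["merB"] = {
        f"MerB_ref{i}": "".join(_mutate(rng, base, 0.15, {0})) for i in (1, 2)
    }

    # --- housekeeping and single-copy markers, one reference each
    for family, length in (("rpoB", 300), ("gyrB", 300),
                           ("marker_1", 200), ("marker_2", 200),
                           ("marker_3", 200), ("marker_4", 200),
                           ("marker_5", 200)):
        seq = _random_protein(rng, length)
        seq[0] = "M"
        panel[family] = {f"{family}_ref1": "".join(seq)}
    return panel


_PANEL: dict[str, dict[str, str]] | None = None


def default_reference_panel() -> dict[str, dict[str, str]]:
    """family -> {reference_id -> protein sequence} (built once, cached)."""
    global _PANEL
    if _PANEL is None:
        _PANEL = _build_panel()
    return _PANEL


def reference_protein(family: str, ref_id: str | None = None) -> tuple[str, str]:
    """Return (reference_id, sequence) for a family; first by id if unset."""
    fam = default_reference_panel()[family]
    if ref_id is None:
        ref_id = sorted(fam)[0]
    return ref_id, fam[ref_id]


def write_reference_fasta(path: str | Path, families: tuple[str, ...] = FAMILIES) -> None:
    """Dump the panel (or a family subset) as a protein FASTA.

    Headers are ``>{ref_id} family={family}`` so a screen run can rebuild
    the family map from the file alone.
    """
    panel = default_reference_panel()
    records = [
        SequenceRecord(id=rid, residues=seq, description=f"family={fam}",
                       alphabet="protein")
        for fam in families
        for rid, seq in sorted(panel[fam].items())
    ]
    write_fasta(records, path)


def read_reference_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Inverse of :func:`write_reference_fasta`."""
    from .io_formats import read_fasta

    panel: dict[str, dict[str, str]] = {}
    for rec in read_fasta(path, alphabet="protein"):
        fam = "unknown"
        for token in rec.description.split():
            if token.startswith("family="):
                fam = token[len("family="):]
        panel.setdefault(fam, {})[rec.id] = rec.residues
    return panel
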