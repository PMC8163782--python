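"""Greedy identity clustering of detected gene nucleotide sequences.

Representative sequences are chosen per identity group before read
recruitment, so that near-identical gene copies recovered from different
bins do not split the mapped signal.  The procedure follows the incremental
greedy scheme of classic identity-clustering tools: sequences are visited
longest-first and joined to the first cluster whose representative they
match at or above the threshold, otherwise they found a new cluster.

Identity between two sequences is computed from a global alignment
(match +1, mismatch -1, gap -2) as the number of identical aligned
positions divided by the length of the *shorter* sequence — the
short-sequence convention, which makes a perfect substring score 1.0.
Among score-optimal alignments the one maximising identical positions is
used, so identity is a well-defined function of the pair.

Unlike the source workflow, the representative is not arbitrary: it is the
longest member (ties broken by lexicographically smallest id), which makes
clustering deterministic and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import global_alignment_matches

__all__ = ["IdentityCluster", "pairwise_identity", "greedy_cluster"]


@dataclass
class IdentityCluster:
    representative_id: str
    member_ids: list[str]
    threshold: float


def pairwise_identity(a_nt: str, b_nt: str) -> float:
    """Global-alignment identity over the shorter sequence."""
    if not a_nt or not b_nt:
        raise ValueError("empty sequence")
    _, matches = global_alignment_matches(a_nt, b_nt)
    return matches / min(len(a_nt), len(b_nt))


def greedy_cluster(sequences: dict[str, str],
                   threshold: float = 0.99) -> list[IdentityCluster]:
    """Cluster sequences at an identity threshold, longest-first.

    Deterministic: input order is irrelevant; the visit order is by
    (length desc, id asc), and each sequence joins the first existing
    cluster (in founding order) whose representative it matches.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1.0]")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    clusters: list[IdentityCluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            if pairwise_identity(sequences[sid],
                                 sequences[cl.representative_id]) >= threshold:
                cl.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(IdentityCluster(sid, [sid], threshold))
    return clusters


def representatives(clusters: list[IdentityCluster],
                    sequences: dict[str, str]) -> dict[str, str]:
    return {cl.representative_id: sequences[cl.representative_id]
            for cl in clusters}
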