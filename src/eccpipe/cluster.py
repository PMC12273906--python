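"""Non-redundant eccDNA set by greedy identity clustering.

Greedy incremental clustering in the style of classic non-redundant
database builders: sequences are sorted by length (descending, id as the
tie-break, so results are deterministic), and each sequence joins the
first existing cluster whose representative aligns to it at or above the
identity threshold, computed over the shorter sequence's length;
otherwise it founds a new cluster.

Clustering operates on rotation/strand-canonical sequences and aligns
against the doubled representative, so the rotation phase of a circular
molecule can never split a cluster — a deliberate improvement over naive
linear clustering of circular molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .circcall import MonomerCall, canonicalize
from .simdata import revcomp


@dataclass
class EccCluster:
    cluster_id: str
    representative_id: str
    member_ids: list[str]
    representative_length: int

    @property
    def size(self) -> int:
        return len(self.member_ids)


def circular_identity(seq_a: str, seq_b: str, max_edits: int = -1) -> float:
    """Identity of two circular sequences over the shorter length.

    The shorter sequence is aligned (infix mode) against the doubled longer
    sequence and against the doubled reverse complement; the better of the
    two placements is used: identity = 1 - edits / shorter_length.
    ``max_edits`` >= 0 enables early abandoning (returns 0.0 when both
    strands exceed it).
    """
    if not seq_a or not seq_b:
        return 0.0
    short, long_ = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    d1 = edlib.align(short, long_ + long_, mode="HW", task="distance",
                     k=max_edits)["editDistance"]
    if d1 == 0:
        return 1.0
    d2 = edlib.align(short, revcomp(long_) + revcomp(long_), mode="HW",
                     task="distance", k=max_edits)["editDistance"]
    candidates = [d for d in (d1, d2) if d >= 0]
    if not candidates:
        return 0.0
    return max(0.0, 1.0 - min(candidates) / len(short))


def cluster_monomers(calls: list[MonomerCall], identity_threshold: float = 0.9
                     ) -> list[EccCluster]:
    """Greedy identity clustering of monomer calls on canonical sequences.

    The representative of each cluster is its founding (longest) member.
    """
    if not 0.5 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0.5, 1.0]")
    order = sorted(calls, key=lambda c: (-len(c.sequence), c.monomer_id))
    clusters: list[EccCluster] = []
    reps: list[str] = []
    for call in order:
        canon = call.canonical_sequence or canonicalize(call.sequence)
        max_edits = int((1.0 - identity_threshold) * len(canon)) + 1
        placed = False
        for cl, rep in zip(clusters, reps):
            if circular_identity(canon, rep, max_edits=max_edits) >= identity_threshold:
                cl.member_ids.append(call.monomer_id)
                placed = True
                break
        if not placed:
            clusters.append(EccCluster(
                cluster_id=f"cluster{len(clusters) + 1:05d}",
                representative_id=call.monomer_id,
                member_ids=[call.monomer_id],
                representative_length=len(call.sequence),
            ))
            reps.append(canon)
    return clusters


def cluster_stats(clusters: list[EccCluster],
                  single_event_by_monomer: dict[str, bool] | None = None) -> dict:
    """Cluster summary: totals, singleton fraction, and (when annotation is
    supplied) the fraction of clusters whose representative derives from a
    single continuous genomic locus."""
    n = len(clusters)
    singletons = sum(1 for c in clusters if c.size == 1)
    out = {
        "total_clusters": n,
        "total_members": sum(c.size for c in clusters),
        "singleton_clusters": singletons,
        "singleton_fraction": singletons / n if n else float("nan"),
    }
    if single_event_by_monomer is not None:
        known = [c for c in clusters if c.representative_id in single_event_by_monomer]
        single = sum(1 for c in known if single_event_by_monomer[c.representative_id])
        out["single_event_clusters"] = single
        out["single_event_fraction"] = single / len(known) if known else float("nan")
    return out
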