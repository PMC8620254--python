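"""Contigs in GC-content x read-depth space: clustering and classification.

A dominant population's contigs co-locate in this 2D space (shared base
composition, shared abundance); a divergent relative too distant to recruit
reads forms its own cluster at a different depth. Density clustering
(DBSCAN on standardized GC and log10 depth) replaces visual inspection of
the scatter plot, and candidate clusters are screened against reference
genomes with the fragment aligner to label them same-species, divergent
relative, or unrelated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.preprocessing import StandardScaler

from phylopop._align import TargetIndex, best_fragment_hit
from phylopop.assembly import ReferenceAssembly, gc_percent
from phylopop.markers import fragments_of
from phylopop.recruit import DepthProfile


@dataclass
class ContigPoint:
    contig_id: str
    length: int
    gc: float  # percent
    mean_depth: float

    @property
    def log10_depth(self) -> float:
        return float(np.log10(self.mean_depth))


@dataclass
class ContigCluster:
    cluster_id: int  # -1 = noise
    members: list[ContigPoint]
    candidate: bool = False
    identity_label: str = "unassigned"  # same_species | divergent_relative | unrelated

    @property
    def centroid(self) -> tuple[float, float]:
        return (
            float(np.mean([m.gc for m in self.members])),
            float(np.mean([m.log10_depth for m in self.members])),
        )

    @property
    def total_length(self) -> int:
        return sum(m.length for m in self.members)


def compute_points(
    contigs: Mapping[str, str],
    profile: DepthProfile,
    min_len: int = 1000,
    gc_lo: float = 30.0,
    gc_hi: float = 70.0,
) -> list[ContigPoint]:
    """Place contigs in GC-depth space, applying the entry filter.

    Only contigs of at least ``min_len`` bp with GC between ``gc_lo`` and
    ``gc_hi`` percent enter clustering; contigs with zero mean depth are
    excluded too (no position on a log-depth axis). A contig absent from
    the depth profile is an error.
    """
    points = []
    for cid, seq in contigs.items():
        if cid not in profile.depth:
            raise KeyError(f"contig {cid} has no depth data")
        if len(seq) < min_len:
            continue
        gc = gc_percent(seq)
        if not gc_lo <= gc <= gc_hi:
            continue
        depth = profile.contig_mean(cid)
        if depth <= 0:
            continue
        points.append(ContigPoint(contig_id=cid, length=len(seq), gc=gc, mean_depth=depth))
    return points


def cluster_points(
    points: Sequence[ContigPoint],
    eps: float = 0.3,
    min_pts: int = 5,
) -> list[ContigCluster]:
    """Density-cluster points on standardized (GC, log10 depth).

    Deterministic given the point set (DBSCAN core/noise labels do not
    depend on input order for distinct points; border-point ties are
    resolved by first-core-reached, so points are sorted by contig id
    first). Unclustered points are returned as one noise cluster (id -1).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    pts = sorted(points, key=lambda p: p.contig_id)
    if not pts:
        return []
    xy = np.array([[p.gc, p.log10_depth] for p in pts])
    scaled = StandardScaler().fit_transform(xy)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(scaled)
    clusters: dict[int, list[ContigPoint]] = {}
    for p, lab in zip(pts, labels):
        clusters.setdefault(int(lab), []).append(p)
    return [
        ContigCluster(cluster_id=lab, members=members)
        for lab, members in sorted(clusters.items())
    ]


def select_candidates(
    clusters: Sequence[ContigCluster],
    gc_lo: float = 35.0,
    gc_hi: float = 65.0,
    depth_max: float = 7500.0,
    min_len: int = 10_000,
) -> list[ContigCluster]:
    """Flag clusters inside the candidate envelope.

    A (non-noise) cluster is a candidate when every member sits within the
    GC window and under the depth ceiling, and at least one member contig
    reaches ``min_len`` (the length screen applied to member contigs).
    Idempotent; returns the same cluster objects with flags set.
    """
    for cluster in clusters:
        if cluster.cluster_id == -1:
            cluster.candidate = False
            continue
        in_envelope = all(
            gc_lo <= m.gc <= gc_hi and m.mean_depth <= depth_max for m in cluster.members
        )
        long_enough = any(m.length >= min_len for m in cluster.members)
        cluster.candidate = in_envelope and long_enough
    return list(clusters)


def classify_cluster(
    cluster: ContigCluster,
    references: Sequence[ReferenceAssembly],
    contigs: Mapping[str, str],
    frag: int = 1020,
    same_species_identity: float = 0.95,
    same_species_cov: float = 0.50,
    divergent_identity: float = 0.80,
    divergent_span: int = 5000,
) -> str:
    """Label a cluster against reference genomes via fragment alignment.

    Member contigs are chopped into fragments and aligned to each
    reference; per reference the mean identity of aligning fragments and
    their summed length (the aligned span) are taken. The cluster is
    ``same_species`` if some reference aligns at identity >=
    ``same_species_identity`` over >= ``same_species_cov`` of the member
    length; ``divergent_relative`` if identity falls in
    [``divergent_identity``, ``same_species_identity``) with span >=
    ``divergent_span`` (low identity over a long stretch — a related
    genome too diverged to recruit reads); ``unrelated`` if fragments
    align only below that; ``unassigned`` if nothing aligns.
    """
    if not references:
        raise ValueError("no references supplied")
    member_seqs = {m.contig_id: contigs[m.contig_id] for m in cluster.members}
    total_len = sum(len(s) for s in member_seqs.values())
    best_label = "unassigned"
    order = {"unassigned": 0, "unrelated": 1, "divergent_relative": 2, "same_species": 3}
    for ref in references:
        index = TargetIndex(ref.contigs, k=16)
        identities: list[float] = []
        span = 0
        for piece in fragments_of(member_seqs, frag):
            hit = best_fragment_hit(piece, index)
            if hit is None:
                continue
            identities.append(hit.identity)
            span += len(piece)
        if not identities:
            continue
        mean_id = float(np.mean(identities))
        if mean_id >= same_species_identity and span >= same_species_cov * total_len:
            label = "same_species"
        elif divergent_identity <= mean_id < same_species_identity and span >= divergent_span:
            label = "divergent_relative"
        else:
            label = "unrelated"
        if order[label] > order[best_label]:
            best_label = label
    cluster.identity_label = best_label
    return best_label


def points_to_tsv(points: Sequence[ContigPoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "contig_id": p.contig_id,
                "length": p.length,
                "gc_percent": p.gc,
                "mean_depth": p.mean_depth,
                "log10_depth": p.log10_depth,
            }
            for p in points
        ]
    ).to_csv(path, sep="\t", index=False)


def clusters_to_tsv(clusters: Sequence[ContigCluster], path: str | Path) -> None:
    rows = []
    for cl in clusters:
        for m in cl.members:
            rows.append(
                {
                    "contig_id": m.contig_id,
                    "cluster_id": cl.cluster_id,
                    "candidate": cl.candidate,
                    "identity_label": cl.identity_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
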