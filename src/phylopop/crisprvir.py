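"""CRISPR arrays, spacer-protospacer matching, and virus-host networks.

A CRISPR array is a run of near-identical direct repeats (23-47 bp)
separated by unique spacers (20-50 bp) sampled from past viral infections.
A spacer matching a viral contig at near-perfect identity links that virus
to the host carrying the array; aggregating matches by the source systems
of spacers and viral contigs yields a biogeography network, and full-length
exact matches against a curated host-spacer database assign candidate host
taxa to viral clusters (a virus whose implicated hosts span more than one
phylum is flagged a generalist).

The detector is a minimal tandem-repeat finder that assumes a uniform
period within one array (fixed spacer length); arrays found by external
annotation can be supplied as TSV instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SpacerArray:
    contig_id: str
    start: int
    end: int  # half-open; includes a trailing partial repeat if present
    repeat_consensus: str
    spacers: list[tuple[str, str]]  # (spacer_id, sequence)
    at_contig_end: bool

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


@dataclass
class ViralMatch:
    spacer_id: str
    spacer_system: str
    viral_contig: str
    viral_cluster: str
    viral_system: str
    alignment_length: int
    identity_percent: float


@dataclass
class NetworkEdge:
    kind: str  # spacer_to_virus | virus_to_host
    from_node: str
    to_node: str
    weight: int


# ---------------------------------------------------------------------------
# array detection


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_crispr_arrays(
    contigs: Mapping[str, str],
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (20, 50),
    min_repeats: int = 3,
    max_repeat_mismatch: int = 1,
    k: int = 11,
) -> list[SpacerArray]:
    """Find repeat-spacer arrays with a uniform period.

    Anchors are pairs of identical k-mers whose distance is a plausible
    period (repeat + spacer length); each anchor is extended to the maximal
    self-match under that period shift, giving the repeat unit, and the
    array is walked in both directions while repeats stay within
    ``max_repeat_mismatch`` of the first. Arrays need ``min_repeats``
    repeats (hence n_repeats - 1 spacers); a partial trailing repeat at a
    contig end is permitted and sets ``at_contig_end``.
    """
    rmin, rmax = repeat_len
    smin, smax = spacer_len
    if not (11 <= rmin <= rmax and smin <= smax and min_repeats >= 3):
        raise ValueError("implausible repeat/spacer bounds")
    dmin, dmax = rmin + smin, rmax + smax
    arrays: list[SpacerArray] = []
    for cid, seq in contigs.items():
        length = len(seq)
        if length < min_repeats * rmin + (min_repeats - 1) * smin:
            continue
        kmer_pos: dict[str, list[int]] = {}
        for i in range(length - k + 1):
            kmer_pos.setdefault(seq[i : i + k], []).append(i)
        claimed: list[tuple[int, int]] = []
        anchors: list[tuple[int, int]] = []
        for positions in kmer_pos.values():
            if len(positions) < 2:
                continue
            for p, q in zip(positions, positions[1:]):
                if dmin <= q - p <= dmax:
                    anchors.append((p, q - p))
        slack = 6  # pairwise runs can overshoot into spacers by chance matches
        for p, d in sorted(anchors):
            if any(s <= p < e for s, e in claimed):
                continue
            # maximal run where seq matches itself shifted by d, around p;
            # this delimits one repeat occurrence up to chance overshoot
            left = p
            while left > 0 and left + d <= length and seq[left - 1] == seq[left - 1 + d]:
                left -= 1
            right = p + k
            while right + d < length and seq[right] == seq[right + d]:
                right += 1
            r = right - left
            if not rmin <= r <= rmax + slack:
                continue
            if not smin - slack <= d - r <= smax:
                continue
            repeat0 = seq[left:right]
            walk_budget = max_repeat_mismatch + 3
            first = left
            while (
                first - d >= 0
                and _hamming(seq[first - d : first - d + r], repeat0) <= walk_budget
            ):
                first -= d
            last = left
            while (
                last + d + r <= length
                and _hamming(seq[last + d : last + d + r], repeat0) <= walk_budget
            ):
                last += d
            n_repeats = (last - first) // d + 1
            if n_repeats < min_repeats:
                continue
            # trim overshoot: end columns not conserved across all occurrences
            # are spacer-derived (spacers are unrelated between periods)
            occs = [seq[first + m * d : first + m * d + r] for m in range(n_repeats)]

            def conserved(i: int) -> bool:
                return all(o[i] == occs[0][i] for o in occs)

            lo, hi = 0, r
            while lo < hi and not conserved(lo):
                lo += 1
            while hi > lo and not conserved(hi - 1):
                hi -= 1
            r_t = hi - lo
            if not rmin <= r_t <= rmax or not smin <= d - r_t <= smax:
                continue
            first += lo
            last += lo
            reps = [seq[first + m * d : first + m * d + r_t] for m in range(n_repeats)]
            if any(_hamming(rep, reps[0]) > max_repeat_mismatch for rep in reps):
                continue
            consensus = "".join(
                max("ACGT", key=lambda b: sum(rep[i] == b for rep in reps))
                for i in range(r_t)
            )
            # trailing partial repeat at the contig end
            end = last + r_t
            at_end = False
            tail_start = last + d
            if tail_start < length and tail_start + r_t > length:
                tail = seq[tail_start:length]
                if len(tail) >= 5 and _hamming(tail, consensus[: len(tail)]) <= max_repeat_mismatch:
                    end = length
                    at_end = True
            if not at_end and length - end < d:
                at_end = True  # no room for another period: array truncated by the edge
            spacers = [
                (
                    f"{cid}_arr{len(arrays)}_sp{m}",
                    seq[first + m * d + r_t : first + (m + 1) * d],
                )
                for m in range(n_repeats - 1)
            ]
            arrays.append(
                SpacerArray(
                    contig_id=cid,
                    start=first,
                    end=end,
                    repeat_consensus=consensus,
                    spacers=spacers,
                    at_contig_end=at_end,
                )
            )
            claimed.append((first, end))
    return arrays


def arrays_to_tsv(arrays: Sequence[SpacerArray], path: str | Path) -> None:
    rows = []
    for a in arrays:
        for sid, sseq in a.spacers:
            rows.append(
                {
                    "contig_id": a.contig_id,
                    "array_start": a.start,
                    "array_end": a.end,
                    "repeat": a.repeat_consensus,
                    "spacer_id": sid,
                    "spacer_seq": sseq,
                    "at_contig_end": a.at_contig_end,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_arrays_tsv(path: str | Path) -> list[SpacerArray]:
    """Load arrays supplied directly (bypassing detection)."""
    df = pd.read_csv(path, sep="\t")
    arrays: dict[tuple[str, int], SpacerArray] = {}
    for row in df.itertuples():
        key = (str(row.contig_id), int(row.array_start))
        if key not in arrays:
            arrays[key] = SpacerArray(
                contig_id=str(row.contig_id),
                start=int(row.array_start),
                end=int(row.array_end),
                repeat_consensus=str(row.repeat),
                spacers=[],
                at_contig_end=bool(row.at_contig_end),
            )
        arrays[key].spacers.append((str(row.spacer_id), str(row.spacer_seq)))
    return list(arrays.values())


# ---------------------------------------------------------------------------
# spacer matching


def match_spacers(
    spacers: Sequence[tuple[str, str, str]],
    catalogue: Mapping[str, str],
    labels: pd.DataFrame,
    min_identity: float = 97.0,
    min_cov: float = 0.95,
    k: int = 10,
) -> list[ViralMatch]:
    """Match spacers to a viral catalogue at near-perfect identity.

    ``spacers`` are (spacer_id, sequence, source_system) triples;
    ``labels`` has columns (contig_id, cluster_label, source_system)
    covering every catalogue contig. Both orientations are searched with
    exact k-mer seeds; a hit is retained when its identity reaches
    ``min_identity`` percent over at least ``min_cov`` of the spacer.
    All qualifying catalogue contigs are reported per spacer; the
    orientation-best identity per (spacer, contig) pair is kept.
    """
    label_of = {str(r.contig_id): r for r in labels.itertuples()}
    missing = set(catalogue) - set(label_of)
    if missing:
        raise ValueError(f"catalogue contigs without labels: {sorted(missing)}")
    index: dict[str, list[tuple[str, int]]] = {}
    for vid, vseq in catalogue.items():
        for i in range(len(vseq) - k + 1):
            index.setdefault(vseq[i : i + k], []).append((vid, i))
    best: dict[tuple[str, str], ViralMatch] = {}
    for sid, sseq, system in spacers:
        sseq = sseq.upper()
        n = len(sseq)
        max_mm = int(n - np.ceil(min_identity / 100.0 * n))
        for oriented in (sseq, sseq.translate(_RC)[::-1]):
            seen_starts: set[tuple[str, int]] = set()
            for qpos in range(0, n - k + 1):
                for vid, vpos in index.get(oriented[qpos : qpos + k], ()):
                    start = vpos - qpos
                    if start < 0 or start + n > len(catalogue[vid]):
                        continue
                    if (vid, start) in seen_starts:
                        continue
                    seen_starts.add((vid, start))
                    # full-length ungapped comparison: coverage is 1.0 >= min_cov
                    # by construction (indel-containing protospacers are missed;
                    # see the methods note)
                    window = catalogue[vid][start : start + n]
                    mm = _hamming(window, oriented)
                    if mm > max_mm:
                        continue
                    identity = 100.0 * (n - mm) / n
                    if identity < min_identity:
                        continue
                    row = label_of[vid]
                    key = (sid, vid)
                    if key not in best or identity > best[key].identity_percent:
                        best[key] = ViralMatch(
                            spacer_id=sid,
                            spacer_system=system,
                            viral_contig=vid,
                            viral_cluster=str(row.cluster_label),
                            viral_system=str(row.source_system),
                            alignment_length=n,
                            identity_percent=identity,
                        )
    return sorted(best.values(), key=lambda m: (m.spacer_id, m.viral_contig))


def matches_to_tsv(matches: Sequence[ViralMatch], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in matches]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# catalogue membership


def classify_catalogue_membership(
    queries: Mapping[str, str],
    catalogue: Mapping[str, str],
    min_aln: int = 1000,
) -> set[str]:
    """Query contigs that belong to the viral catalogue.

    A query is viral iff some catalogue contig matches it at 100% identity
    across the whole length of the shorter of the two sequences (either
    orientation), with that length at least ``min_aln`` bp. Symmetric in
    query/catalogue roles by construction.
    """
    viral: set[str] = set()
    for qid, qseq in queries.items():
        qseq = qseq.upper()
        qrc = qseq.translate(_RC)[::-1]
        for vseq in catalogue.values():
            short_len = min(len(qseq), len(vseq))
            if short_len < min_aln:
                continue
            if len(qseq) <= len(vseq):
                if qseq in vseq or qrc in vseq:
                    viral.add(qid)
                    break
            else:
                if vseq in qseq or vseq in qrc:
                    viral.add(qid)
                    break
    return viral


# ---------------------------------------------------------------------------
# network construction


def _phylum(taxon: str) -> str:
    return taxon.split(";")[0].strip()


def build_network(
    matches: Sequence[ViralMatch],
    host_spacer_db: pd.DataFrame | None = None,
    catalogue: Mapping[str, str] | None = None,
    host_identity: float = 100.0,
) -> tuple[list[NetworkEdge], pd.DataFrame]:
    """Aggregate spacer-virus matches into a biogeography/host network.

    ``spacer_to_virus`` edges count distinct (spacer, viral contig) pairs
    per (spacer source system -> viral source system). When a host-spacer
    database (columns spacer_seq, host_taxon, source_system) and the
    catalogue sequences are given, ``virus_to_host`` edges link each
    matched viral cluster to host taxa whose spacers occur full-length at
    100% identity in its contigs; the host table flags clusters whose
    hosts span more than one phylum as generalists.
    """
    edges: dict[tuple[str, str, str], int] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for m in matches:
        pair = (m.spacer_id, m.viral_contig)
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        key = ("spacer_to_virus", m.spacer_system, m.viral_system)
        edges[key] = edges.get(key, 0) + 1

    host_rows: list[dict] = []
    if host_spacer_db is not None and catalogue is not None:
        matched_contigs = {m.viral_contig: m.viral_cluster for m in matches}
        cluster_hosts: dict[str, set[str]] = {}
        for row in host_spacer_db.itertuples():
            hseq = str(row.spacer_seq).upper()
            hrc = hseq.translate(_RC)[::-1]
            for vid, cluster in matched_contigs.items():
                vseq = catalogue[vid]
                if hseq in vseq or hrc in vseq:  # full-length exact occurrence
                    cluster_hosts.setdefault(cluster, set()).add(str(row.host_taxon))
                    key = ("virus_to_host", cluster, str(row.host_taxon))
                    edges[key] = edges.get(key, 0) + 1
        for cluster, hosts in sorted(cluster_hosts.items()):
            phyla = {_phylum(h) for h in hosts}
            host_rows.append(
                {
                    "viral_cluster": cluster,
                    "host_taxa": ",".join(sorted(hosts)),
                    "n_phyla": len(phyla),
                    "generalist": len(phyla) > 1,
                }
            )
    edge_list = [
        NetworkEdge(kind=k, from_node=a, to_node=b, weight=w)
        for (k, a, b), w in sorted(edges.items())
    ]
    return edge_list, pd.DataFrame(host_rows)


def network_to_json(edges: Sequence[NetworkEdge], path: str | Path) -> None:
    nodes = sorted({e.from_node for e in edges} | {e.to_node for e in edges})
    doc = {
        "nodes": nodes,
        "edges": [vars(e) for e in edges],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def edges_to_tsv(edges: Sequence[NetworkEdge], path: str | Path) -> None:
    pd.DataFrame([vars(e) for e in edges]).to_csv(path, sep="\t", index=False)
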