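"""Seed-and-extend fragment alignment shared by the ANI and cluster classifiers.

A query fragment is anchored on a target by exact k-mer seeds (so unrelated
sequences, which share no seeds beyond chance, simply do not align — the
role the e-value cutoff plays in BLAST-style searches) and then scored with
a banded gapped alignment around the seeded diagonal. Identity is matching
columns over alignment columns, gaps included.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class FragmentHit:
    target_id: str
    target_start: int
    target_end: int
    identity: float  # fraction in [0, 1]
    columns: int
    strand: str


class TargetIndex:
    """Exact k-mer index over a set of target sequences."""

    def __init__(self, targets: dict[str, str], k: int = 16) -> None:
        self.k = k
        self.targets = targets
        self.ids = list(targets)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ti, tid in enumerate(self.ids):
            seq = targets[tid]
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((ti, i))


def _cigar_stats(cigar: str, query: str, target: str, t_start: int) -> tuple[int, int, int]:
    """(columns, matches, target span) for an edlib extended cigar."""
    import re

    qpos, tpos = 0, t_start
    columns = matches = 0
    for n_str, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n_str)
        if op in "=M":
            for j in range(n):
                if query[qpos + j] == target[tpos + j] and query[qpos + j] != "N":
                    matches += 1
            qpos += n
            tpos += n
            columns += n
        elif op == "X":
            qpos += n
            tpos += n
            columns += n
        elif op == "I":
            qpos += n
            columns += n
        elif op == "D":
            tpos += n
            columns += n
    return columns, matches, tpos - t_start


def best_fragment_hit(
    fragment: str,
    index: TargetIndex,
    max_divergence: float = 0.35,
    seed_stride: int | None = None,
    max_candidates: int = 8,
    diag_bin: int = 32,
) -> FragmentHit | None:
    """Best placement of a fragment on the indexed targets, or None.

    Candidate diagonals are binned (width ``diag_bin``) and ranked by seed
    count; the ``max_candidates`` best bins per strand are scored with a
    banded alignment allowing up to ``max_divergence`` edits per column.
    """
    k = index.k
    stride = seed_stride or max(1, k // 2)
    best: FragmentHit | None = None
    best_key: tuple | None = None
    for strand in ("+", "-"):
        seq = fragment if strand == "+" else fragment.translate(_RC)[::-1]
        if len(seq) < k:
            continue
        bins: dict[tuple[int, int], int] = {}
        positions = list(range(0, len(seq) - k + 1, stride))
        if positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        for qpos in positions:
            for ti, tpos in index.index.get(seq[qpos : qpos + k], ()):
                bins[(ti, (tpos - qpos) // diag_bin)] = (
                    bins.get((ti, (tpos - qpos) // diag_bin), 0) + 1
                )
        ranked = sorted(bins.items(), key=lambda kv: (-kv[1], kv[0]))[:max_candidates]
        max_edits = int(max_divergence * len(seq))
        pad = max_edits + diag_bin
        for (ti, dbin), _count in ranked:
            target = index.targets[index.ids[ti]]
            diag = dbin * diag_bin
            w_start = max(0, diag - pad)
            w_end = min(len(target), diag + len(seq) + pad)
            if w_end - w_start < len(seq) - max_edits:
                continue
            res = edlib.align(seq, target[w_start:w_end], mode="HW", task="path", k=max_edits)
            if res["editDistance"] < 0:
                continue
            loc = min(res["locations"])
            t_start = w_start + loc[0]
            columns, matches, span = _cigar_stats(res["cigar"], seq, target, t_start)
            if columns == 0:
                continue
            identity = matches / columns
            key = (-identity, ti, t_start, strand)
            if best_key is None or key < best_key:
                best_key = key
                best = FragmentHit(
                    target_id=index.ids[ti],
                    target_start=t_start,
                    target_end=t_start + span,
                    identity=identity,
                    columns=columns,
                    strand=strand,
                )
    return best
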