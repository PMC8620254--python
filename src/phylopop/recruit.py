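"""Fragment recruitment: align reads to a reference under a minimum-identity rule.

The recruiter emulates the ``minid`` semantics of production read mappers at
desk scale: k-mer seeds on the reference select candidate diagonals, each
candidate is scored with a banded gapped alignment (edlib), and a read is
reported once, at its best-identity placement, if that identity reaches the
threshold (default 0.95, i.e. 95% minimum alignment identity). Externally
produced SAM alignments can be ingested instead; identity is always
recomputed from the alignment itself, never trusted from tags.

Identity is defined as matching columns / alignment columns, where columns
include gap columns and exclude terminal soft-clips. N bases never match.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
import pysam
from Bio import SeqIO

from phylopop.assembly import ReferenceAssembly

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
ALLELES = ("A", "C", "G", "T", "DEL")


@dataclass
class ReadAlignment:
    """A single accepted read placement on the reference.

    ``mismatches`` holds (ref_pos, read_base) pairs; ``deletions`` holds
    reference positions spanned by the read but absent from it (these count
    toward depth and toward the DEL allele).
    """

    read_id: str
    contig_id: str
    ref_start: int
    ref_end: int  # half-open
    identity: float
    strand: str = "+"
    mismatches: list[tuple[int, str]] = field(default_factory=list)
    deletions: list[int] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.ref_end - self.ref_start


class DepthProfile:
    """Per-base read depth per contig, plus the aligned-read count.

    The genome-wide mean depth is the ratio of summed base depths to the
    base count — the quantity every relative-coverage figure is scaled by.
    """

    def __init__(self, ref: ReferenceAssembly) -> None:
        self.contig_ids = ref.contig_ids
        self.depth: dict[str, np.ndarray] = {
            cid: np.zeros(len(seq), dtype=np.int64) for cid, seq in ref.contigs.items()
        }
        self.aligned_read_count = 0

    def contig_mean(self, contig_id: str) -> float:
        return float(self.depth[contig_id].mean())

    def genome_mean(self) -> float:
        total = sum(int(d.sum()) for d in self.depth.values())
        nbases = sum(d.size for d in self.depth.values())
        return total / nbases

    def total_depth(self) -> int:
        return sum(int(d.sum()) for d in self.depth.values())

    def to_bedgraph(self, path: str | Path) -> None:
        """Write depth as bedGraph runs (contig, start, end, depth; 0-based half-open)."""
        with open(path, "w") as fh:
            for cid in self.contig_ids:
                d = self.depth[cid]
                if d.size == 0:
                    continue
                breaks = np.flatnonzero(np.diff(d)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [d.size]))
                for s, e in zip(starts, ends):
                    fh.write(f"{cid}\t{s}\t{e}\t{d[s]}\n")


class AlleleCounts:
    """Per-position counts of A, C, G, T and DEL (deletion-spanning reads).

    Counts sum to the depth at each position except where reads carried
    ambiguous bases, hence A+C+G+T+DEL <= depth always holds.
    """

    def __init__(self, ref: ReferenceAssembly) -> None:
        self.contig_ids = ref.contig_ids
        self.counts: dict[str, np.ndarray] = {
            cid: np.zeros((5, len(seq)), dtype=np.int64) for cid, seq in ref.contigs.items()
        }

    def at(self, contig_id: str, pos: int) -> dict[str, int]:
        col = self.counts[contig_id][:, pos]
        return dict(zip(ALLELES, (int(x) for x in col)))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\tA\tC\tG\tT\tDEL\n")
            for cid in self.contig_ids:
                mat = self.counts[cid]
                nonzero = np.flatnonzero(mat.sum(axis=0))
                for p in nonzero:
                    a, c, g, t, dl = (int(x) for x in mat[:, p])
                    fh.write(f"{cid}\t{p}\t{a}\t{c}\t{g}\t{t}\t{dl}\n")


# ---------------------------------------------------------------------------
# read input


def iter_reads(reads: str | Path | Iterable[tuple[str, str]]) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA/FASTQ (plain or gzip) or pairs."""
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        stem = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq).upper()
    else:
        for rid, seq in reads:
            yield rid, seq.upper()


# ---------------------------------------------------------------------------
# recruitment


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class _ReferenceIndex:
    """Exact k-mer index over reference contigs (forward strand)."""

    def __init__(self, ref: ReferenceAssembly, k: int) -> None:
        self.k = k
        self.ref = ref
        self.rank = {cid: i for i, cid in enumerate(ref.contig_ids)}
        self.arrays = [
            np.frombuffer(ref.contigs[cid].encode(), dtype=np.uint8) for cid in ref.contig_ids
        ]
        self.index: dict[str, list[tuple[int, int]]] = {}
        for cid, seq in ref.contigs.items():
            ci = self.rank[cid]
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((ci, i))

    def candidate_diagonals(self, read: str) -> list[tuple[int, int]]:
        """Sorted (contig_rank, diagonal) pairs sharing a seed with the read.

        Seeds are taken at non-overlapping offsets plus the read tail, which
        guarantees every exact occurrence of the read is found and tolerates
        scattered substitutions (each error can spoil at most two seeds).
        """
        k = self.k
        out: set[tuple[int, int]] = set()
        positions = list(range(0, len(read) - k + 1, k))
        if positions and positions[-1] != len(read) - k:
            positions.append(len(read) - k)
        get = self.index.get
        for qpos in positions:
            hits = get(read[qpos : qpos + k])
            if hits:
                for ci, rpos in hits:
                    out.add((ci, rpos - qpos))
        return sorted(out)


def _parse_edlib_cigar(
    cigar: str, read: str, ref_seq: str, ref_start: int
) -> tuple[int, int, int, list[tuple[int, str]], list[int], int]:
    """Walk an edlib extended cigar; return columns, matches, gap columns,
    mismatch (ref_pos, read_base) pairs, deleted ref positions, and ref span."""
    qpos = 0
    rpos = ref_start
    columns = matches = gapcols = 0
    mismatches: list[tuple[int, str]] = []
    deletions: list[int] = []
    for n_str, op in _CIGAR_RE.findall(cigar):
        n = int(n_str)
        if op in "=M":
            for j in range(n):
                # edlib treats N as mismatching only against other letters;
                # enforce "N never matches" explicitly
                if read[qpos + j] == ref_seq[rpos + j] and read[qpos + j] != "N":
                    matches += 1
                else:
                    mismatches.append((rpos + j, read[qpos + j]))
            qpos += n
            rpos += n
            columns += n
        elif op == "X":
            for j in range(n):
                mismatches.append((rpos + j, read[qpos + j]))
            qpos += n
            rpos += n
            columns += n
        elif op == "I":  # base in read, gap in reference
            qpos += n
            columns += n
            gapcols += n
        elif op == "D":  # gap in read, base in reference (deletion)
            deletions.extend(range(rpos, rpos + n))
            rpos += n
            columns += n
            gapcols += n
    return columns, matches, gapcols, mismatches, deletions, rpos - ref_start


def recruit_reads(
    reads: str | Path | Iterable[tuple[str, str]],
    ref: ReferenceAssembly,
    minid: float = 0.95,
    k: int = 21,
    min_span_frac: float = 0.9,
    max_gap_columns: int = 2,
) -> list[ReadAlignment]:
    """Recruit reads to the reference at a minimum alignment identity.

    Each read is reported at most once, at its best-identity ungapped
    placement (ties broken by lowest contig rank, then lowest reference
    start, then forward strand); when no ungapped placement reaches
    ``minid``, a gapped rescue with up to ``max_gap_columns`` gap columns
    is attempted. A placement is accepted iff identity >= ``minid`` and
    the aligned span covers >= ``min_span_frac`` of the read. Both
    orientations are tried.

    Parameters
    ----------
    reads
        FASTA/FASTQ path (optionally gzipped) or an iterable of
        (read_id, sequence) pairs.
    ref
        The reference assembly.
    minid
        Minimum alignment identity in [0, 1]; default 0.95.
    k
        Seed length, 11..31.
    """
    if not 11 <= k <= 31:
        raise ValueError(f"seed length k must be in [11, 31]: got {k}")
    if not ref.contigs:
        raise ValueError("empty reference assembly")
    index = _ReferenceIndex(ref, k)
    contig_ids = ref.contig_ids
    seqs = [ref.contigs[cid] for cid in contig_ids]
    arrays = index.arrays
    ord_n = ord("N")

    accepted: list[ReadAlignment] = []
    n_short = 0
    n_total = 0
    for rid, seq in iter_reads(reads):
        n_total += 1
        length = len(seq)
        if length < k:
            n_short += 1
            continue
        max_edits = int((1.0 - minid) * length) + max_gap_columns
        pad = max_edits + 2
        candidates: list[tuple[str, str, np.ndarray, int, int]] = []
        for strand in ("+", "-"):
            oriented = seq if strand == "+" else seq.translate(_RC_TABLE)[::-1]
            arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
            for ci, diag in index.candidate_diagonals(oriented):
                candidates.append((strand, oriented, arr, ci, diag))

        # ungapped scoring at each candidate diagonal; gap rescue below only
        # applies to reads no ungapped placement accepts
        best: tuple | None = None
        for strand, oriented, arr, ci, diag in candidates:
            ref_arr = arrays[ci]
            if diag < 0 or diag + length > ref_arr.size:
                continue
            window = ref_arr[diag : diag + length]
            mism_mask = (window != arr) | (arr == ord_n) | (window == ord_n)
            n_mism = int(mism_mask.sum())
            identity = (length - n_mism) / length
            if identity < minid:
                continue
            key = (-identity, ci, diag, strand)
            if best is None or key < best[0]:
                mism = [(diag + int(p), oriented[int(p)]) for p in np.flatnonzero(mism_mask)]
                best = (
                    key,
                    ReadAlignment(
                        read_id=rid,
                        contig_id=contig_ids[ci],
                        ref_start=diag,
                        ref_end=diag + length,
                        identity=identity,
                        strand=strand,
                        mismatches=mism,
                        deletions=[],
                    ),
                )

        if best is None:
            # gapped rescue, only for reads no ungapped placement accepts:
            # banded alignment in a window around each diagonal
            for strand, oriented, arr, ci, diag in candidates:
                ref_seq = seqs[ci]
                w_start = max(0, diag - pad)
                w_end = min(len(ref_seq), diag + length + pad)
                if w_end - w_start < length - max_edits:
                    continue
                res = edlib.align(
                    oriented, ref_seq[w_start:w_end], mode="HW", task="path", k=max_edits
                )
                if res["editDistance"] < 0:
                    continue
                loc = min(res["locations"])
                aln_start = w_start + loc[0]
                columns, matches, gapcols, mism, dels, span = _parse_edlib_cigar(
                    res["cigar"], oriented, ref_seq, aln_start
                )
                if gapcols > max_gap_columns:
                    continue
                identity = matches / columns
                if identity < minid or span < min_span_frac * length:
                    continue
                key = (-identity, ci, aln_start, strand)
                if best is None or key < best[0]:
                    best = (
                        key,
                        ReadAlignment(
                            read_id=rid,
                            contig_id=contig_ids[ci],
                            ref_start=aln_start,
                            ref_end=aln_start + span,
                            identity=identity,
                            strand=strand,
                            mismatches=mism,
                            deletions=dels,
                        ),
                    )
        if best is not None:
            accepted.append(best[1])
    if n_total == 0:
        raise ValueError("no reads supplied")
    if n_short:
        logger.info("skipped %d reads shorter than k=%d", n_short, k)
    return accepted


# ---------------------------------------------------------------------------
# SAM ingestion


def read_alignments_sam(
    path: str | Path,
    ref: ReferenceAssembly,
    minid: float | None = None,
) -> list[ReadAlignment]:
    """Ingest a SAM file, recomputing identity from each alignment record.

    Identity is matching columns / alignment columns (gap columns included,
    soft clips excluded), recomputed against the in-memory reference — MD
    tags or NM fields are not trusted. Unmapped records are ignored and
    counted in the log; records below ``minid`` (when given) are excluded.
    """
    unknown: set[str] = set()
    out: list[ReadAlignment] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            cid = rec.reference_name
            if cid not in ref.contigs:
                unknown.add(str(cid))
                continue
            ref_seq = ref.contigs[cid]
            read_seq = (rec.query_sequence or "").upper()
            qpos = 0
            rpos = rec.reference_start
            columns = matches = 0
            mismatches: list[tuple[int, str]] = []
            deletions: list[int] = []
            for op, n in rec.cigartuples or []:
                if op in (0, 7, 8):  # M, =, X
                    for j in range(n):
                        b = read_seq[qpos + j] if read_seq else "N"
                        if b == ref_seq[rpos + j] and b != "N":
                            matches += 1
                        else:
                            mismatches.append((rpos + j, b))
                    qpos += n
                    rpos += n
                    columns += n
                elif op == 1:  # I
                    qpos += n
                    columns += n
                elif op == 2:  # D
                    deletions.extend(range(rpos, rpos + n))
                    rpos += n
                    columns += n
                elif op in (4,):  # S: excluded from columns
                    qpos += n
                elif op in (3,):  # N: skip region, not counted
                    rpos += n
                # H/P consume nothing relevant
            if columns == 0:
                continue
            identity = matches / columns
            if minid is not None and identity < minid:
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name or "",
                    contig_id=str(cid),
                    ref_start=rec.reference_start,
                    ref_end=rpos,
                    identity=identity,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=mismatches,
                    deletions=deletions,
                )
            )
    if unknown:
        raise ValueError(f"SAM references contigs absent from the reference: {sorted(unknown)}")
    if n_unmapped:
        logger.info("ignored %d unmapped SAM records", n_unmapped)
    return out


def write_sam(alignments: Sequence[ReadAlignment], ref: ReferenceAssembly, path: str | Path) -> None:
    """Write accepted placements as a minimal SAM file (ungapped runs encoded
    as M with mismatches implicit; deletions as D)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq in ref.contigs.items()],
    }
    rank = {cid: i for i, cid in enumerate(ref.contig_ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = rank[aln.contig_id]
            rec.reference_start = aln.ref_start
            rec.mapping_quality = 60
            rec.flag = 16 if aln.strand == "-" else 0
            # rebuild the query sequence from the reference plus recorded edits
            seq = list(ref.contigs[aln.contig_id][aln.ref_start : aln.ref_end])
            for pos, base in aln.mismatches:
                seq[pos - aln.ref_start] = base
            delset = set(aln.deletions)
            cigar: list[tuple[int, int]] = []
            query_chars: list[str] = []
            for p in range(aln.ref_start, aln.ref_end):
                if p in delset:
                    op = 2
                else:
                    op = 0
                    query_chars.append(seq[p - aln.ref_start])
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + 1)
                else:
                    cigar.append((op, 1))
            rec.query_sequence = "".join(query_chars)
            rec.cigartuples = cigar
            out.write(rec)


# ---------------------------------------------------------------------------
# pileup and merging


def pileup(
    alignments: Sequence[ReadAlignment], ref: ReferenceAssembly
) -> tuple[DepthProfile, AlleleCounts]:
    """Pile alignments into per-base depth and per-position allele counts.

    Depth at a position is the number of alignments spanning it; a read
    spanning a deletion contributes to depth and to the DEL allele there.
    Reference-base counts are depth minus non-reference observations, so
    the counts reconcile with depth exactly when no read carried N.
    """
    profile = DepthProfile(ref)
    counts = AlleleCounts(ref)
    ref_idx: dict[str, np.ndarray] = {}
    for cid, seq in ref.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        idx = np.full(arr.size, -1, dtype=np.int8)
        for base, bi in _BASE_INDEX.items():
            idx[arr == ord(base)] = bi
        ref_idx[cid] = idx

    # depth via difference arrays
    diffs = {cid: np.zeros(len(seq) + 1, dtype=np.int64) for cid, seq in ref.contigs.items()}
    nonref = {cid: np.zeros(len(seq), dtype=np.int64) for cid, seq in ref.contigs.items()}
    for aln in alignments:
        diffs[aln.contig_id][aln.ref_start] += 1
        diffs[aln.contig_id][aln.ref_end] -= 1
        cmat = counts.counts[aln.contig_id]
        for pos, base in aln.mismatches:
            bi = _BASE_INDEX.get(base)
            nonref[aln.contig_id][pos] += 1
            if bi is not None:
                cmat[bi, pos] += 1
            # N read bases count toward depth but no allele
        for pos in aln.deletions:
            nonref[aln.contig_id][pos] += 1
            cmat[4, pos] += 1
    for cid in ref.contig_ids:
        profile.depth[cid] = np.cumsum(diffs[cid][:-1])
        idx = ref_idx[cid]
        refcount = profile.depth[cid] - nonref[cid]
        cmat = counts.counts[cid]
        valid = idx >= 0
        cmat[idx[valid], np.flatnonzero(valid)] += refcount[valid]
    profile.aligned_read_count = len(alignments)
    return profile, counts


def merge_profiles(
    profiles: Sequence[DepthProfile],
    allele_counts: Sequence[AlleleCounts] | None = None,
) -> DepthProfile | tuple[DepthProfile, AlleleCounts]:
    """Element-wise sum of depth profiles (and optionally allele counts).

    Used to pool filter fractions of one sample into a merged metagenome;
    the merged mean depth is the ratio of summed base depths to base count.
    """
    if not profiles:
        raise ValueError("no profiles to merge")
    first = profiles[0]
    for p in profiles[1:]:
        if p.contig_ids != first.contig_ids or any(
            p.depth[c].size != first.depth[c].size for c in first.contig_ids
        ):
            raise ValueError("profiles computed against different references")
    merged = DepthProfile.__new__(DepthProfile)
    merged.contig_ids = list(first.contig_ids)
    merged.depth = {
        cid: np.sum([p.depth[cid] for p in profiles], axis=0) for cid in first.contig_ids
    }
    merged.aligned_read_count = sum(p.aligned_read_count for p in profiles)
    if allele_counts is None:
        return merged
    mc = AlleleCounts.__new__(AlleleCounts)
    mc.contig_ids = list(first.contig_ids)
    mc.counts = {
        cid: np.sum([a.counts[cid] for a in allele_counts], axis=0) for cid in first.contig_ids
    }
    return merged, mc
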