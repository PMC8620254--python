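"""Pairwise marker identity and fragment-based average nucleotide identity.

Marker identity counts matching columns over alignment columns of a global
alignment (terminal gaps free and excluded), the convention under which two
16S rRNA genes of 1505 nt differing at 17 sites are "99%" identical and two
366-aa FmoA proteins with six substitutions are "98%".

ANI follows the fragment convention (ANIb): the query genome is chopped
into 1020-bp windows, each is aligned to the subject, fragments passing the
identity/coverage floor are kept, ANI is their mean identity, and the
alignment fraction is the kept bases over the query length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from Bio import Align, SeqIO

from phylopop._align import TargetIndex, best_fragment_hit

_PROTEIN_ONLY = set("EFILPQZ*")  # residues outside the nucleotide alphabet


@dataclass
class PairwiseIdentity:
    alignment_length: int  # columns, terminal gaps excluded
    mismatches: int
    gap_columns: int
    identity_percent: float
    identity_rounded: int  # half-up integer percent

    @classmethod
    def from_counts(cls, columns: int, mismatches: int, gap_columns: int = 0) -> "PairwiseIdentity":
        if columns <= 0:
            raise ValueError("alignment has no columns")
        pct = 100.0 * (columns - mismatches - gap_columns) / columns
        return cls(
            alignment_length=columns,
            mismatches=mismatches,
            gap_columns=gap_columns,
            identity_percent=pct,
            identity_rounded=int(math.floor(pct + 0.5)),
        )


@dataclass
class ANIResult:
    ani_percent: float
    alignment_fraction: float  # percent of query genome aligned
    fragment_length: int
    n_fragments_used: int
    n_fragments_total: int


def is_protein(seq: str) -> bool:
    return bool(set(seq.upper()) & _PROTEIN_ONLY)


def _global_align(a: str, b: str) -> tuple[str, str]:
    """Global alignment, match +1 / mismatch -1 / gap -2, terminal gaps free."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    for attr in ("end_insertion_score", "end_deletion_score"):
        if hasattr(aligner, attr):  # Biopython >= 1.86 naming
            setattr(aligner, attr, 0)
        else:  # pragma: no cover - older releases
            aligner.target_end_gap_score = 0
            aligner.query_end_gap_score = 0
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: str, b: str, aligned: bool | None = None) -> PairwiseIdentity:
    """Identity of two sequences, aligning them globally if needed.

    Pass ``aligned=True`` (or supply gapped sequences of equal length) to
    count columns directly. Terminal gap columns are excluded; internal gap
    columns count as non-matching columns. Rounding of the integer percent
    is half-up.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if aligned is None:
        aligned = "-" in a or "-" in b
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        row_a, row_b = a.upper(), b.upper()
    else:
        row_a, row_b = _global_align(a, b)
    # trim terminal gap columns (leading/trailing runs containing a gap)
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    # N is an ambiguity code for nucleotides (never a match) but a residue
    # (asparagine) in proteins
    protein = is_protein(a) or is_protein(b)
    columns = mismatches = gaps = 0
    for ca, cb in zip(row_a[start:end], row_b[start:end]):
        columns += 1
        if ca == "-" or cb == "-":
            gaps += 1
        elif ca != cb or (ca == "N" and not protein):
            mismatches += 1
    return PairwiseIdentity.from_counts(columns, mismatches, gaps)


def _load_genome(genome: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {k: v.upper() for k, v in genome.items()}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}


def fragments_of(genome: Mapping[str, str], frag: int, min_tail: int = 100) -> list[str]:
    """Consecutive fragment windows per contig; a trailing window shorter
    than ``min_tail`` is dropped."""
    out: list[str] = []
    for seq in genome.values():
        for i in range(0, len(seq), frag):
            piece = seq[i : i + frag]
            if len(piece) >= min_tail:
                out.append(piece)
    return out


def ani(
    genome_a: str | Path | Mapping[str, str],
    genome_b: str | Path | Mapping[str, str],
    frag: int = 1020,
    min_frag_identity: float = 30.0,
    min_frag_cov: float = 0.70,
) -> ANIResult:
    """Fragment-based one-way ANI of genome A against genome B.

    A is chopped into ``frag``-length windows; each window is seeded and
    aligned to B, kept when its identity reaches ``min_frag_identity``
    percent over at least ``min_frag_cov`` of the fragment. ANI is the mean
    identity of kept fragments (in percent); the alignment fraction is the
    kept aligned bases over the length of A.
    """
    a = _load_genome(genome_a)
    b = _load_genome(genome_b)
    total_a = sum(len(s) for s in a.values())
    total_b = sum(len(s) for s in b.values())
    if total_a < frag or total_b < frag:
        raise ValueError(f"genome shorter than one fragment ({frag} bp)")
    if total_a < 2 * frag or total_b < 2 * frag:
        raise ValueError(f"genomes must be at least 2 x fragment length ({2 * frag} bp)")
    index = TargetIndex(b, k=16)
    frags = fragments_of(a, frag)
    kept_ids: list[float] = []
    kept_bp = 0
    for piece in frags:
        hit = best_fragment_hit(piece, index)
        if hit is None:
            continue
        coverage = hit.columns / len(piece)  # whole fragment is consumed by the aligner
        if 100.0 * hit.identity >= min_frag_identity and coverage >= min_frag_cov:
            kept_ids.append(hit.identity)
            kept_bp += len(piece)
    ani_pct = 100.0 * sum(kept_ids) / len(kept_ids) if kept_ids else 0.0
    return ANIResult(
        ani_percent=ani_pct,
        alignment_fraction=100.0 * kept_bp / total_a,
        fragment_length=frag,
        n_fragments_used=len(kept_ids),
        n_fragments_total=len(frags),
    )


def ani_symmetric(
    genome_a: str | Path | Mapping[str, str],
    genome_b: str | Path | Mapping[str, str],
    **kwargs,
) -> tuple[ANIResult, ANIResult]:
    """ANI in both directions (A vs B, B vs A)."""
    return ani(genome_a, genome_b, **kwargs), ani(genome_b, genome_a, **kwargs)
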