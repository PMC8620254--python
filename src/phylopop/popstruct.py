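"""SNP classification, low-coverage regions, and relative-coverage statistics.

The central statistic is relative coverage,

    100 x mean read depth(region) / mean read depth(whole reference),

with mean depth defined as the sum of per-base read depths divided by the
number of bases. Relative coverage of a region is read as the percentage of
the population whose genomes carry that region: a segment present in every
cell tracks the genome-wide depth (100%), a segment carried by a third of
cells recruits a third of the reads (~33%).

SNPs are classified by variant frequency — the fraction of aligned reads at
a position carrying a non-reference allele (deletion-spanning reads count
in the denominator): calls at frequency >= 0.01 are reported, and calls at
frequency >= 0.9 are considered fixed in the population. Calls supported by
fewer than five reads are flagged, since at that depth a recurrent
sequencing error is indistinguishable from a rare allele.

Low-coverage regions (LCRs) are found by a windowed rule — maximal runs of
windows whose mean depth falls below a fraction (default 0.8) of the
genome-wide mean — merged across the small gaps between adjacent contigs
of a scaffold, never across scaffolds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phylopop.assembly import ReferenceAssembly
from phylopop.recruit import ALLELES, AlleleCounts, DepthProfile
from phylopop._rng import child_rng

#: a region is a (contig, start, end) segment or a list of segments
Region = tuple[str, int, int] | Sequence[tuple[str, int, int]]


@dataclass
class SNPCall:
    contig: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str  # one of A/C/G/T or "DEL"
    variant_frequency: float
    depth: int
    alt_count: int
    klass: str  # "reported" or "fixed"
    low_depth_flag: bool


@dataclass
class LCR:
    """A low-coverage region; may span adjacent contigs of one scaffold."""

    id: str
    scaffold: str
    segments: list[tuple[str, int, int]]  # per-contig (contig, start, end)
    length: int
    mean_depth: float
    relative_coverage_percent: float

    @property
    def first_contig(self) -> str:
        return self.segments[0][0]

    @property
    def last_contig(self) -> str:
        return self.segments[-1][0]

    def contains(self, contig: str, pos: int) -> bool:
        return any(c == contig and s <= pos < e for c, s, e in self.segments)


@dataclass
class DiffResult:
    region_id: str
    log2_fold_change: float
    p_value: float
    p_adjusted: float


# ---------------------------------------------------------------------------
# SNP calling


def call_snps(
    counts: AlleleCounts,
    ref: ReferenceAssembly,
    report_threshold: float = 0.01,
    fixed_threshold: float = 0.9,
    low_depth: int = 5,
) -> list[SNPCall]:
    """Call one SNP per (position, alternate allele) above the report threshold.

    A call is emitted for every non-reference allele (including DEL) with a
    positive count whose variant frequency reaches ``report_threshold``
    (inclusive — a frequency exactly at a threshold is in). Frequency uses
    the total allele-count depth at the position as denominator, so
    deletion-spanning reads dilute substitution frequencies. The
    ``low_depth_flag`` marks calls whose supporting read count is below
    ``low_depth``.
    """
    if not 0 < report_threshold <= 1 or not 0 < fixed_threshold <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    if report_threshold > fixed_threshold:
        raise ValueError("report_threshold must not exceed fixed_threshold")
    calls: list[SNPCall] = []
    for cid in counts.contig_ids:
        mat = counts.counts[cid]
        depth = mat.sum(axis=0)
        seq = ref.contigs[cid]
        ref_idx = np.full(len(seq), -1, dtype=np.int8)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for ai, base in enumerate("ACGT"):
            ref_idx[arr == ord(base)] = ai
        for ai, allele in enumerate(ALLELES):
            row = mat[ai]
            cand = np.flatnonzero((row > 0) & (ref_idx != ai) & (depth > 0))
            for p in cand:
                vf = row[p] / depth[p]
                if vf < report_threshold:
                    continue
                calls.append(
                    SNPCall(
                        contig=cid,
                        pos=int(p),
                        ref_base=seq[p],
                        alt_base=allele,
                        variant_frequency=float(vf),
                        depth=int(depth[p]),
                        alt_count=int(row[p]),
                        klass="fixed" if vf >= fixed_threshold else "reported",
                        low_depth_flag=bool(row[p] < low_depth),
                    )
                )
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt_base))
    return calls


def snps_to_tsv(calls: Sequence[SNPCall], path: str | Path) -> None:
    pd.DataFrame([vars(c) for c in calls]).rename(columns={"klass": "class"}).to_csv(
        path, sep="\t", index=False
    )


def snps_to_vcf(calls: Sequence[SNPCall], ref: ReferenceAssembly, path: str | Path) -> None:
    """Minimal VCF 4.2: CHROM/POS/REF/ALT with VF, DP and CLASS in INFO.

    DEL alleles are written with the anchor-base convention (REF = base
    before + deleted base, ALT = anchor base)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for cid, seq in ref.contigs.items():
            fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
        fh.write('##INFO=<ID=VF,Number=1,Type=Float,Description="Variant frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="reported or fixed">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            if c.alt_base == "DEL":
                if c.pos == 0:
                    continue  # no anchor base; TSV output retains the call
                anchor = ref.contigs[c.contig][c.pos - 1]
                pos, refa, alta = c.pos, anchor + c.ref_base, anchor
            else:
                pos, refa, alta = c.pos + 1, c.ref_base, c.alt_base
            info = f"VF={c.variant_frequency:.6g};DP={c.depth};CLASS={c.klass}"
            fh.write(f"{c.contig}\t{pos}\t.\t{refa}\t{alta}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# depth statistics


def _segments(region: Region) -> list[tuple[str, int, int]]:
    if isinstance(region, tuple) and len(region) == 3 and isinstance(region[0], str):
        return [region]  # type: ignore[list-item]
    return list(region)  # type: ignore[arg-type]


def mean_depth(profile: DepthProfile, region: Region) -> float:
    """Mean read depth over a region: summed base depths / base count."""
    total = 0
    nbases = 0
    for contig, start, end in _segments(region):
        if contig not in profile.depth:
            raise KeyError(f"contig {contig} not in profile")
        d = profile.depth[contig]
        if not 0 <= start <= end <= d.size:
            raise ValueError(f"region ({contig}, {start}, {end}) outside reference")
        total += int(d[start:end].sum())
        nbases += end - start
    if nbases == 0:
        raise ValueError("zero-length region")
    return total / nbases


def relative_coverage(profile: DepthProfile, region: Region) -> float:
    """Relative coverage percent: 100 x mean depth(region) / mean depth(genome)."""
    genome = profile.genome_mean()
    if genome == 0:
        raise ValueError("genome-wide mean depth is zero")
    return 100.0 * mean_depth(profile, region) / genome


# ---------------------------------------------------------------------------
# LCR detection


def detect_lcrs(
    profile: DepthProfile,
    ref: ReferenceAssembly,
    low_frac: float = 0.8,
    window: int = 500,
    step: int = 100,
    min_len: int = 2000,
    gap_merge: int = 500,
) -> list[LCR]:
    """Detect low-coverage regions on each scaffold.

    Contigs of a scaffold are concatenated in rank order and scanned with
    sliding windows; positions covered by any window whose mean depth is
    below ``low_frac`` x genome mean are marked low. Maximal low runs are
    merged when separated by fewer than ``gap_merge`` bp, kept when at
    least ``min_len`` long, and mapped back to per-contig segments — so a
    region straddling adjacent contigs of one scaffold is reported as a
    single LCR, while scaffold boundaries are never crossed.
    """
    if window < step:
        raise ValueError("window must be >= step")
    genome = profile.genome_mean()
    if genome == 0:
        raise ValueError("genome-wide mean depth is zero")
    threshold = low_frac * genome
    lcrs: list[LCR] = []
    n = 0
    for sid, members in ref.scaffolds.items():
        depth = np.concatenate([profile.depth[c] for c in members])
        offsets: list[tuple[str, int, int]] = []  # (contig, concat_start, concat_end)
        pos = 0
        for c in members:
            size = profile.depth[c].size
            offsets.append((c, pos, pos + size))
            pos += size
        length = depth.size
        low = np.zeros(length, dtype=bool)
        csum = np.concatenate(([0], np.cumsum(depth)))
        starts = list(range(0, max(1, length - window + 1), step))
        if starts and starts[-1] + window < length:
            starts.append(length - window)
        for s in starts:
            e = min(s + window, length)
            if (csum[e] - csum[s]) / (e - s) < threshold:
                low[s:e] = True
        # maximal runs
        runs: list[list[int]] = []
        in_run = False
        for i in np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0])))):
            if not in_run:
                runs.append([int(i), -1])
                in_run = True
            else:
                runs[-1][1] = int(i)
                in_run = False
        # merge runs separated by < gap_merge
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < gap_merge:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < min_len:
                continue
            segments = []
            for c, cs, ce in offsets:
                lo, hi = max(s, cs), min(e, ce)
                if lo < hi:
                    segments.append((c, lo - cs, hi - cs))
            n += 1
            md = float(depth[s:e].mean())
            lcrs.append(
                LCR(
                    id=f"LCR{n}",
                    scaffold=sid,
                    segments=segments,
                    length=e - s,
                    mean_depth=md,
                    relative_coverage_percent=100.0 * md / genome,
                )
            )
    return lcrs


def lcrs_to_bed(lcrs: Sequence[LCR], path: str | Path) -> None:
    """BED6: one line per contig segment, name = LCR id."""
    with open(path, "w") as fh:
        for lcr in lcrs:
            for contig, start, end in lcr.segments:
                fh.write(
                    f"{contig}\t{start}\t{end}\t{lcr.id}\t"
                    f"{lcr.relative_coverage_percent:.1f}\t.\n"
                )


# ---------------------------------------------------------------------------
# aggregation and differential analysis


def aggregate_groups(
    coverage: pd.DataFrame,
    metadata: pd.DataFrame,
    group_key: str = "season",
) -> pd.DataFrame:
    """Summarize per-sample relative coverages by season or system.

    ``coverage`` has columns (region_id, sample_id, relative_coverage);
    ``metadata`` maps sample_id to season/system. Returns per (region,
    group) the arithmetic mean and the minimum ("at least X% of the
    population carries the region"), plus a summer/winter fold change
    column when grouping by season and both seasons are present.
    """
    meta = metadata.set_index("sample_id")
    unknown = set(coverage["sample_id"]) - set(meta.index)
    if unknown:
        raise KeyError(f"samples missing from metadata: {sorted(unknown)}")
    df = coverage.merge(
        meta[[group_key]], left_on="sample_id", right_index=True, how="left"
    )
    out = (
        df.groupby(["region_id", group_key])["relative_coverage"]
        .agg(mean="mean", minimum="min", n_samples="size")
        .reset_index()
    )
    if group_key == "season":
        wide = out.pivot(index="region_id", columns="season", values="mean")
        if "summer" in wide.columns and "winter" in wide.columns:
            fold = (wide["summer"] / wide["winter"]).rename("summer_winter_fold_change")
            out = out.merge(fold, left_on="region_id", right_index=True, how="left")
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment (monotone, capped at 1)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")


def differential_regions(
    depth_table: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[DiffResult]:
    """Permutation test for differential region depth between two groups.

    ``depth_table`` is regions x samples of depths normalized by each
    sample's genome-wide mean depth. The statistic is the log2 ratio of
    group means. When the number of distinct label permutations is within
    ``n_perm`` the null is enumerated exhaustively (exact p, identity
    permutation included); otherwise ``n_perm`` random permutations are
    drawn with the add-one correction. P-values are BH-adjusted across
    regions.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    samples = list(group_a) + list(group_b)
    data = depth_table[samples].to_numpy(dtype=float)
    n_a = len(group_a)

    def stat(mat: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(mat[:, idx_a].mean(axis=1) / mat[:, idx_b].mean(axis=1))

    all_idx = np.arange(len(samples))
    obs = stat(data, all_idx[:n_a], all_idx[n_a:])

    n_comb = math.comb(len(samples), n_a)
    exceed = np.zeros(data.shape[0], dtype=np.int64)
    if n_comb <= n_perm:
        total = 0
        for combo in itertools.combinations(range(len(samples)), n_a):
            idx_a = np.array(combo)
            idx_b = np.setdiff1d(all_idx, idx_a)
            perm = np.abs(stat(data, idx_a, idx_b))
            exceed += (perm >= np.abs(obs) - 1e-12).astype(np.int64)
            total += 1
        pvals = exceed / total
    else:
        rng = child_rng(seed, "differential_regions")
        for _ in range(n_perm):
            perm_idx = rng.permutation(len(samples))
            perm = np.abs(stat(data, perm_idx[:n_a], perm_idx[n_a:]))
            exceed += (perm >= np.abs(obs) - 1e-12).astype(np.int64)
        pvals = (exceed + 1) / (n_perm + 1)
    padj = benjamini_hochberg(pvals)
    return [
        DiffResult(
            region_id=str(rid),
            log2_fold_change=float(obs[i]),
            p_value=float(pvals[i]),
            p_adjusted=float(padj[i]),
        )
        for i, rid in enumerate(depth_table.index)
    ]


# ---------------------------------------------------------------------------
# diversity and consistency


def simpson_diversity(counts: Sequence[int] | Mapping[str, int]) -> float:
    """Simpson's index of diversity 1 - lambda', with
    lambda' = sum n_i (n_i - 1) / (N (N - 1))."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if any(v < 0 for v in values):
        raise ValueError("counts must be non-negative")
    n_total = sum(values)
    if n_total < 2:
        raise ValueError("need at least two individuals")
    lam = sum(v * (v - 1) for v in values) / (n_total * (n_total - 1))
    return 1.0 - lam


def snp_consistency_report(
    calls_by_sample: Mapping[str, Sequence[SNPCall]],
    lcrs: Sequence[LCR],
    metadata: pd.DataFrame | None = None,
    low_depth: int = 5,
) -> pd.DataFrame:
    """Cross-sample SNP table: LCR membership and which samples report each.

    One row per (contig, pos, alt): whether the site lies inside an LCR,
    the set of samples (and systems, when metadata is given) reporting it,
    and the mean supporting read count across those samples — SNPs whose
    mean support is below ``low_depth`` are flagged as possible sequencing
    errors.
    """
    system_of: dict[str, str] = {}
    if metadata is not None:
        system_of = dict(zip(metadata["sample_id"], metadata["system"]))
    rows: dict[tuple[str, int, str], dict] = {}
    for sample, calls in calls_by_sample.items():
        for c in calls:
            key = (c.contig, c.pos, c.alt_base)
            row = rows.setdefault(
                key,
                {
                    "contig": c.contig,
                    "pos": c.pos,
                    "alt_base": c.alt_base,
                    "in_lcr": any(l.contains(c.contig, c.pos) for l in lcrs),
                    "samples": set(),
                    "systems": set(),
                    "alt_counts": [],
                },
            )
            row["samples"].add(sample)
            if sample in system_of:
                row["systems"].add(system_of[sample])
            row["alt_counts"].append(c.alt_count)
    records = []
    for row in rows.values():
        mean_support = float(np.mean(row["alt_counts"]))
        records.append(
            {
                "contig": row["contig"],
                "pos": row["pos"],
                "alt_base": row["alt_base"],
                "in_lcr": row["in_lcr"],
                "samples": ",".join(sorted(row["samples"])),
                "systems": ",".join(sorted(row["systems"])),
                "n_samples": len(row["samples"]),
                "mean_alt_count": mean_support,
                "low_depth_mean": mean_support < low_depth,
            }
        )
    return pd.DataFrame(records).sort_values(["contig", "pos", "alt_base"]).reset_index(drop=True)
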