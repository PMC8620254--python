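"""Synthetic metacommunities with planted ground truth.

The generator emulates the population structure the analysis chain is built
to resolve: one near-clonal dominant species whose subpopulations
(phylotypes) differ by accessory loci — genomic segments present in only a
fraction of cells — and by SNP alleles at planted frequencies. Per-sample
abundance spans a seasonal range of two orders of magnitude, reads carry
substitution errors, and CRISPR repeat-spacer arrays with matching viral
contigs can be planted for the virus-host machinery.

Everything is deterministic under one root seed: each operation draws from
a child stream keyed by a stable string (see :mod:`phylopop._rng`), so any
module can be re-run in isolation and reproduce its inputs byte for byte.

Coordinates are 0-based half-open throughout. Ground truth
(:class:`SimulationTruth`) records, per sample, the exact expectation of
every statistic the downstream modules estimate, and is the oracle the
test suite scores against.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from phylopop._rng import child_rng
from phylopop.assembly import ReferenceAssembly, revcomp
from phylopop.recruit import DepthProfile

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_OF = {65: "A", 67: "C", 71: "G", 84: "T"}


class ConfigurationError(ValueError):
    """A simulation parameter is out of bounds; the message names the field."""


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class PhylotypeSpec:
    """A subpopulation: loci it lacks and SNP alleles it carries.

    ``deleted_loci`` are (contig, start, end) segments absent from this
    phylotype's genome; ``snp_sites`` are (contig, pos, alt_base, carrier)
    tuples — carrier=False documents sites segregating in *other*
    phylotypes so that per-sample expected frequencies can be tabulated.
    """

    id: str
    deleted_loci: list[tuple[str, int, int]] = field(default_factory=list)
    snp_sites: list[tuple[str, int, str, bool]] = field(default_factory=list)


@dataclass
class SampleDesign:
    """One metagenome sample: where, when, and how deep."""

    sample_id: str
    system: str  # AL, EF, TB, other
    season: str  # summer, winter, spring
    filter_fraction: str
    mean_depth: float
    phylotype_fractions: dict[str, float]


@dataclass
class ArraySpec:
    """A CRISPR repeat-spacer array to plant (uniform period)."""

    n_repeats: int = 4
    repeat_len: int = 30
    spacer_len: int = 32
    at_contig_end: bool = False
    contig: str | None = None  # default: chosen round-robin


@dataclass
class PlantSpec:
    """One spacer copy to embed in a viral contig, optionally mutated."""

    array_index: int
    spacer_index: int
    viral_index: int
    n_mismatches: int = 0


@dataclass
class CrisprSpec:
    arrays: list[ArraySpec] = field(default_factory=list)
    plants: list[PlantSpec] = field(default_factory=list)
    n_viral_contigs: int = 6
    viral_contig_len: int = 8000
    viral_systems: list[str] = field(default_factory=lambda: ["AL", "EF", "TB"])
    host_system: str = "EF"


@dataclass
class SimulationConfig:
    """Declarative description of one synthetic metacommunity."""

    seed: int
    genome_length: int = 60_000
    n_contigs: int = 8
    n_scaffolds: int = 4
    gc_target: float = 0.5
    read_length: int = 150
    error_rate: float = 0.005
    samples: list[SampleDesign] = field(default_factory=list)
    phylotypes: list[PhylotypeSpec] = field(default_factory=list)
    crispr: CrisprSpec | None = None

    def __post_init__(self) -> None:
        if self.genome_length < self.n_contigs * 1000:
            raise ConfigurationError(
                f"genome_length: {self.genome_length} < n_contigs x 1000 = {self.n_contigs * 1000}"
            )
        if not 0 < self.n_scaffolds <= self.n_contigs:
            raise ConfigurationError(
                f"n_scaffolds: must be in [1, n_contigs]: got {self.n_scaffolds}"
            )
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigurationError(f"error_rate: must be in [0, 0.05]: got {self.error_rate}")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigurationError(f"gc_target: must be in [0, 1]: got {self.gc_target}")
        if self.read_length < 20:
            raise ConfigurationError(f"read_length: must be >= 20: got {self.read_length}")
        ids = [p.id for p in self.phylotypes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("phylotypes: duplicate phylotype ids")
        for s in self.samples:
            _validate_design(s, ids)


def _validate_design(design: SampleDesign, phylotype_ids: Sequence[str]) -> None:
    if design.mean_depth <= 0:
        raise ConfigurationError(
            f"samples[{design.sample_id}].mean_depth: must be > 0: got {design.mean_depth}"
        )
    fracs = design.phylotype_fractions
    # presets fill phylotypes after drawing the reference; defer id checks
    if phylotype_ids and set(fracs) - set(phylotype_ids):
        raise ConfigurationError(
            f"samples[{design.sample_id}].phylotype_fractions: unknown phylotype ids "
            f"{sorted(set(fracs) - set(phylotype_ids))}"
        )
    if any(f < 0 for f in fracs.values()):
        raise ConfigurationError(
            f"samples[{design.sample_id}].phylotype_fractions: negative fraction"
        )
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"samples[{design.sample_id}].phylotype_fractions: sum "
            f"{sum(fracs.values()):.6f} != 1"
        )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SimulationTruth:
    """Planted quantities, sufficient to score every downstream module.

    ``loci`` carry, per sample, both the carrier percentage (100 x summed
    fractions of phylotypes retaining the locus) and the exact expected
    relative coverage, which additionally accounts for the deflation of the
    genome-wide mean depth by all planted deletions.
    """

    samples: dict[str, dict] = field(default_factory=dict)
    loci: list[dict] = field(default_factory=list)
    snps: list[dict] = field(default_factory=list)
    arrays: list[dict] = field(default_factory=list)
    spacer_edges: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(**d)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SimulationTruth) and self.to_dict() == other.to_dict()


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Serialize ground truth as JSON; round-trips losslessly."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# reference construction


def _partition(total: int, parts: int, minimum: int, rng: np.random.Generator) -> list[int]:
    """Composition of ``total`` into ``parts`` pieces, each >= minimum,
    jittered around equal size (+-25%) so no piece is degenerate."""
    w = rng.uniform(0.75, 1.25, size=parts)
    lengths = np.maximum(minimum, np.floor(w / w.sum() * total).astype(np.int64))
    diff = int(total - lengths.sum())
    order = np.argsort(-lengths)
    i = 0
    while diff != 0:
        j = order[i % parts]
        step = 1 if diff > 0 else -1
        if lengths[j] + step >= minimum:
            lengths[j] += step
            diff -= step
        i += 1
    return [int(x) for x in lengths]


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def make_reference(config: SimulationConfig) -> ReferenceAssembly:
    """Build a random reference assembly per the config.

    Contigs are i.i.d. bases with P(G or C) = gc_target, partitioned into
    ``n_scaffolds`` contiguous groups in contig-rank order. Deterministic
    under (config, seed); realized GC concentrates within a fraction of a
    percentage point of the target for genomes of 100 kb and more.
    """
    rng = child_rng(config.seed, "reference")
    lengths = _partition(config.genome_length, config.n_contigs, 1000, rng)
    width = len(str(config.n_contigs))
    contigs = {
        f"C{i + 1:0{width}d}": random_sequence(n, config.gc_target, rng)
        for i, n in enumerate(lengths)
    }
    group_sizes = _partition(config.n_contigs, config.n_scaffolds, 1, rng)
    scaffolds: dict[str, list[str]] = {}
    ids = list(contigs)
    pos = 0
    for si, g in enumerate(group_sizes):
        scaffolds[f"S{si + 1:02d}"] = ids[pos : pos + g]
        pos += g
    return ReferenceAssembly(contigs=contigs, scaffolds=scaffolds)


# ---------------------------------------------------------------------------
# phylotype genomes and reads


def _validate_phylotype(phy: PhylotypeSpec, ref: ReferenceAssembly) -> None:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in phy.deleted_loci:
        if contig not in ref.contigs:
            raise ConfigurationError(f"phylotypes[{phy.id}].deleted_loci: unknown contig {contig}")
        if not 0 <= start < end <= len(ref.contigs[contig]):
            raise ConfigurationError(
                f"phylotypes[{phy.id}].deleted_loci: ({contig}, {start}, {end}) out of bounds"
            )
        by_contig.setdefault(contig, []).append((start, end))
    for contig, spans in by_contig.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ConfigurationError(
                    f"phylotypes[{phy.id}].deleted_loci: overlapping loci on {contig}"
                )
    for contig, pos, alt, carrier in phy.snp_sites:
        if contig not in ref.contigs or not 0 <= pos < len(ref.contigs[contig]):
            raise ConfigurationError(
                f"phylotypes[{phy.id}].snp_sites: ({contig}, {pos}) out of bounds"
            )
        if carrier and ref.contigs[contig][pos] == alt:
            raise ConfigurationError(
                f"phylotypes[{phy.id}].snp_sites: alt equals reference base at {contig}:{pos}"
            )
        for s, e in by_contig.get(contig, []):
            if s <= pos < e:
                raise ConfigurationError(
                    f"phylotypes[{phy.id}].snp_sites: position {contig}:{pos} "
                    "inside a deleted locus of the same phylotype"
                )


def phylotype_genome(ref: ReferenceAssembly, phy: PhylotypeSpec) -> dict[str, str]:
    """The phylotype's genome: reference with its SNP alleles substituted
    and its deleted loci excised (contigs keep their reference ids)."""
    _validate_phylotype(phy, ref)
    out: dict[str, str] = {}
    snps_by_contig: dict[str, list[tuple[int, str]]] = {}
    for contig, pos, alt, carrier in phy.snp_sites:
        if carrier:
            snps_by_contig.setdefault(contig, []).append((pos, alt))
    dels_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in phy.deleted_loci:
        dels_by_contig.setdefault(contig, []).append((start, end))
    for cid, seq in ref.contigs.items():
        chars = list(seq)
        for pos, alt in snps_by_contig.get(cid, []):
            chars[pos] = alt
        kept: list[str] = []
        cursor = 0
        for start, end in sorted(dels_by_contig.get(cid, [])):
            kept.extend(chars[cursor:start])
            cursor = end
        kept.extend(chars[cursor:])
        out[cid] = "".join(kept)
    return out


def _reads_per_phylotype(
    fraction: float, mean_depth: float, accessible_length: int, read_length: int
) -> int:
    return int(np.rint(fraction * mean_depth * accessible_length / read_length))


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` among ``weights``.

    Stratified allocation: expected counts are honoured exactly (no
    multinomial allocation noise inflating per-contig depth variance) and
    the pieces sum to ``total``.
    """
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:remainder]] += 1
    return base


def simulate_reads(
    ref: ReferenceAssembly,
    phylotypes: Sequence[PhylotypeSpec],
    design: SampleDesign,
    *,
    seed: int,
    read_length: int = 150,
    error_rate: float = 0.005,
    revcomp_fraction: float = 0.0,
) -> list[tuple[str, str]]:
    """Draw single-end reads for one sample as (read_id, sequence) pairs.

    Each phylotype contributes exactly
    ``round(fraction x mean_depth x accessible_length / read_length)``
    reads, drawn uniformly over start positions of its own genome
    (reference minus its deleted loci, with its SNP alleles substituted),
    with i.i.d. substitution errors at ``error_rate``. Forward strand by
    default; set ``revcomp_fraction`` to emit a fraction reverse-complemented.
    """
    rng = child_rng(seed, f"reads/{design.sample_id}")
    reads: list[tuple[str, str]] = []
    for phy in phylotypes:
        fraction = design.phylotype_fractions.get(phy.id, 0.0)
        if fraction == 0.0:
            continue
        genome = phylotype_genome(ref, phy)
        shortest = min(len(s) for s in genome.values())
        if read_length > shortest:
            raise ConfigurationError(
                f"read_length {read_length} exceeds shortest contig of phylotype "
                f"{phy.id} ({shortest} bp)"
            )
        accessible = sum(len(s) for s in genome.values())
        n_reads = _reads_per_phylotype(fraction, design.mean_depth, accessible, read_length)
        if n_reads == 0:
            continue
        cids = list(genome)
        weights = np.array([len(genome[c]) for c in cids], dtype=float)
        per_contig = _apportion(n_reads, weights)
        for cid, n in zip(cids, per_contig):
            if n == 0:
                continue
            arr = np.frombuffer(genome[cid].encode(), dtype=np.uint8)
            starts = rng.integers(0, arr.size - read_length + 1, size=n)
            mat = arr[starts[:, None] + np.arange(read_length)]
            if error_rate > 0:
                mask = rng.random(mat.shape) < error_rate
                n_err = int(mask.sum())
                if n_err:
                    base_idx = np.searchsorted(_BASES, mat[mask])
                    shift = rng.integers(1, 4, size=n_err)
                    mat[mask] = _BASES[(base_idx + shift) % 4]
            flip = (
                rng.random(n) < revcomp_fraction
                if revcomp_fraction > 0
                else np.zeros(n, dtype=bool)
            )
            for i in range(int(n)):
                seq = mat[i].tobytes().decode()
                if flip[i]:
                    seq = revcomp(seq)
                reads.append((f"{design.sample_id}:{phy.id}:{cid}:{int(starts[i])}:{i}", seq))
    return reads


def simulate_depth_profile(
    ref: ReferenceAssembly,
    phylotypes: Sequence[PhylotypeSpec],
    design: SampleDesign,
    *,
    seed: int,
    read_length: int = 150,
) -> DepthProfile:
    """Coverage-level shortcut: the depth profile recruitment would yield.

    Draws the same per-phylotype read counts and uniform start positions as
    :func:`simulate_reads` but bins them into a depth profile directly,
    without materializing sequences or aligning. Reads spanning a deletion
    junction are discarded, as they would fail recruitment. Useful when an
    analysis consumes only depth (relative coverage, LCRs, differential
    tests) and read-level fidelity adds nothing but runtime.
    """
    rng = child_rng(seed, f"reads/{design.sample_id}")
    profile = DepthProfile(ref)
    diffs = {cid: np.zeros(len(seq) + 1, dtype=np.int64) for cid, seq in ref.contigs.items()}
    n_aligned = 0
    for phy in phylotypes:
        fraction = design.phylotype_fractions.get(phy.id, 0.0)
        if fraction == 0.0:
            continue
        _validate_phylotype(phy, ref)
        dels: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in phy.deleted_loci:
            dels.setdefault(contig, []).append((start, end))
        kept_len = {
            cid: len(seq) - sum(e - s for s, e in dels.get(cid, []))
            for cid, seq in ref.contigs.items()
        }
        accessible = sum(kept_len.values())
        n_reads = _reads_per_phylotype(fraction, design.mean_depth, accessible, read_length)
        if n_reads == 0:
            continue
        cids = list(ref.contigs)
        weights = np.array([kept_len[c] for c in cids], dtype=float)
        per_contig = _apportion(n_reads, weights)
        for cid, n in zip(cids, per_contig):
            if n == 0:
                continue
            # draw starts in phylotype-genome coordinates, lift to reference
            starts = np.sort(rng.integers(0, kept_len[cid] - read_length + 1, size=n))
            spans = sorted(dels.get(cid, []))
            ref_starts = starts.astype(np.int64)
            shift = 0
            for s, e in spans:
                # positions at/after the junction (phylotype coord s - shift)
                ref_starts[starts >= s - shift] += e - s
                shift += e - s
            # discard reads spanning a junction: their reference footprint
            # would cross a deleted locus and recruitment would reject them
            ok = np.ones(n, dtype=bool)
            for s, e in spans:
                ok &= ~((ref_starts < s) & (ref_starts + read_length > s))
            ref_starts = ref_starts[ok]
            np.add.at(diffs[cid], ref_starts, 1)
            np.add.at(diffs[cid], ref_starts + read_length, -1)
            n_aligned += int(ok.sum())
    for cid in ref.contig_ids:
        profile.depth[cid] = np.cumsum(diffs[cid][:-1])
    profile.aligned_read_count = n_aligned
    return profile


# ---------------------------------------------------------------------------
# CRISPR / viral fixtures


def plant_crispr_fixture(
    ref: ReferenceAssembly,
    crispr: CrisprSpec,
    seed: int,
    spacer_system: str = "EF",
) -> tuple[ReferenceAssembly, dict[str, str], list[dict], SimulationTruth]:
    """Insert repeat-spacer arrays into the reference and build a viral catalogue.

    Returns the modified assembly, the catalogue sequences, the catalogue
    label rows (contig_id, cluster_label, source_system) and a truth object
    whose ``arrays`` describe every planted array and whose
    ``spacer_edges`` list each planted spacer -> viral contig link with its
    exact identity (100 x (spacer_len - n_mismatches) / spacer_len).
    """
    rng = child_rng(seed, "crispr")
    truth = SimulationTruth()
    contigs = dict(ref.contigs)
    contig_ids = list(contigs)
    spacer_seqs: dict[tuple[int, int], str] = {}
    for ai, spec in enumerate(crispr.arrays):
        if not 23 <= spec.repeat_len <= 47:
            raise ConfigurationError(f"crispr.arrays[{ai}].repeat_len: must be in [23, 47]")
        if not 20 <= spec.spacer_len <= 50:
            raise ConfigurationError(f"crispr.arrays[{ai}].spacer_len: must be in [20, 50]")
        if spec.n_repeats < 3:
            raise ConfigurationError(f"crispr.arrays[{ai}].n_repeats: must be >= 3")
        repeat = random_sequence(spec.repeat_len, 0.5, rng)
        spacers = [
            random_sequence(spec.spacer_len, 0.5, rng) for _ in range(spec.n_repeats - 1)
        ]
        for si, s in enumerate(spacers):
            spacer_seqs[(ai, si)] = s
        array_seq = repeat + "".join(s + repeat for s in spacers)
        cid = spec.contig or contig_ids[ai % len(contig_ids)]
        host = contigs[cid]
        if spec.at_contig_end:
            insert_at = len(host)
        else:
            insert_at = int(rng.integers(200, max(201, len(host) - 200)))
        contigs[cid] = host[:insert_at] + array_seq + host[insert_at:]
        truth.arrays.append(
            {
                "array_id": f"array{ai}",
                "contig": cid,
                "start": insert_at,
                "end": insert_at + len(array_seq),
                "n_repeats": spec.n_repeats,
                "repeat": repeat,
                "repeat_len": spec.repeat_len,
                "spacer_len": spec.spacer_len,
                "spacers": spacers,
                "at_contig_end": spec.at_contig_end,
            }
        )

    catalogue: dict[str, str] = {}
    labels: list[dict] = []
    for vi in range(crispr.n_viral_contigs):
        vid = f"vc_{vi + 1:03d}"
        catalogue[vid] = random_sequence(crispr.viral_contig_len, 0.45, rng)
        labels.append(
            {
                "contig_id": vid,
                "cluster_label": f"cl_{(vi % 3) + 1:04d}",
                "source_system": crispr.viral_systems[vi % len(crispr.viral_systems)],
            }
        )
    for plant in crispr.plants:
        key = (plant.array_index, plant.spacer_index)
        if key not in spacer_seqs:
            raise ConfigurationError(
                f"crispr.plants: no spacer at array {plant.array_index}, "
                f"index {plant.spacer_index}"
            )
        spacer = spacer_seqs[key]
        planted = spacer
        if plant.n_mismatches:
            pos = rng.choice(len(spacer), size=plant.n_mismatches, replace=False)
            chars = list(spacer)
            for p in pos:
                old = chars[p]
                choices = [b for b in "ACGT" if b != old]
                chars[int(p)] = choices[int(rng.integers(0, 3))]
            planted = "".join(chars)
        vid = f"vc_{plant.viral_index + 1:03d}"
        vseq = catalogue[vid]
        at = int(rng.integers(100, len(vseq) - len(planted) - 100))
        catalogue[vid] = vseq[:at] + planted + vseq[at + len(planted) :]
        identity = 100.0 * (len(spacer) - plant.n_mismatches) / len(spacer)
        truth.spacer_edges.append(
            {
                "spacer_id": f"array{plant.array_index}_sp{plant.spacer_index}",
                "spacer_seq": spacer,
                "spacer_system": spacer_system,
                "viral_contig": vid,
                "viral_system": labels[plant.viral_index]["source_system"],
                "n_mismatches": plant.n_mismatches,
                "spacer_len": len(spacer),
                "identity_percent": identity,
            }
        )
    modified = ReferenceAssembly(
        contigs=contigs, scaffolds={k: list(v) for k, v in ref.scaffolds.items()}
    )
    return modified, catalogue, labels, truth


# ---------------------------------------------------------------------------
# truth tabulation


def tabulate_truth(
    config: SimulationConfig,
    ref: ReferenceAssembly,
    locus_registry: list[tuple[str, str, int, int]] | None = None,
) -> SimulationTruth:
    """Compute expected values of every downstream statistic from the config.

    ``locus_registry`` optionally names loci as (locus_id, contig, start,
    end); by default the union of all phylotype deleted loci is used.

    For each locus and sample the truth records two quantities: the
    carrier percentage (100 x summed fractions of phylotypes retaining the
    locus — the textbook reading of relative coverage) and the exact
    expected relative coverage of the estimator under the generative
    model. The two differ by small systematic factors: the genome-wide
    mean depth is deflated by every planted deletion, reads cannot start
    within a read length of a contig end (so contig interiors run slightly
    above the contig mean), and junction-spanning reads of deletion
    phylotypes are never recruited. All three are accounted for in closed
    form.
    """
    genome_len = len(ref)
    read_length = config.read_length
    if locus_registry is None:
        seen: dict[tuple[str, int, int], str] = {}
        for phy in config.phylotypes:
            for contig, start, end in phy.deleted_loci:
                seen.setdefault((contig, start, end), f"locus_{contig}_{start}_{end}")
        locus_registry = [(lid, c, s, e) for (c, s, e), lid in seen.items()]

    truth = SimulationTruth()
    for design in config.samples:
        truth.samples[design.sample_id] = {
            "system": design.system,
            "season": design.season,
            "filter_fraction": design.filter_fraction,
            "mean_depth": design.mean_depth,
        }

    # per phylotype: contig -> (kept length, sorted deletions)
    phy_geometry: dict[str, dict[str, tuple[int, list[tuple[int, int]]]]] = {}
    for phy in config.phylotypes:
        dels: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e in phy.deleted_loci:
            dels.setdefault(contig, []).append((s, e))
        phy_geometry[phy.id] = {
            cid: (
                len(seq) - sum(e - s for s, e in sorted(dels.get(cid, []))),
                sorted(dels.get(cid, [])),
            )
            for cid, seq in ref.contigs.items()
        }

    def expected_recruited_reads(design: SampleDesign) -> float:
        """Reads recruited after junction-spanning reads are lost."""
        total = 0.0
        for phy in config.phylotypes:
            f = design.phylotype_fractions.get(phy.id, 0.0)
            if f == 0.0:
                continue
            geo = phy_geometry[phy.id]
            accessible = sum(kept for kept, _ in geo.values())
            n_reads = _reads_per_phylotype(f, design.mean_depth, accessible, read_length)
            for kept, spans in geo.values():
                n_c = n_reads * kept / accessible
                starts = kept - read_length + 1
                # each interior junction voids read_length - 1 start positions
                lost = len(spans) * (read_length - 1) / starts if starts > 0 else 0.0
                total += n_c * max(0.0, 1.0 - lost)
        return total

    def expected_locus_sum(design: SampleDesign, contig: str, start: int, end: int) -> float:
        """Expected summed base depth over [start, end) on ``contig``."""
        total = 0.0
        for phy in config.phylotypes:
            f = design.phylotype_fractions.get(phy.id, 0.0)
            if f == 0.0:
                continue
            geo = phy_geometry[phy.id]
            kept, spans = geo[contig]
            # locus positions retained by this phylotype, in its coordinates
            pieces: list[tuple[int, int]] = [(start, end)]
            for s, e in spans:
                split: list[tuple[int, int]] = []
                for a, b in pieces:
                    if a < s:
                        split.append((a, min(b, s)))
                    if e < b:
                        split.append((max(a, e), b))
                pieces = split
            if not pieces:
                continue
            accessible = sum(k for k, _ in geo.values())
            n_reads = _reads_per_phylotype(f, design.mean_depth, accessible, read_length)
            n_c = n_reads * kept / accessible
            n_starts = kept - read_length + 1
            if n_starts <= 0:
                continue
            for a, b in pieces:
                shift = sum(e - s for s, e in spans if e <= a)
                pa, pb = a - shift, b - shift  # phylotype coordinates
                x = np.arange(pa, pb)
                cover = (
                    np.minimum(x, kept - read_length)
                    - np.maximum(0, x - read_length + 1)
                    + 1
                )
                total += n_c * float(np.clip(cover, 0, None).sum()) / n_starts
        return total

    for lid, contig, start, end in locus_registry:
        entry = {
            "locus_id": lid,
            "contig": contig,
            "start": start,
            "end": end,
            "carrier_percent": {},
            "expected_relative_coverage": {},
        }
        for design in config.samples:
            carrier = 0.0
            for phy in config.phylotypes:
                f = design.phylotype_fractions.get(phy.id, 0.0)
                lacks = any(
                    c == contig and s < end and start < e for c, s, e in phy.deleted_loci
                )
                if not lacks:
                    carrier += f
            entry["carrier_percent"][design.sample_id] = 100.0 * carrier
            genome_mean = expected_recruited_reads(design) * read_length / genome_len
            locus_mean = expected_locus_sum(design, contig, start, end) / (end - start)
            entry["expected_relative_coverage"][design.sample_id] = (
                100.0 * locus_mean / genome_mean if genome_mean > 0 else 0.0
            )
        truth.loci.append(entry)

    snp_keys: dict[tuple[str, int, str], dict] = {}
    for phy in config.phylotypes:
        for contig, pos, alt, carrier in phy.snp_sites:
            key = (contig, pos, alt)
            if key not in snp_keys:
                snp_keys[key] = {
                    "contig": contig,
                    "pos": pos,
                    "ref": ref.contigs[contig][pos],
                    "alt": alt,
                    "expected_frequency": {},
                    "expected_observed_frequency": {},
                }
    carries = {
        phy.id: {(c, p, a) for c, p, a, carr in phy.snp_sites if carr}
        for phy in config.phylotypes
    }
    for (contig, pos, alt), entry in snp_keys.items():
        for design in config.samples:
            carrier = covering = 0.0
            for phy in config.phylotypes:
                f = design.phylotype_fractions.get(phy.id, 0.0)
                if any(c == contig and s <= pos < e for c, s, e in phy.deleted_loci):
                    continue
                covering += f
                if (contig, pos, alt) in carries[phy.id]:
                    carrier += f
            f_true = carrier / covering if covering > 0 else 0.0
            entry["expected_frequency"][design.sample_id] = f_true
            # substitution errors flip alt->other at rate e and any of the
            # three non-alt bases to alt at rate e/3
            e = config.error_rate
            entry["expected_observed_frequency"][design.sample_id] = f_true * (1 - e) + (
                1 - f_true
            ) * (e / 3)
        truth.snps.append(entry)
    return truth


# ---------------------------------------------------------------------------
# packaged presets


def recovery_config(seed: int) -> SimulationConfig:
    """One deep sample over a structured population: the parameter-recovery
    scenario.

    Five phylotypes at fractions 0.01/0.04/0.25/0.20/0.50 realize accessory
    loci carried by 30%, 50% and 70% of cells and SNP sites segregating at
    expected frequencies 0.01, 0.25 and 0.95, profiled at 300x mean depth —
    deep enough that relative coverage resolves carrier fractions to a
    couple of percentage points and allele counts sit in narrow binomial
    intervals.
    """
    genome = 60_000
    cfg = SimulationConfig(
        seed=seed,
        genome_length=genome,
        n_contigs=8,
        n_scaffolds=4,
        samples=[
            SampleDesign(
                sample_id="DEEP_1",
                system="AL",
                season="summer",
                filter_fraction="0.1um",
                mean_depth=300.0,
                phylotype_fractions={"P1": 0.01, "P2": 0.04, "P3": 0.25, "P4": 0.20, "P5": 0.50},
            )
        ],
        phylotypes=[],
    )
    ref = make_reference(cfg)
    sizes = {cid: len(s) for cid, s in ref.contigs.items()}
    by_size = sorted(ref.contig_ids, key=lambda c: -sizes[c])

    def centered(contig: str, length: int) -> tuple[str, int, int]:
        start = (sizes[contig] - length) // 2
        return (contig, start, start + length)

    # accessory loci: 3 kb segments interior to the three largest contigs
    l30 = centered(by_size[0], 3000)  # carriers P1+P2+P3 = 0.30
    l50 = centered(by_size[1], 3000)  # carrier  P5       = 0.50
    l70 = centered(by_size[2], 3000)  # carriers P4+P5    = 0.70
    # SNP sites on a locus-free contig
    snp_contig = by_size[3]
    snp_sites = {0.01: 500, 0.25: 900, 0.95: 1300}

    def alt(contig: str, pos: int) -> str:
        base = ref.contigs[contig][pos]
        return {"A": "C", "C": "G", "G": "T", "T": "A"}[base]

    def snps(*freqs: float) -> list[tuple[str, int, str, bool]]:
        return [
            (snp_contig, snp_sites[f], alt(snp_contig, snp_sites[f]), True) for f in freqs
        ]

    cfg.phylotypes = [
        PhylotypeSpec("P1", deleted_loci=[l50, l70], snp_sites=snps(0.01)),
        PhylotypeSpec("P2", deleted_loci=[l50, l70], snp_sites=[]),
        PhylotypeSpec("P3", deleted_loci=[l50, l70], snp_sites=snps(0.25, 0.95)),
        PhylotypeSpec("P4", deleted_loci=[l30, l50], snp_sites=snps(0.95)),
        PhylotypeSpec("P5", deleted_loci=[l30], snp_sites=snps(0.95)),
    ]
    return cfg


def lcr_config(seed: int) -> SimulationConfig:
    """Planted low-coverage regions, one straddling two contigs of a scaffold.

    Two phylotypes (0.3 / 0.7): the major one lacks two 5-kb segments, so
    both drop to 30% of the genome-wide depth. The second segment spans the
    junction of two adjacent contigs on one scaffold and must be reported
    as a single merged LCR.
    """
    cfg = SimulationConfig(
        seed=seed,
        genome_length=48_000,
        n_contigs=8,
        n_scaffolds=4,
        samples=[
            SampleDesign(
                sample_id="LCR_1",
                system="AL",
                season="summer",
                filter_fraction="0.1um",
                mean_depth=100.0,
                phylotype_fractions={"core": 0.3, "major": 0.7},
            )
        ],
        phylotypes=[],
    )
    ref = make_reference(cfg)
    # within-contig locus: 5 kb interior to the largest contig
    sizes = {cid: len(s) for cid, s in ref.contigs.items()}
    big = max(ref.contig_ids, key=lambda c: sizes[c])
    start_a = (sizes[big] - 5000) // 2
    locus_a = (big, start_a, start_a + 5000)
    # straddling locus: across the junction of two adjacent contigs of one
    # scaffold, preferring a scaffold that does not hold the first locus
    pair: tuple[str, str] | None = None
    for members in ref.scaffolds.values():
        for c1, c2 in zip(members, members[1:]):
            if big not in (c1, c2):
                pair = (c1, c2)
                break
        if pair:
            break
    if pair is None:  # fall back to any adjacent pair
        members = next(m for m in ref.scaffolds.values() if len(m) >= 2)
        pair = (members[0], members[1])
    c1, c2 = pair
    take1 = min(2500, sizes[c1] - 300)
    take2 = min(5000 - take1, sizes[c2] - 300)
    locus_b1 = (c1, sizes[c1] - take1, sizes[c1])
    locus_b2 = (c2, 0, take2)
    cfg.phylotypes = [
        PhylotypeSpec("core"),
        PhylotypeSpec("major", deleted_loci=[locus_a, locus_b1, locus_b2]),
    ]
    return cfg


def seasonal_preset(seed: int) -> tuple[SimulationConfig, dict]:
    """The packaged seasonal design: summer abundance 100x winter, with a
    phylotype whose accessory region is twice as common in summer.

    Four summer samples at 1500x and four winter samples at 15x mean depth
    (the two-orders-of-magnitude seasonal abundance swing); the accessory
    phylotype carries a 5-kb region in 80% of summer cells and 40% of
    winter cells (the ~2-fold seasonal shift). Returns the config and a
    region table: the planted region plus 50 null regions tiling the core
    genome.
    """
    genome = 100_000
    cfg = SimulationConfig(
        seed=seed,
        genome_length=genome,
        n_contigs=10,
        n_scaffolds=5,
        samples=[],
        phylotypes=[],
    )
    ref = make_reference(cfg)
    sizes = {cid: len(s) for cid, s in ref.contigs.items()}
    big = max(ref.contig_ids, key=lambda c: sizes[c])
    start = (sizes[big] - 5000) // 2
    locus = (big, start, start + 5000)
    cfg.phylotypes = [
        PhylotypeSpec("carrier"),
        PhylotypeSpec("lacking", deleted_loci=[locus]),
    ]
    for i in range(4):
        cfg.samples.append(
            SampleDesign(
                sample_id=f"SUM_{i + 1}",
                system="AL",
                season="summer",
                filter_fraction="pooled",
                mean_depth=1500.0,
                phylotype_fractions={"carrier": 0.8, "lacking": 0.2},
            )
        )
        cfg.samples.append(
            SampleDesign(
                sample_id=f"WIN_{i + 1}",
                system="AL",
                season="winter",
                filter_fraction="pooled",
                mean_depth=15.0,
                phylotype_fractions={"carrier": 0.4, "lacking": 0.6},
            )
        )
    # 50 null regions: 1.5-kb windows tiling contigs free of the planted locus
    null_regions: dict[str, tuple[str, int, int]] = {}
    i = 0
    for cid in ref.contig_ids:
        if cid == big:
            continue
        pos = 200
        while pos + 1500 <= sizes[cid] - 200 and i < 50:
            null_regions[f"null_{i + 1:02d}"] = (cid, pos, pos + 1500)
            pos += 1500
            i += 1
    regions = {"planted": locus, **null_regions}
    return cfg, regions


def gcdepth_scenario(
    seed: int,
    n_dominant: int = 12,
    n_minor: int = 10,
    contig_len: int = 12_000,
    dominant_depth: float = 2000.0,
    depth_ratio: float = 20.0,
    divergence: float = 0.10,
) -> tuple[dict[str, str], "DepthProfile", ReferenceAssembly, dict[str, str]]:
    """Metagenome contigs for the GC-depth machinery, with truth labels.

    A dominant population contributes its MAG contigs at high depth; a
    divergent relative contributes copies of a subset of those contigs
    mutated at ``divergence`` of positions (AT-biased substitutions, so the
    relative sits a few GC points away, as diverged genomes generally do)
    at ``depth_ratio``-fold lower depth. Returns (contigs, depth profile,
    the dominant MAG as a reference assembly, contig -> population labels).
    """
    rng = child_rng(seed, "gcdepth")
    base_cfg = SimulationConfig(
        seed=seed,
        genome_length=n_dominant * contig_len,
        n_contigs=n_dominant,
        n_scaffolds=max(1, n_dominant // 3),
        gc_target=0.52,
    )
    mag = make_reference(base_cfg)
    contigs: dict[str, str] = dict(mag.contigs)
    labels = {cid: "dominant" for cid in mag.contigs}
    at_biased = np.array([0.45, 0.05, 0.05, 0.45])  # A, C, G, T
    for i, cid in enumerate(list(mag.contigs)[:n_minor]):
        arr = np.frombuffer(mag.contigs[cid].encode(), dtype=np.uint8).copy()
        sites = np.flatnonzero(rng.random(arr.size) < divergence)
        for p in sites:
            probs = at_biased.copy()
            probs[np.searchsorted(_BASES, arr[p])] = 0.0
            arr[p] = rng.choice(_BASES, p=probs / probs.sum())
        mid = f"M{i + 1:02d}"
        contigs[mid] = arr.tobytes().decode()
        labels[mid] = "minor"
    assembly = ReferenceAssembly(contigs=contigs)
    profile = DepthProfile(assembly)
    for cid in contigs:
        target = dominant_depth if labels[cid] == "dominant" else dominant_depth / depth_ratio
        depth = max(1, int(round(target * rng.lognormal(0.0, 0.05))))
        profile.depth[cid][:] = depth
    return contigs, profile, mag, labels


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sample_metadata(samples: Sequence[SampleDesign], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "system": s.system,
                "season": s.season,
                "filter_fraction": s.filter_fraction,
                "mean_depth": s.mean_depth,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)
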