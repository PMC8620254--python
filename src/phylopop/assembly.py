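"""Reference assemblies: contigs plus scaffold membership.

A reference assembly (typically a MAG) is an ordered list of contigs, each
belonging to exactly one scaffold; scaffold membership and contig rank
define the coordinate frame for LCR merging and circos-style plotting.
Coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass
class ReferenceAssembly:
    """Contigs with sequences plus an ordered scaffold grouping.

    Parameters
    ----------
    contigs
        Mapping of contig id -> uppercase A/C/G/T/N sequence, in rank order.
    scaffolds
        Mapping of scaffold id -> ordered list of member contig ids.
    """

    contigs: dict[str, str]
    scaffolds: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scaffolds:
            # degenerate default: one scaffold per contig
            self.scaffolds = {f"S{i + 1}": [cid] for i, cid in enumerate(self.contigs)}
        seen: set[str] = set()
        for sid, members in self.scaffolds.items():
            for cid in members:
                if cid not in self.contigs:
                    raise ValueError(f"scaffold {sid} names unknown contig {cid}")
                if cid in seen:
                    raise ValueError(f"contig {cid} appears in more than one scaffold")
                seen.add(cid)
        missing = set(self.contigs) - seen
        if missing:
            raise ValueError(f"contigs not assigned to any scaffold: {sorted(missing)}")
        for cid, seq in self.contigs.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"contig {cid} contains invalid characters {sorted(bad)}")

    # -- introspection -------------------------------------------------

    @property
    def contig_ids(self) -> list[str]:
        return list(self.contigs)

    def contig_rank(self, contig_id: str) -> int:
        return self.contig_ids.index(contig_id)

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def scaffold_of(self, contig_id: str) -> str:
        for sid, members in self.scaffolds.items():
            if contig_id in members:
                return sid
        raise KeyError(contig_id)

    # -- IO ------------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Write contigs as FASTA; headers carry the scaffold id."""
        records = [
            SeqRecord(Seq(seq), id=cid, description=f"scaffold={self.scaffold_of(cid)}")
            for cid, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def scaffold_table(self) -> pd.DataFrame:
        """Scaffold membership as a tidy table (contig_id, scaffold_id, rank)."""
        rows = []
        for sid, members in self.scaffolds.items():
            for rank, cid in enumerate(members):
                rows.append({"contig_id": cid, "scaffold_id": sid, "rank": rank})
        return pd.DataFrame(rows)

    def to_scaffold_tsv(self, path: str | Path) -> None:
        self.scaffold_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fasta(
        cls,
        fasta: str | Path,
        scaffold_tsv: str | Path | None = None,
    ) -> "ReferenceAssembly":
        """Load from FASTA plus an optional scaffold-membership TSV.

        Without a TSV, scaffold ids are taken from ``scaffold=`` header
        tags when present, else each contig becomes its own scaffold.
        """
        contigs: dict[str, str] = {}
        header_scaffold: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta), "fasta"):
            contigs[rec.id] = str(rec.seq).upper()
            for token in rec.description.split():
                if token.startswith("scaffold="):
                    header_scaffold[rec.id] = token.split("=", 1)[1]
        scaffolds: dict[str, list[str]] = {}
        if scaffold_tsv is not None:
            table = pd.read_csv(scaffold_tsv, sep="\t")
            table = table.sort_values(["scaffold_id", "rank"])
            for row in table.itertuples():
                scaffolds.setdefault(str(row.scaffold_id), []).append(str(row.contig_id))
        elif header_scaffold:
            for cid in contigs:
                scaffolds.setdefault(header_scaffold.get(cid, cid), []).append(cid)
        return cls(contigs=contigs, scaffolds=scaffolds)


def gc_percent(seq: str) -> float:
    """GC content in percent, ignoring N bases."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
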