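"""Paralog flagging and family copy-number statistics.

Any single genome containing at least two members of a protein family must
encode paralogs, whether or not those paralogs are isofunctional.  This module
flags such (family, genome) pairs, computes census statistics over a
family × genome membership matrix, and emits per-gene annotation-confidence
downgrades: confidence in a similarity-transferred annotation should drop as
soon as the family is known to contain paralogs anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .io import FamilyTable, Genome

REASON_SAME_GENOME = "paralog_in_same_genome"
REASON_ELSEWHERE = "family_has_paralogs_elsewhere"


@dataclass(frozen=True)
class ParalogFlag:
    family_id: str
    genome_id: str
    member_gene_ids: Tuple[str, ...]
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number != len(self.member_gene_ids) or self.copy_number < 2:
            raise ValueError(
                f"flag {self.family_id}/{self.genome_id}: copy_number must equal "
                "the member count and be >= 2"
            )


@dataclass(frozen=True)
class FamilyCopyStats:
    n_families: int
    n_genomes: int
    max_copy_number: Mapping[str, int]
    fraction_single_copy_everywhere: float
    fraction_with_paralogs: float

    def to_json(self, path: Path) -> Path:
        payload = {
            "n_families": self.n_families,
            "n_genomes": self.n_genomes,
            "fraction_single_copy_everywhere": self.fraction_single_copy_everywhere,
            "fraction_with_paralogs": self.fraction_with_paralogs,
            "max_copy_number": dict(self.max_copy_number),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return Path(path)


def find_paralogs(
    genomes: Sequence[Genome], family_table: FamilyTable
) -> List[ParalogFlag]:
    """One flag per (family, genome) with at least two members.

    Multiple contigs (chromosome + plasmids) count within the same genome:
    paralogy is a per-genome concept.  Output is ordered by
    (family_id, genome_id) and invariant under genome input order.
    """
    counts: Dict[Tuple[str, str], List[str]] = {}
    for genome in genomes:
        for gene in genome.genes():
            family_id = family_table.family_of(gene.gene_id)
            if family_id is None:
                continue
            counts.setdefault((family_id, genome.genome_id), []).append(gene.gene_id)
    flags = [
        ParalogFlag(
            family_id=family_id,
            genome_id=genome_id,
            member_gene_ids=tuple(sorted(members)),
            copy_number=len(members),
        )
        for (family_id, genome_id), members in counts.items()
        if len(members) >= 2
    ]
    flags.sort(key=lambda f: (f.family_id, f.genome_id))
    return flags


def family_copy_stats(membership: pd.DataFrame) -> FamilyCopyStats:
    """Copy-number census over a family × genome count matrix.

    ``fraction_single_copy_everywhere`` is the proportion of families whose
    maximum per-genome copy number is 1; its complement is
    ``fraction_with_paralogs``.  Families with zero members in every genome
    are excluded from the denominator.
    """
    if membership.size == 0:
        raise ValueError("empty membership matrix")
    if (membership.to_numpy() < 0).any():
        raise ValueError("membership counts must be non-negative")
    max_copy = membership.max(axis=1)
    present = max_copy[max_copy >= 1]
    if present.empty:
        raise ValueError("membership matrix has no family with any member")
    single = (present <= 1).sum()
    n = len(present)
    return FamilyCopyStats(
        n_families=int(n),
        n_genomes=int(membership.shape[1]),
        max_copy_number={str(f): int(c) for f, c in max_copy.items()},
        fraction_single_copy_everywhere=float(single / n),
        fraction_with_paralogs=float((n - single) / n),
    )


def flag_annotations(
    genomes: Sequence[Genome],
    family_table: FamilyTable,
    flags: Sequence[ParalogFlag],
) -> List[Tuple[str, str]]:
    """Per-gene annotation-confidence downgrades.

    Every member of any flagged family receives exactly one reason:
    ``paralog_in_same_genome`` when the gene's own genome carries >= 2 members,
    else ``family_has_paralogs_elsewhere``.  Same-genome takes precedence.
    """
    flagged_pairs = {(f.family_id, f.genome_id) for f in flags}
    flagged_families = {f.family_id for f in flags}
    out: List[Tuple[str, str]] = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for gene in genome.genes():
            family_id = family_table.family_of(gene.gene_id)
            if family_id not in flagged_families:
                continue
            if (family_id, genome.genome_id) in flagged_pairs:
                out.append((gene.gene_id, REASON_SAME_GENOME))
            else:
                out.append((gene.gene_id, REASON_ELSEWHERE))
    out.sort(key=lambda r: r[0])
    return out


def load_membership_long(path: Path) -> pd.DataFrame:
    """Load a long-format membership TSV (family_id, genome_id, gene_id)
    into a family × genome count matrix."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"family_id", "genome_id"} - set(df.columns)
    if missing:
        raise ValueError(f"membership table lacks columns: {sorted(missing)}")
    counts = (
        df.groupby(["family_id", "genome_id"]).size().unstack(fill_value=0)
    )
    return counts


def load_membership_matrix(path: Path) -> pd.DataFrame:
    """Load a pre-aggregated count matrix CSV (first column = family_id)."""
    return pd.read_csv(path, index_col=0)


def write_flags_tsv(flags: Sequence[ParalogFlag], path: Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "genome_id": f.genome_id,
                "copy_number": f.copy_number,
                "member_gene_ids": ";".join(f.member_gene_ids),
            }
            for f in flags
        ],
        columns=["family_id", "genome_id", "copy_number", "member_gene_ids"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)
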