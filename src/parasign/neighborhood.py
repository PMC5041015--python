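"""Gene-neighbourhood profiles, context graphs and subgroup partitions.

Paralogs that sit in the same conserved gene neighbourhood across multiple
genomes are likely isofunctional; paralogs in different conserved
neighbourhoods are likely not.  A neighbourhood profile is the set of family
labels flanking a focal gene within a window of ``k`` genes per side on the
same contig.  Profiles are compared by Jaccard similarity on those label sets
(order, strand and distance are deliberately ignored — the simplest measure
consistent with cross-genome context conservation), profiles above a
similarity threshold ``tau`` are linked, and single-linkage connected
components with at least two members spanning at least two genomes become
provisional isofunctional subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .io import FamilyTable, Gene, Genome


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Neighbour families within ``window_k`` genes of a focal gene."""

    focal_gene_id: str
    window_k: int
    neighbor_families: FrozenSet[str]
    ordered_neighbors: Tuple[Tuple[int, Optional[str], str], ...]

    def __post_init__(self) -> None:
        if len(self.ordered_neighbors) > 2 * self.window_k:
            raise ValueError("more neighbours than the window allows")
        for offset, _family, _strand in self.ordered_neighbors:
            if offset == 0 or abs(offset) > self.window_k:
                raise ValueError(f"offset {offset} outside [-k, k] \\ {{0}}")


@dataclass(frozen=True)
class Subgroup:
    label: str
    members: Tuple[str, ...]
    supporting_families: FrozenSet[str]


@dataclass(frozen=True)
class SubgroupPartition:
    family_id: str
    subgroups: Tuple[Subgroup, ...]
    unplaced: Tuple[str, ...]

    def label_of(self, gene_id: str) -> Optional[str]:
        for sg in self.subgroups:
            if gene_id in sg.members:
                return sg.label
        return None

    @property
    def all_members(self) -> Tuple[str, ...]:
        out: List[str] = []
        for sg in self.subgroups:
            out.extend(sg.members)
        out.extend(self.unplaced)
        return tuple(sorted(out))


def extract_neighborhood(
    gene: Gene,
    genome: Genome,
    window_k: int = 5,
    include_singletons: bool = False,
) -> NeighborhoodProfile:
    """Profile of up to ``window_k`` genes on each side of ``gene``.

    Truncated at contig ends.  The focal gene's own family is excluded from
    ``neighbor_families``.  Neighbours without a family label are excluded by
    default; with ``include_singletons`` they contribute a reserved
    ``singleton:<gene_id>`` label instead.
    """
    contig_id, idx = genome.locate(gene.gene_id)
    genes = genome.contigs[contig_id]
    ordered: List[Tuple[int, Optional[str], str]] = []
    families: set = set()
    for offset in range(-window_k, window_k + 1):
        if offset == 0:
            continue
        pos = idx + offset
        if pos < 0 or pos >= len(genes):
            continue
        neighbor = genes[pos]
        label = neighbor.family_id
        if label is None and include_singletons:
            label = f"singleton:{neighbor.gene_id}"
        ordered.append((offset, label, neighbor.strand))
        if label is not None and label != gene.family_id:
            families.add(label)
    return NeighborhoodProfile(
        focal_gene_id=gene.gene_id,
        window_k=window_k,
        neighbor_families=frozenset(families),
        ordered_neighbors=tuple(ordered),
    )


def neighborhood_similarity(
    p1: NeighborhoodProfile, p2: NeighborhoodProfile
) -> float:
    """Jaccard index of the two neighbour-family sets (both empty → 0)."""
    a, b = p1.neighbor_families, p2.neighbor_families
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def build_context_graph(
    profiles: Sequence[NeighborhoodProfile], tau: float = 0.3
) -> nx.Graph:
    """Undirected graph linking focal genes with neighbourhood similarity >= tau.

    All focal genes appear as nodes, including isolated ones.
    """
    graph = nx.Graph()
    for p in profiles:
        graph.add_node(p.focal_gene_id)
    for i, p1 in enumerate(profiles):
        for p2 in profiles[i + 1 :]:
            if p1.focal_gene_id == p2.focal_gene_id:
                continue
            sim = neighborhood_similarity(p1, p2)
            if sim >= tau:
                graph.add_edge(p1.focal_gene_id, p2.focal_gene_id, weight=sim)
    return graph


def partition_family(
    graph: nx.Graph,
    profiles: Mapping[str, NeighborhoodProfile],
    gene_to_genome: Mapping[str, str],
    family_id: str = "",
) -> SubgroupPartition:
    """Subgroups = connected components with >= 2 members from >= 2 genomes.

    Components failing the two-genome support rule, and isolated nodes, are
    unplaced.  Labels SG1, SG2, ... are assigned in order of each subgroup's
    smallest member gene_id, so they are stable under member input order.
    The supporting family set is the intersection of the members' neighbour
    families, falling back to labels shared by >= 50% of members when the
    intersection is empty.
    """
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    subgroups: List[Subgroup] = []
    unplaced: List[str] = []
    for members in components:
        genomes = {gene_to_genome[g] for g in members}
        if len(members) < 2 or len(genomes) < 2:
            unplaced.extend(members)
            continue
        member_sets = [profiles[g].neighbor_families for g in members]
        support = frozenset.intersection(*member_sets)
        if not support:
            counts: Dict[str, int] = {}
            for s in member_sets:
                for label in s:
                    counts[label] = counts.get(label, 0) + 1
            support = frozenset(
                label
                for label, n in counts.items()
                if n >= 0.5 * len(members)
            )
        subgroups.append(
            Subgroup(
                label="",
                members=tuple(members),
                supporting_families=support,
            )
        )
    subgroups.sort(key=lambda sg: sg.members[0])
    labeled = tuple(
        Subgroup(
            label=f"SG{i + 1}",
            members=sg.members,
            supporting_families=sg.supporting_families,
        )
        for i, sg in enumerate(subgroups)
    )
    return SubgroupPartition(
        family_id=family_id,
        subgroups=labeled,
        unplaced=tuple(sorted(unplaced)),
    )


def gnn_summary(
    partition: SubgroupPartition,
    profiles: Mapping[str, NeighborhoodProfile],
) -> pd.DataFrame:
    """Per-subgroup neighbour-family tabulation (genome-neighbourhood summary).

    For each subgroup, every neighbour family with the number of members whose
    profile contains it and the member fraction, sorted by descending count.
    """
    rows: List[dict] = []
    for sg in partition.subgroups:
        counts: Dict[str, int] = {}
        for gene_id in sg.members:
            for label in profiles[gene_id].neighbor_families:
                counts[label] = counts.get(label, 0) + 1
        n = len(sg.members)
        for label in sorted(counts, key=lambda l: (-counts[l], l)):
            rows.append(
                {
                    "subgroup": sg.label,
                    "neighbor_family": label,
                    "n_members": counts[label],
                    "member_fraction": counts[label] / n,
                }
            )
    return pd.DataFrame(
        rows, columns=["subgroup", "neighbor_family", "n_members", "member_fraction"]
    )


def tau_sweep(
    profiles: Sequence[NeighborhoodProfile],
    gene_to_genome: Mapping[str, str],
    taus: Optional[Sequence[float]] = None,
    family_id: str = "",
) -> pd.DataFrame:
    """Sensitivity of the partition to the similarity threshold.

    The similarity scheme is an artifact decision (conserved context is never
    quantified in the source workflow), so the partition's stability across
    tau is reported alongside any single default.
    """
    if taus is None:
        taus = [round(t, 2) for t in np.arange(0.0, 1.0001, 0.05)]
    profile_map = {p.focal_gene_id: p for p in profiles}
    rows = []
    for tau in taus:
        graph = build_context_graph(profiles, tau=tau)
        part = partition_family(graph, profile_map, gene_to_genome, family_id)
        rows.append(
            {
                "tau": tau,
                "n_subgroups": len(part.subgroups),
                "n_unplaced": len(part.unplaced),
                "largest_subgroup": max(
                    (len(sg.members) for sg in part.subgroups), default=0
                ),
            }
        )
    return pd.DataFrame(rows)


def write_partition_tsv(partition: SubgroupPartition, path) -> None:
    rows = []
    for sg in partition.subgroups:
        for gene_id in sg.members:
            rows.append(
                {
                    "gene_id": gene_id,
                    "subgroup": sg.label,
                    "supporting_families": ";".join(sorted(sg.supporting_families)),
                }
            )
    for gene_id in partition.unplaced:
        rows.append(
            {"gene_id": gene_id, "subgroup": "unplaced", "supporting_families": ""}
        )
    pd.DataFrame(rows, columns=["gene_id", "subgroup", "supporting_families"]).to_csv(
        path, sep="\t", index=False
    )
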