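"""Read and write the standard formats and join them into a pan-genome model.

The input contract is one GFF3 file and one protein FASTA file per genome
(the file stem is the genome identifier) plus a tab-separated table mapping
gene identifiers to family labels (COG-style).  Coordinates follow the GFF3
convention: 1-based, inclusive.  Only ``gene`` and ``CDS`` features are
consulted; the ``ID`` attribute (falling back to ``locus_tag``) is the gene
identifier.

Genes that appear in the GFF3 but have no protein sequence are kept — flanking
genes only need a family label to contribute neighbourhood evidence.  Genes
with no family row are kept with an unassigned family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AA20 + "X")

ANNOTATION_COLUMNS = (
    "gene_id",
    "genome_id",
    "family_id",
    "subgroup",
    "evidence",
    "confidence",
    "motif_matched",
)


@dataclass(frozen=True)
class Gene:
    """A single gene model on a contig.

    ``protein`` may be ``None`` for neighbours that only contribute a family
    label; ``family_id`` may be ``None`` for genes outside any family.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: Optional[str] = None
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.protein is not None:
            bad = set(self.protein) - VALID_RESIDUES
            if bad:
                raise ValueError(
                    f"gene {self.gene_id}: non-standard residues {sorted(bad)}"
                )


@dataclass
class Genome:
    """Ordered gene models per contig for one genome.

    Within each contig genes are ordered by start coordinate regardless of
    strand, mirroring how neighbourhood context mixes strands in prokaryotic
    gene clusters.
    """

    genome_id: str
    contigs: Dict[str, List[Gene]]
    _positions: Dict[str, Tuple[str, int]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for contig_id, genes in self.contigs.items():
            genes.sort(key=lambda g: (g.start, g.gene_id))
            for gene in genes:
                if gene.genome_id != self.genome_id:
                    raise ValueError(
                        f"gene {gene.gene_id} belongs to genome {gene.genome_id}, "
                        f"not {self.genome_id}"
                    )
        self._reindex()

    def _reindex(self) -> None:
        self._positions = {}
        for contig_id, genes in self.contigs.items():
            for i, gene in enumerate(genes):
                self._positions[gene.gene_id] = (contig_id, i)

    @classmethod
    def from_genes(cls, genome_id: str, genes: Iterable[Gene]) -> "Genome":
        contigs: Dict[str, List[Gene]] = {}
        for gene in genes:
            contigs.setdefault(gene.contig_id, []).append(gene)
        return cls(genome_id=genome_id, contigs=contigs)

    def genes(self) -> Iterator[Gene]:
        for contig_id in sorted(self.contigs):
            yield from self.contigs[contig_id]

    def locate(self, gene_id: str) -> Tuple[str, int]:
        """Return (contig_id, index within contig) for a gene."""
        try:
            return self._positions[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id} not found in genome {self.genome_id}"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._positions

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.genome_id == other.genome_id and self.contigs == other.contigs


class FamilyTable:
    """Gene → family assignments with derived per-family indexes.

    Each gene maps to at most one family; multi-family rows are rejected
    because fused/multi-domain genes are out of scope.
    """

    def __init__(
        self,
        rows: Iterable[Tuple[str, str]],
        gene_to_genome: Optional[Mapping[str, str]] = None,
    ) -> None:
        self._family_of: Dict[str, str] = {}
        for gene_id, family_id in rows:
            if gene_id in self._family_of:
                if self._family_of[gene_id] != family_id:
                    raise ValueError(
                        f"gene {gene_id} assigned to two families "
                        f"({self._family_of[gene_id]}, {family_id}); "
                        "fusion genes are unsupported"
                    )
                raise ValueError(f"duplicate family row for gene {gene_id}")
            self._family_of[gene_id] = family_id
        self._members: Dict[str, List[str]] = {}
        for gene_id, family_id in self._family_of.items():
            self._members.setdefault(family_id, []).append(gene_id)
        for members in self._members.values():
            members.sort()
        self._gene_to_genome: Dict[str, str] = dict(gene_to_genome or {})

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self._family_of.items()), columns=["gene_id", "family_id"]
        )

    @property
    def families(self) -> List[str]:
        return sorted(self._members)

    def family_of(self, gene_id: str) -> Optional[str]:
        return self._family_of.get(gene_id)

    def genes_in(self, family_id: str) -> List[str]:
        return list(self._members.get(family_id, []))

    def members(self, family_id: str, genome_id: str) -> List[str]:
        return [
            g
            for g in self._members.get(family_id, [])
            if self._gene_to_genome.get(g) == genome_id
        ]

    def genome_of(self, gene_id: str) -> Optional[str]:
        return self._gene_to_genome.get(gene_id)

    def attach_genomes(self, genomes: Sequence[Genome]) -> None:
        for genome in genomes:
            for gene in genome.genes():
                self._gene_to_genome[gene.gene_id] = genome.genome_id

    def __len__(self) -> int:
        return len(self._family_of)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyTable):
            return NotImplemented
        return self._family_of == other._family_of


def _gene_id_of(feature: gffutils.Feature) -> str:
    for key in ("ID", "locus_tag"):
        values = feature.attributes.get(key)
        if values:
            return values[0]
    raise ValueError(
        f"feature at {feature.seqid}:{feature.start}-{feature.end} has neither "
        "ID nor locus_tag attribute"
    )


def read_pangenome(
    gff_paths: Sequence[Path],
    fasta_paths: Sequence[Path],
    family_table_path: Path,
) -> Tuple[List[Genome], FamilyTable]:
    """Join GFF3 gene models, protein FASTA and family labels.

    Returns genomes sorted by genome identifier (the file stem) and the joined
    family table.  Family rows referencing unknown genes are skipped with a
    logged count; duplicate gene identifiers and multi-family genes are hard
    errors.
    """
    proteins: Dict[str, str] = {}
    for fasta_path in fasta_paths:
        for record in SeqIO.parse(str(fasta_path), "fasta"):
            if record.id in proteins:
                raise ValueError(f"duplicate protein record for gene {record.id}")
            proteins[record.id] = str(record.seq).upper()

    genomes: List[Genome] = []
    seen_genes: Dict[str, str] = {}
    for gff_path in sorted(Path(p) for p in gff_paths):
        genome_id = gff_path.stem
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes: List[Gene] = []
        for feature in db.all_features():
            if feature.featuretype not in ("gene", "CDS"):
                continue
            gene_id = _gene_id_of(feature)
            if gene_id in seen_genes:
                raise ValueError(
                    f"duplicate gene_id {gene_id} "
                    f"(in {seen_genes[gene_id]} and {genome_id})"
                )
            seen_genes[gene_id] = genome_id
            genes.append(
                Gene(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=feature.seqid,
                    start=feature.start,
                    end=feature.end,
                    strand=feature.strand if feature.strand in "+-" else "+",
                    protein=proteins.get(gene_id),
                )
            )
        genomes.append(Genome.from_genes(genome_id, genes))
    genomes.sort(key=lambda g: g.genome_id)

    table = pd.read_csv(family_table_path, sep="\t", dtype=str)
    missing = {"gene_id", "family_id"} - set(table.columns)
    if missing:
        raise ValueError(f"family table lacks columns: {sorted(missing)}")

    rows: List[Tuple[str, str]] = []
    skipped = 0
    for gene_id, family_id in zip(table["gene_id"], table["family_id"]):
        if gene_id not in seen_genes:
            skipped += 1
            continue
        rows.append((gene_id, family_id))
    if skipped:
        logger.warning(
            "family table: skipped %d row(s) referencing unknown genes", skipped
        )

    family_table = FamilyTable(rows)
    family_table.attach_genomes(genomes)

    # fold family labels back onto the Gene objects
    for genome in genomes:
        for contig_id, genes in genome.contigs.items():
            genome.contigs[contig_id] = [
                Gene(
                    gene_id=g.gene_id,
                    genome_id=g.genome_id,
                    contig_id=g.contig_id,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    protein=g.protein,
                    family_id=family_table.family_of(g.gene_id),
                )
                for g in genes
            ]
        genome._reindex()
    return genomes, family_table


def write_annotation_table(calls: Sequence["AnnotationCall"], path: Path) -> Path:
    """Write annotation calls as TSV, ordered by (genome_id, gene_id).

    Multiple matched patterns (hybrid calls) are joined with ';'.
    """
    rows = [
        {
            "gene_id": c.gene_id,
            "genome_id": c.genome_id,
            "family_id": c.family_id,
            "subgroup": c.subgroup,
            "evidence": c.evidence,
            "confidence": c.confidence,
            "motif_matched": ";".join(c.matched_patterns),
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    df = df.sort_values(["genome_id", "gene_id"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_annotation_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df


GRAPH_FORMATS = ("edgelist", "graphml")


def write_graph(graph: nx.Graph, path: Path, format: str = "edgelist") -> Path:
    """Export a weighted graph for external viewers (Cytoscape etc.)."""
    if format == "edgelist":
        nx.write_weighted_edgelist(graph, str(path))
    elif format == "graphml":
        nx.write_graphml(graph, str(path))
    else:
        raise ValueError(
            f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}"
        )
    return Path(path)


def read_graph(path: Path, format: str = "edgelist") -> nx.Graph:
    if format == "edgelist":
        return nx.read_weighted_edgelist(str(path))
    if format == "graphml":
        g = nx.read_graphml(str(path))
        out = nx.Graph()
        out.add_nodes_from(g.nodes())
        for u, v, data in g.edges(data=True):
            out.add_edge(u, v, weight=float(data.get("weight", 1.0)))
        return out
    raise ValueError(
        f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}"
    )


def write_genome_gff3(genome: Genome, path: Path) -> Path:
    """Emit one genome as GFF3 (gene features, ID + locus_tag attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id in sorted(genome.contigs):
            genes = genome.contigs[contig_id]
            region_end = max((g.end for g in genes), default=1) + 1000
            fh.write(f"##sequence-region {contig_id} 1 {region_end}\n")
            for gene in genes:
                attrs = f"ID={gene.gene_id};locus_tag={gene.gene_id}"
                fh.write(
                    f"{contig_id}\tparasign\tgene\t{gene.start}\t{gene.end}"
                    f"\t.\t{gene.strand}\t.\t{attrs}\n"
                )
    return Path(path)


def write_genome_fasta(genome: Genome, path: Path) -> Path:
    """Emit the protein FASTA for one genome (genes with sequences only)."""
    records = [
        SeqRecord(Seq(g.protein), id=g.gene_id, description="")
        for g in genome.genes()
        if g.protein is not None
    ]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def write_family_table(family_table: FamilyTable, path: Path) -> Path:
    family_table.df.to_csv(path, sep="\t", index=False)
    return Path(path)
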