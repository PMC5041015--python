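"""Seeded synthetic pan-genomes with planted subgroup structure.

The generator emulates the situation the workflow targets: a focal multigene
family whose members fall into isofunctional subgroups, where each subgroup
carries (i) a distinct conserved set of flanking neighbour families and
(ii) a distinct short signature motif embedded in otherwise diverged
sequences.  Noise knobs cover neighbour gene loss, neighbour rearrangement
and per-literal motif mutation.  Everything is deterministic given the seed,
and a machine-readable truth set ships with the files so every stage of the
workflow can be scored without external data.

Member proteins are ungapped copies of a per-subgroup template: the template
is background-sampled (motif literals written at a subgroup-specific offset,
wildcard positions drawn from the background once, into the template), and
each member re-samples every non-literal position with probability
``background_divergence``.  This mimics subfamily sequences that are
alignable yet diverged, while the motif literals stay nearly invariant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    AA20,
    FamilyTable,
    Gene,
    Genome,
    write_family_table,
    write_genome_fasta,
    write_genome_gff3,
)
from .motif import WILDCARD

DEFAULT_PATTERNS = ("CxxxHGH", "CxxxxxHGH", "ExxHGH")

_LEADING_SPACERS = 6
_BLOCK_SPACERS = 8
_MOTIF_MARGIN = 10


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic pan-genome."""

    n_genomes: int = 20
    n_subgroups: int = 3
    motif_patterns: Tuple[str, ...] = DEFAULT_PATTERNS
    context_size: int = 3
    window_k: int = 5
    protein_length: int = 120
    motif_mutation: float = 0.02
    gene_loss: float = 0.1
    rearrangement: float = 0.2
    decoy_families: int = 30
    decoy_label_density: float = 0.15
    background_divergence: float = 0.55
    background: str = "uniform"
    paralog_genome_fraction: float = 0.5
    duplicate_prob: float = 0.15
    family_id: str = "FAM1"
    context_labels: Optional[Tuple[Tuple[str, ...], ...]] = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "motif_mutation",
            "gene_loss",
            "rearrangement",
            "decoy_label_density",
            "background_divergence",
            "paralog_genome_fraction",
            "duplicate_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.motif_patterns) != self.n_subgroups:
            raise ValueError("one motif pattern per subgroup required")
        for pattern in self.motif_patterns:
            if len(pattern) + 2 * _MOTIF_MARGIN > self.protein_length:
                raise ValueError(
                    f"motif {pattern!r} does not fit in proteins of length "
                    f"{self.protein_length}"
                )
        if self.context_labels is not None and len(self.context_labels) != (
            self.n_subgroups
        ):
            raise ValueError("one context label set per subgroup required")

    def subgroup_labels(self) -> Tuple[str, ...]:
        return tuple(f"sub{i + 1}" for i in range(self.n_subgroups))

    def contexts(self) -> Tuple[Tuple[str, ...], ...]:
        if self.context_labels is not None:
            return self.context_labels
        return tuple(
            tuple(f"CTX{i + 1}_{j + 1}" for j in range(self.context_size))
            for i in range(self.n_subgroups)
        )


@dataclass(frozen=True)
class TruthRecord:
    subgroup: str
    context_labels: Tuple[str, ...]
    motif_start: int
    pattern: str
    motif_intact: bool


@dataclass
class TruthSet:
    """Planted ground truth, consistent with the emitted files."""

    family_id: str
    subgroup_of: Dict[str, TruthRecord]
    gene_order: Dict[str, List[str]]
    patterns: Dict[str, str]
    contexts: Dict[str, Tuple[str, ...]]

    @property
    def focal_genes(self) -> List[str]:
        return sorted(self.subgroup_of)

    def labels(self) -> Dict[str, str]:
        return {g: r.subgroup for g, r in self.subgroup_of.items()}

    def to_json(self, path: Path) -> Path:
        payload = {
            "family_id": self.family_id,
            "patterns": self.patterns,
            "contexts": {k: list(v) for k, v in self.contexts.items()},
            "gene_order": self.gene_order,
            "genes": {
                g: {
                    "subgroup": r.subgroup,
                    "context_labels": list(r.context_labels),
                    "motif_start": r.motif_start,
                    "pattern": r.pattern,
                    "motif_intact": r.motif_intact,
                }
                for g, r in sorted(self.subgroup_of.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return Path(path)

    @classmethod
    def from_json(cls, path: Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            family_id=payload["family_id"],
            subgroup_of={
                g: TruthRecord(
                    subgroup=d["subgroup"],
                    context_labels=tuple(d["context_labels"]),
                    motif_start=d["motif_start"],
                    pattern=d["pattern"],
                    motif_intact=d["motif_intact"],
                )
                for g, d in payload["genes"].items()
            },
            gene_order={k: list(v) for k, v in payload["gene_order"].items()},
            patterns=dict(payload["patterns"]),
            contexts={k: tuple(v) for k, v in payload["contexts"].items()},
        )


@dataclass
class SyntheticPangenome:
    config: SynthConfig
    genomes: List[Genome]
    family_table: FamilyTable
    truth: TruthSet
    paths: Optional[Dict[str, object]] = None


def _sample_background(rng: np.random.Generator, n: int) -> List[str]:
    return [AA20[i] for i in rng.integers(0, len(AA20), size=n)]


def _mutate_residue(rng: np.random.Generator, residue: str) -> str:
    choices = [a for a in AA20 if a != residue]
    return choices[int(rng.integers(0, len(choices)))]


class _SubgroupModel:
    """Template + motif placement for one subgroup."""

    def __init__(
        self, label: str, pattern: str, config: SynthConfig, rng: np.random.Generator
    ) -> None:
        self.label = label
        self.pattern = pattern
        self.template = _sample_background(rng, config.protein_length)
        self.offset = int(
            rng.integers(
                _MOTIF_MARGIN,
                config.protein_length - len(pattern) - _MOTIF_MARGIN + 1,
            )
        )
        # literals are written into the template; wildcard positions keep
        # their background draw and diverge like the rest of the backbone
        for p, c in enumerate(pattern):
            if c != WILDCARD:
                self.template[self.offset + p] = c
        self.literal_positions = frozenset(
            self.offset + p for p, c in enumerate(pattern) if c != WILDCARD
        )

    def sample_member(
        self, config: SynthConfig, rng: np.random.Generator
    ) -> Tuple[str, bool]:
        seq = list(self.template)
        intact = True
        for pos in range(len(seq)):
            if pos in self.literal_positions:
                if rng.random() < config.motif_mutation:
                    seq[pos] = _mutate_residue(rng, seq[pos])
                    intact = False
            else:
                if rng.random() < config.background_divergence:
                    seq[pos] = AA20[int(rng.integers(0, len(AA20)))]
        return "".join(seq), intact


def generate_pangenome(
    config: SynthConfig, out_dir: Optional[Path] = None
) -> SyntheticPangenome:
    """Generate genomes, family table and truth set; optionally write files.

    Each focal member sits in a block flanked by its subgroup's context
    families (each lost with ``gene_loss`` probability, order shuffled with
    ``rearrangement`` probability); blocks are separated by runs of decoy
    loci, a fraction of which carry decoy family labels while the rest are
    family-unassigned.  About ``paralog_genome_fraction`` of genomes carry
    members of two or more subgroups (the workflow's entry point).
    """
    rng = np.random.default_rng(config.seed)
    labels = config.subgroup_labels()
    contexts = config.contexts()
    models = [
        _SubgroupModel(labels[i], config.motif_patterns[i], config, rng)
        for i in range(config.n_subgroups)
    ]
    decoy_pool = [f"DEC{j + 1:03d}" for j in range(config.decoy_families)]

    genomes: List[Genome] = []
    family_rows: List[Tuple[str, str]] = []
    truth_genes: Dict[str, TruthRecord] = {}
    gene_order: Dict[str, List[str]] = {}

    for g in range(config.n_genomes):
        genome_id = f"G{g + 1:02d}"
        contig_id = f"{genome_id}_c1"
        # which subgroups does this genome host?
        host: List[int] = []
        if rng.random() < config.paralog_genome_fraction and config.n_subgroups >= 2:
            m = int(rng.integers(2, config.n_subgroups + 1))
            host = sorted(rng.choice(config.n_subgroups, size=m, replace=False))
            blocks: List[int] = []
            for i in host:
                copies = 2 if rng.random() < config.duplicate_prob else 1
                blocks.extend([i] * copies)
        else:
            blocks = [int(rng.integers(0, config.n_subgroups))]
        blocks = [int(b) for b in rng.permutation(blocks)]

        # lay out the contig as (family label or None, protein, truth record)
        loci: List[Tuple[Optional[str], Optional[str], Optional[TruthRecord]]] = []

        def spacers(n: int) -> None:
            for _ in range(n):
                if rng.random() < config.decoy_label_density:
                    label = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
                else:
                    label = None
                loci.append((label, None, None))

        spacers(_LEADING_SPACERS)
        for b, sub_idx in enumerate(blocks):
            if b > 0:
                spacers(_BLOCK_SPACERS)
            model = models[sub_idx]
            kept = [
                lab
                for lab in contexts[sub_idx]
                if rng.random() >= config.gene_loss
            ]
            if len(kept) > 1 and rng.random() < config.rearrangement:
                kept = [kept[i] for i in rng.permutation(len(kept))]
            n_left = len(kept) // 2
            protein, intact = model.sample_member(config, rng)
            record = TruthRecord(
                subgroup=model.label,
                context_labels=tuple(sorted(kept)),
                motif_start=model.offset,
                pattern=model.pattern,
                motif_intact=intact,
            )
            for lab in kept[:n_left]:
                loci.append((lab, None, None))
            loci.append((config.family_id, protein, record))
            for lab in kept[n_left:]:
                loci.append((lab, None, None))
        spacers(_LEADING_SPACERS)

        genes: List[Gene] = []
        order: List[str] = []
        for idx, (family_label, protein, record) in enumerate(loci):
            gene_id = f"{genome_id}_{idx + 1:04d}"
            start = 10 + idx * 1000
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=start,
                    end=start + 899,
                    strand=strand,
                    protein=protein,
                    family_id=family_label,
                )
            )
            order.append(gene_id)
            if family_label is not None:
                family_rows.append((gene_id, family_label))
            if record is not None:
                truth_genes[gene_id] = record
        genomes.append(Genome.from_genes(genome_id, genes))
        gene_order[genome_id] = order

    family_table = FamilyTable(family_rows)
    family_table.attach_genomes(genomes)
    truth = TruthSet(
        family_id=config.family_id,
        subgroup_of=truth_genes,
        gene_order=gene_order,
        patterns={m.label: m.pattern for m in models},
        contexts={labels[i]: contexts[i] for i in range(config.n_subgroups)},
    )

    paths: Optional[Dict[str, object]] = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        gdir = out_dir / "genomes"
        gdir.mkdir(parents=True, exist_ok=True)
        gff_paths: List[Path] = []
        fasta_paths: List[Path] = []
        for genome in genomes:
            gff = gdir / f"{genome.genome_id}.gff3"
            faa = gdir / f"{genome.genome_id}.faa"
            write_genome_gff3(genome, gff)
            write_genome_fasta(genome, faa)
            gff_paths.append(gff)
            fasta_paths.append(faa)
        families = out_dir / "families.tsv"
        write_family_table(family_table, families)
        truth_path = out_dir / "truth.json"
        truth.to_json(truth_path)
        paths = {
            "gff": gff_paths,
            "fasta": fasta_paths,
            "families": families,
            "truth": truth_path,
        }
    return SyntheticPangenome(
        config=config,
        genomes=genomes,
        family_table=family_table,
        truth=truth,
        paths=paths,
    )


def corrupt_annotations(
    truth: TruthSet, fraction: float, seed: int
) -> Tuple[pd.DataFrame, List[str]]:
    """A baseline annotation table with cross-subgroup label transfers.

    Exactly ``round(fraction * n)`` members get another subgroup's label,
    modelling over-annotation by transfer between functionally divergent
    paralogs.  Returns the table and the corrupted gene ids.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.focal_genes
    n_corrupt = round(fraction * len(genes))
    corrupted = sorted(
        rng.choice(genes, size=n_corrupt, replace=False).tolist()
    )
    all_labels = sorted(truth.patterns)
    rows = []
    corrupted_set = set(corrupted)
    for gene_id in genes:
        true_label = truth.subgroup_of[gene_id].subgroup
        if gene_id in corrupted_set:
            others = [l for l in all_labels if l != true_label]
            label = others[int(rng.integers(0, len(others)))]
        else:
            label = true_label
        rows.append({"gene_id": gene_id, "subgroup": label})
    return pd.DataFrame(rows, columns=["gene_id", "subgroup"]), corrupted


def overlapping_similarity_family(
    seed: int = 7,
    n_per_group: int = 8,
    length: int = 150,
    template_divergence: float = 0.2,
    member_divergence: Tuple[float, float] = (0.05, 0.6),
) -> Tuple[Dict[str, str], Dict[str, str]]:
    """Two subgroups whose similarity ranges overlap.

    Both subgroup templates descend from a common ancestor, and member
    divergence from the subgroup template is graded from tight to loose, so
    the loosest within-subgroup pairs score below the tightest
    between-subgroup pairs.  This is the regime in which no similarity
    threshold can both keep each subgroup whole and keep the clusters pure.
    Returns (proteins, labels).
    """
    rng = np.random.default_rng(seed)
    ancestor = _sample_background(rng, length)

    def derive(template: List[str], rate: float) -> List[str]:
        return [
            (AA20[int(rng.integers(0, len(AA20)))] if rng.random() < rate else c)
            for c in template
        ]

    proteins: Dict[str, str] = {}
    labels: Dict[str, str] = {}
    rates = np.linspace(member_divergence[0], member_divergence[1], n_per_group)
    for group in ("A", "B"):
        template = derive(ancestor, template_divergence)
        for i, rate in enumerate(rates):
            gene_id = f"{group}{i + 1:02d}"
            proteins[gene_id] = "".join(derive(template, float(rate)))
            labels[gene_id] = group
    return proteins, labels
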