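"""Sequence-similarity networks and the threshold-sweep diagnostic.

Pairwise similarity is the Smith–Waterman optimal local alignment score under
BLOSUM62 with affine gaps (open 11, extend 1), converted to a bit score

    bits = (lambda * S - ln K) / ln 2

with the standard gapped-BLOSUM62(11,1) constants lambda = 0.267, K = 0.041.
Bit scores are database-free and monotone in the raw score, which makes the
exhaustive threshold sweep well defined; the classic workflow's "alignment
score" thresholds 15/25/30 are retained as named presets, with the caveat
that those were expressed in a different tool's units.

The sweep quantifies the known failure mode of similarity-only clustering:
when between-subgroup similarity overlaps within-subgroup similarity, any
edge threshold high enough to make every cluster label-pure also splits some
subgroup across clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import VALID_RESIDUES

LAMBDA_GAPPED = 0.267
K_GAPPED = 0.041

GAP_OPEN = -11.0
GAP_EXTEND = -1.0

#: Named presets mirroring the commonly used alignment-score cutoffs.
THRESHOLD_PRESETS = {"initial": 15.0, "gnn": 25.0, "separation": 30.0}


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def raw_to_bits(score: float) -> float:
    return (LAMBDA_GAPPED * score - math.log(K_GAPPED)) / math.log(2)


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric all-vs-all alignment bit scores over family members."""

    gene_ids: Tuple[str, ...]
    bits: np.ndarray
    raw: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.bits.shape != (n, n) or self.raw.shape != (n, n):
            raise ValueError("score matrix shape does not match gene count")

    def index_of(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def off_diagonal_bits(self) -> np.ndarray:
        n = len(self.gene_ids)
        iu = np.triu_indices(n, k=1)
        return self.bits[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bits, index=list(self.gene_ids), columns=list(self.gene_ids)
        )


def pairwise_scores(proteins: Mapping[str, str]) -> ScoreMatrix:
    """All-vs-all Smith–Waterman bit scores.

    Sequences must be non-empty and contain only the 20 standard residues
    plus X.  Bit scores are clamped at 0.
    """
    ids = tuple(sorted(proteins))
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    for gene_id in ids:
        seq = proteins[gene_id]
        if not seq:
            raise ValueError(f"empty sequence for gene {gene_id}")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"invalid residues {sorted(bad)} in sequence for gene {gene_id}"
            )
    aligner = _local_aligner()
    n = len(ids)
    raw = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = aligner.score(proteins[ids[i]], proteins[ids[j]])
            raw[i, j] = raw[j, i] = s
    bits = np.maximum(raw_to_bits(raw), 0.0)
    return ScoreMatrix(gene_ids=ids, bits=bits, raw=raw)


@dataclass(frozen=True)
class SSNGraph:
    threshold: float
    graph: nx.Graph

    @property
    def components(self) -> List[Tuple[str, ...]]:
        comps = [tuple(sorted(c)) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: c[0])
        return comps


def build_ssn(scores: ScoreMatrix, threshold: float) -> SSNGraph:
    """Graph with an edge wherever the bit score meets the threshold."""
    graph = nx.Graph()
    graph.add_nodes_from(scores.gene_ids)
    n = len(scores.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if scores.bits[i, j] >= threshold:
                graph.add_edge(
                    scores.gene_ids[i],
                    scores.gene_ids[j],
                    weight=float(scores.bits[i, j]),
                )
    return SSNGraph(threshold=threshold, graph=graph)


def _purity_and_splits(
    components: Sequence[Tuple[str, ...]], labels: Mapping[str, str]
) -> Tuple[float, int, bool]:
    n_nodes = sum(len(c) for c in components)
    pure_nodes = 0
    all_pure = True
    clusters_of_label: Dict[str, int] = {}
    for comp in components:
        counts: Dict[str, int] = {}
        for node in comp:
            counts[labels[node]] = counts.get(labels[node], 0) + 1
        majority = min(
            (label for label in counts), key=lambda l: (-counts[l], l)
        )
        pure_nodes += counts[majority]
        if len(counts) > 1:
            all_pure = False
        for label in counts:
            clusters_of_label[label] = clusters_of_label.get(label, 0) + 1
    n_split = sum(1 for k in clusters_of_label.values() if k >= 2)
    one_cluster_each = all(k == 1 for k in clusters_of_label.values())
    return pure_nodes / n_nodes, n_split, all_pure and one_cluster_each


def threshold_sweep(
    scores: ScoreMatrix, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Exhaustive sweep over all distinct off-diagonal bit scores.

    For each candidate threshold: number of connected components, cluster
    purity (fraction of nodes whose cluster's majority label is their own),
    the number of subgroups split across >= 2 clusters, and whether every
    cluster is label-pure while every label occupies exactly one cluster
    (``fully_separated``).
    """
    missing = set(scores.gene_ids) - set(labels)
    if missing:
        raise ValueError(f"labels missing for nodes: {sorted(missing)}")
    candidates = sorted(set(np.round(scores.off_diagonal_bits(), 9)))
    rows = []
    for t in candidates:
        ssn = build_ssn(scores, float(t))
        comps = ssn.components
        purity, n_split, separated = _purity_and_splits(comps, labels)
        rows.append(
            {
                "threshold": float(t),
                "n_clusters": len(comps),
                "purity": purity,
                "n_split_subgroups": n_split,
                "fully_separated": separated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "threshold",
            "n_clusters",
            "purity",
            "n_split_subgroups",
            "fully_separated",
        ],
    )


def write_scores_tsv(scores: ScoreMatrix, path) -> None:
    scores.to_frame().to_csv(path, sep="\t")
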