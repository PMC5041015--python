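"""Shared test helpers: tiny pan-genome builders and independent oracles.

Every oracle here is implemented independently of the package code paths it
checks (plain loops and sets, no calls into the functions under test).
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from parasign.io import Gene, Genome

BLOSUM62_OPEN = -11.0
BLOSUM62_EXTEND = -1.0


def make_contig(
    genome_id: str,
    families: Sequence[Optional[str]],
    contig_id: str = "c1",
    proteins: Optional[Sequence[Optional[str]]] = None,
    start_index: int = 0,
) -> List[Gene]:
    """A run of adjacent genes with the given family labels."""
    genes = []
    for i, family in enumerate(families):
        idx = start_index + i
        genes.append(
            Gene(
                gene_id=f"{genome_id}_g{idx:03d}",
                genome_id=genome_id,
                contig_id=contig_id,
                start=10 + idx * 100,
                end=60 + idx * 100,
                strand="+",
                protein=proteins[i] if proteins else None,
                family_id=family,
            )
        )
    return genes


def make_genome(genome_id: str, families: Sequence[Optional[str]], **kw) -> Genome:
    return Genome.from_genes(genome_id, make_contig(genome_id, families, **kw))


def jaccard_oracle(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def components_oracle(nodes: Sequence[str], edges: Sequence[Tuple[str, str]]):
    """Exhaustive connected components by repeated closure (no graph library)."""
    adj: Dict[str, set] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    comps: List[Tuple[str, ...]] = []
    for n in sorted(nodes):
        if n in seen:
            continue
        comp = {n}
        frontier = {n}
        while frontier:
            nxt = set()
            for u in frontier:
                nxt |= adj[u] - comp
            comp |= nxt
            frontier = nxt
        seen |= comp
        comps.append(tuple(sorted(comp)))
    return sorted(comps)


def _blosum62() -> Dict[Tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    table: Dict[Tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def smith_waterman_oracle(x: str, y: str) -> float:
    """Independent Gotoh dynamic program for the optimal local alignment score
    (BLOSUM62, first gap residue -11, each further residue -1)."""
    sub = _blosum62()
    n, m = len(x), len(y)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = prev + sub[(x[i - 1], y[j - 1])]
            Ix[i, j] = max(
                M[i - 1, j] + BLOSUM62_OPEN, Ix[i - 1, j] + BLOSUM62_EXTEND
            )
            Iy[i, j] = max(
                M[i, j - 1] + BLOSUM62_OPEN, Iy[i, j - 1] + BLOSUM62_EXTEND
            )
            best = max(best, M[i, j])
    return best


def welch_oracle(xa: Sequence[float], xb: Sequence[float], eps: float = 1e-9) -> float:
    """Closed-form Welch t statistic on indicator vectors with the epsilon
    pooled-variance rule."""
    xa = list(xa)
    xb = list(xb)
    na, nb = len(xa), len(xb)
    ma = sum(xa) / na
    mb = sum(xb) / nb
    va = sum((v - ma) ** 2 for v in xa) / (na - 1)
    vb = sum((v - mb) ** 2 for v in xb) / (nb - 1)
    return (ma - mb) / ((va / na + vb / nb + eps) ** 0.5)


def pssm_oracle(protein: str, freqs: Mapping[str, Sequence[float]], width: int,
                pseudocount: float = 0.5 / 20,
                background: float = 1.0 / 20) -> Tuple[float, int]:
    """Exhaustive best-window log-odds enumeration."""
    import math

    best = -1e18
    best_pos = 0
    for start in range(len(protein) - width + 1):
        s = 0.0
        for j in range(width):
            c = protein[start + j]
            f = freqs[c][j] if c in freqs else 0.0
            s += math.log2((f + pseudocount) / background)
        if s > best + 1e-12:
            best = s
            best_pos = start
    return best, best_pos
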