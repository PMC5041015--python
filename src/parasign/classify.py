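"""Propagate subgroup annotations by signature-motif matching.

Context evidence (membership in a neighbourhood-derived subgroup) always
takes precedence; signature motifs extend annotations to family members that
lack conserved context.  Matching is literal/wildcard pattern scanning —
signatures are short patterns such as CxxxHGH where 'x' matches any residue —
with an optional position-specific scoring backstop reported as supplementary
evidence only.  A sequence matching the signatures of two subgroups is called
a hybrid, not an error: bifunctional hybrids genuinely occur (e.g. a CExxHGH
sequence satisfying both the CxxxHGH and ExxHGH patterns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .io import AA20, Gene
from .motif import WILDCARD, MotifSignature, PositionFrequencyMatrix
from .neighborhood import SubgroupPartition

PSEUDOCOUNT = 0.5 / 20

EVIDENCE_LEVELS = ("context", "motif", "context+motif", "hybrid", "ambiguous", "none")
CONFIDENCE_LEVELS = ("high", "medium", "low")
UNRESOLVED = "unresolved"

SHORT_SEQUENCE_NOTE = "short, possible wrong start call"


@dataclass(frozen=True)
class AnnotationCall:
    gene_id: str
    genome_id: str
    family_id: str
    subgroup: str
    evidence: str
    matched_patterns: Tuple[str, ...] = ()
    pssm_score: Optional[float] = None
    confidence: str = "low"
    note: str = ""

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence level {self.evidence!r}")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence {self.confidence!r}")
        if self.evidence == "hybrid" and len(self.matched_patterns) < 2:
            raise ValueError("hybrid calls require at least two matched patterns")
        if self.evidence == "none" and self.subgroup != UNRESOLVED:
            raise ValueError("no-evidence calls must be unresolved")


def _validate_pattern(pattern: str) -> None:
    if not pattern:
        raise ValueError("empty pattern")
    bad = set(pattern) - set(AA20) - {WILDCARD}
    if bad:
        raise ValueError(
            f"invalid pattern characters {sorted(bad)} in {pattern!r}; "
            f"expected residues {AA20} or wildcard '{WILDCARD}'"
        )


def match_motif(protein: str, signature: MotifSignature | str) -> List[int]:
    """All start offsets where the pattern matches, wildcards matching any
    residue; overlapping matches are reported."""
    pattern = signature.pattern if isinstance(signature, MotifSignature) else signature
    _validate_pattern(pattern)
    w = len(pattern)
    hits: List[int] = []
    for start in range(len(protein) - w + 1):
        ok = True
        for pc, sc in zip(pattern, protein[start : start + w]):
            if pc != WILDCARD and pc != sc:
                ok = False
                break
        if ok:
            hits.append(start)
    return hits


def score_pssm(
    protein: str,
    pfm: PositionFrequencyMatrix,
    background: Optional[Mapping[str, float]] = None,
) -> Tuple[float, int]:
    """Best-window log-odds score (bits) and its position.

    Score of a window is the sum over positions of
    ``log2((freq + pseudocount) / background)`` with pseudocount 0.5/20 per
    cell and a uniform background by default.  Residues absent from the PFM
    alphabet (X) score on the pseudocount alone.
    """
    w = pfm.width
    if len(protein) < w:
        raise ValueError(
            f"protein length {len(protein)} shorter than PSSM width {w}"
        )
    freqs = pfm.frequencies.loc[list(AA20)]
    if background is None:
        background = {a: 1.0 / len(AA20) for a in AA20}
    lods: Dict[str, List[float]] = {}
    for a in AA20:
        lods[a] = [
            math.log2((float(freqs.loc[a, j]) + PSEUDOCOUNT) / background[a])
            for j in range(w)
        ]
    unknown = [
        math.log2(PSEUDOCOUNT / (1.0 / len(AA20))) for _ in range(w)
    ]
    best_score = -math.inf
    best_pos = 0
    for start in range(len(protein) - w + 1):
        s = 0.0
        for j in range(w):
            c = protein[start + j]
            s += lods[c][j] if c in lods else unknown[j]
        if s > best_score + 1e-12:
            best_score = s
            best_pos = start
    return best_score, best_pos


def classify_gene(
    gene: Gene,
    signatures: Mapping[str, MotifSignature],
    partition: SubgroupPartition,
    use_pssm: bool = False,
) -> AnnotationCall:
    """Classify one family member.

    Precedence: (1) context subgroup membership wins (with ``context+motif``
    evidence when the member also matches its own subgroup's signature);
    (2) exactly one signature matches → that subgroup by motif; (3) two or
    more match → hybrid listing all patterns; (4) none → unresolved.
    """
    if not signatures:
        raise ValueError("signatures must be non-empty")
    family_id = gene.family_id or ""
    protein = gene.protein
    matched = []
    if protein is not None:
        for label in sorted(signatures):
            if match_motif(protein, signatures[label]):
                matched.append(label)
    context_label = partition.label_of(gene.gene_id)
    pssm_score = None
    if use_pssm and protein is not None:
        scored = [
            score_pssm(protein, signatures[l].pfm)[0]
            for l in sorted(signatures)
            if signatures[l].pfm is not None
            and len(protein) >= signatures[l].pfm.width
        ]
        pssm_score = max(scored) if scored else None

    if context_label is not None:
        own_matches = (
            context_label in signatures and context_label in matched
        )
        return AnnotationCall(
            gene_id=gene.gene_id,
            genome_id=gene.genome_id,
            family_id=family_id,
            subgroup=context_label,
            evidence="context+motif" if own_matches else "context",
            matched_patterns=(
                (signatures[context_label].pattern,) if own_matches else ()
            ),
            pssm_score=pssm_score,
            confidence="high",
        )
    if len(matched) == 1:
        label = matched[0]
        return AnnotationCall(
            gene_id=gene.gene_id,
            genome_id=gene.genome_id,
            family_id=family_id,
            subgroup=label,
            evidence="motif",
            matched_patterns=(signatures[label].pattern,),
            pssm_score=pssm_score,
            confidence="medium",
        )
    if len(matched) >= 2:
        return AnnotationCall(
            gene_id=gene.gene_id,
            genome_id=gene.genome_id,
            family_id=family_id,
            subgroup="+".join(matched),
            evidence="hybrid",
            matched_patterns=tuple(signatures[l].pattern for l in matched),
            pssm_score=pssm_score,
            confidence="medium",
        )
    note = ""
    if protein is None:
        note = "no protein sequence"
    elif len(protein) < min(len(s.pattern) for s in signatures.values()):
        note = SHORT_SEQUENCE_NOTE
    return AnnotationCall(
        gene_id=gene.gene_id,
        genome_id=gene.genome_id,
        family_id=family_id,
        subgroup=UNRESOLVED,
        evidence="none",
        matched_patterns=(),
        pssm_score=pssm_score,
        confidence="low",
        note=note,
    )


def annotate_family(
    members: Sequence[Gene],
    partition: SubgroupPartition,
    signatures: Mapping[str, MotifSignature],
    use_pssm: bool = False,
) -> List[AnnotationCall]:
    """One call per family member, ordered by (genome_id, gene_id).

    With an empty signature set, context-placed members keep their context
    call and everything else is unresolved.
    """
    calls: List[AnnotationCall] = []
    for gene in sorted(members, key=lambda g: (g.genome_id, g.gene_id)):
        if signatures:
            calls.append(classify_gene(gene, signatures, partition, use_pssm))
            continue
        context_label = partition.label_of(gene.gene_id)
        if context_label is not None:
            calls.append(
                AnnotationCall(
                    gene_id=gene.gene_id,
                    genome_id=gene.genome_id,
                    family_id=gene.family_id or "",
                    subgroup=context_label,
                    evidence="context",
                    confidence="high",
                )
            )
        else:
            calls.append(
                AnnotationCall(
                    gene_id=gene.gene_id,
                    genome_id=gene.genome_id,
                    family_id=gene.family_id or "",
                    subgroup=UNRESOLVED,
                    evidence="none",
                    confidence="low",
                )
            )
    return calls


def write_signatures(
    signatures: Mapping[str, MotifSignature], path: Path
) -> Path:
    rows = [
        {
            "subgroup": label,
            "pattern": signatures[label].pattern,
            "window_start": signatures[label].window[0],
            "window_stop": signatures[label].window[1],
        }
        for label in sorted(signatures)
    ]
    pd.DataFrame(
        rows, columns=["subgroup", "pattern", "window_start", "window_stop"]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_signatures(path: Path) -> Dict[str, MotifSignature]:
    df = pd.read_csv(path, sep="\t", dtype={"subgroup": str, "pattern": str})
    out: Dict[str, MotifSignature] = {}
    for _, row in df.iterrows():
        out[row["subgroup"]] = MotifSignature(
            label=row["subgroup"],
            pattern=row["pattern"],
            window=(int(row["window_start"]), int(row["window_stop"])),
        )
    return out
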