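"""Signature-motif derivation from context-defined subgroups.

For each provisional isofunctional subgroup: align the member proteins,
locate the most conserved window, build a position frequency matrix with
per-column information content, collapse it to a consensus pattern over the
20 residues plus the wildcard 'x', and contrast subgroups with a per-position,
per-residue two-sample t-test (the "two-sample logo" statistic).

Information content per column is ``log2(20) - H`` where ``H`` is the Shannon
entropy of the non-gap residue frequencies, i.e. the height of the column in
a standard sequence logo.  Consensus positions become literals when a single
residue reaches the conservation threshold (default 0.9, tolerating rare
mistranslated or wrongly-started members); everything else is the wildcard.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy import stats

from .io import AA20

GAP = "-"
WILDCARD = "x"

#: Added to the pooled variance of the two-sample t statistic so that
#: perfectly conserved columns (zero variance in both groups) yield a large
#: finite t instead of an undefined one.
EPSILON_VARIANCE = 1e-9

DEFAULT_WINDOW_WIDTH = 16
DEFAULT_CONSERVATION = 0.9


@dataclass(frozen=True)
class AlignedBlock:
    """A multiple alignment of one subgroup (rows of equal length)."""

    label: str
    ids: Tuple[str, ...]
    rows: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an aligned block needs at least two rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("aligned rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def slice(self, window: Tuple[int, int]) -> "AlignedBlock":
        start, stop = window
        return AlignedBlock(
            label=self.label,
            ids=self.ids,
            rows=tuple(row[start:stop] for row in self.rows),
        )


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Counts, frequencies and information content over a column window."""

    counts: pd.DataFrame  # rows: AA20 + '-', columns: 0..w-1
    n_rows: int
    window: Tuple[int, int]
    information: np.ndarray  # bits, one per column
    all_gap_columns: Tuple[int, ...]

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n_rows

    def nongap_frequencies(self) -> pd.DataFrame:
        """Per-column residue frequencies renormalised over non-gap rows;
        all-gap columns fall back to uniform."""
        res = self.counts.loc[list(AA20)].astype(float)
        totals = res.sum(axis=0)
        out = res.copy()
        for j, total in enumerate(totals):
            if total == 0:
                out.iloc[:, j] = 1.0 / len(AA20)
            else:
                out.iloc[:, j] = res.iloc[:, j] / total
        return out


@dataclass(frozen=True)
class MotifSignature:
    """A consensus pattern over {residues, wildcard 'x'} for one subgroup."""

    label: str
    pattern: str
    window: Tuple[int, int]  # columns of the source block after trimming
    pfm: Optional[PositionFrequencyMatrix] = None

    def __post_init__(self) -> None:
        if not any(c != WILDCARD for c in self.pattern):
            raise ValueError("signature must contain at least one literal")


@dataclass(frozen=True)
class TwoSampleLogoResult:
    """Per (column, residue) enrichment statistics between two blocks."""

    table: pd.DataFrame
    alpha: float
    correction: Optional[str]
    n_tests: int

    def significant_cells(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


def _global_aligner() -> Align.PairwiseAligner:
    # Stiffer gap opening than the local-scoring convention: progressive
    # merging amplifies every spurious pairwise gap into a full MSA column,
    # so the center-star trades a little sensitivity for column stability.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -20.0
    aligner.extend_gap_score = -1.0
    return aligner


def _merge_into_master(
    master_center: str,
    rows: List[str],
    center_aln: str,
    seq_aln: str,
) -> Tuple[str, List[str], str]:
    """Merge one pairwise (center, sequence) alignment into the master MSA."""
    new_master: List[str] = []
    new_rows: List[List[str]] = [[] for _ in rows]
    new_seq: List[str] = []
    i = j = 0
    while i < len(master_center) or j < len(center_aln):
        mi = master_center[i] if i < len(master_center) else None
        cj = center_aln[j] if j < len(center_aln) else None
        if mi == GAP:
            # column inserted by an earlier merge: the new sequence gaps it
            new_master.append(GAP)
            for r, row in enumerate(rows):
                new_rows[r].append(row[i])
            new_seq.append(GAP)
            i += 1
        elif cj == GAP:
            # the new pairwise alignment inserts into the center
            new_master.append(GAP)
            for r in range(len(rows)):
                new_rows[r].append(GAP)
            new_seq.append(seq_aln[j])
            j += 1
        elif mi is not None and cj is not None:
            new_master.append(mi)
            for r, row in enumerate(rows):
                new_rows[r].append(row[i])
            new_seq.append(seq_aln[j])
            i += 1
            j += 1
        else:  # pragma: no cover - lengths disagree only on internal error
            raise RuntimeError("center-star merge walked off both alignments")
    return (
        "".join(new_master),
        ["".join(r) for r in new_rows],
        "".join(new_seq),
    )


def _center_star(ids: Sequence[str], seqs: Sequence[str]) -> List[str]:
    """Deterministic center-star progressive alignment.

    The center is the sequence with the greatest summed global alignment
    score against all others (ties broken by input order); every other
    sequence is aligned to the center pairwise and the alignments are merged
    on center coordinates.
    """
    aligner = _global_aligner()
    n = len(seqs)
    if n == 2:
        aln = aligner.align(seqs[0], seqs[1])[0]
        return [str(aln[0]), str(aln[1])]
    sums = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i], seqs[j])
            sums[i] += s
            sums[j] += s
    center = int(np.argmax(sums))
    master_center = seqs[center]
    aligned: Dict[int, str] = {}
    rows: List[str] = []
    order: List[int] = []
    for idx in range(n):
        if idx == center:
            continue
        aln = aligner.align(master_center.replace(GAP, ""), seqs[idx])[0]
        master_center, rows, new_row = _merge_into_master(
            master_center, rows, str(aln[0]), str(aln[1])
        )
        rows.append(new_row)
        order.append(idx)
    aligned[center] = master_center
    for pos, idx in enumerate(order):
        aligned[idx] = rows[pos]
    return [aligned[i] for i in range(n)]


def _mafft(ids: Sequence[str], seqs: Sequence[str]) -> List[str]:
    mafft = shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for name, seq in zip(ids, seqs):
                fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            [mafft, "--auto", "--quiet", "--anysymbol", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
        out = Path(tmp) / "out.fasta"
        out.write_text(proc.stdout)
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(out), "fasta")}
    return [records[name] for name in ids]


def align_subgroup(
    proteins: Mapping[str, str],
    label: str = "",
    method: str = "center_star",
) -> AlignedBlock:
    """Multiple alignment of one subgroup's proteins.

    ``method`` is ``center_star`` (built-in, deterministic), ``mafft``
    (external aligner) or ``auto`` (mafft when available, else center-star).
    Row order follows sorted sequence identifiers.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two sequences to align")
    ids = tuple(sorted(proteins))
    seqs = [proteins[i] for i in ids]
    if method == "auto":
        method = "mafft" if shutil.which("mafft") else "center_star"
    if method == "center_star":
        rows = _center_star(ids, seqs)
    elif method == "mafft":
        rows = _mafft(ids, seqs)
    else:
        raise ValueError(f"unknown alignment method {method!r}")
    return AlignedBlock(label=label, ids=ids, rows=tuple(rows))


def column_information(
    block: AlignedBlock, small_sample_correction: bool = False
) -> np.ndarray:
    """Per-column information content in bits over the whole block."""
    pfm = build_pfm(
        block,
        window=(0, block.n_columns),
        small_sample_correction=small_sample_correction,
    )
    return pfm.information


def build_pfm(
    block: AlignedBlock,
    window: Optional[Tuple[int, int]] = None,
    small_sample_correction: bool = False,
) -> PositionFrequencyMatrix:
    """Counts + frequencies + information content over a column window.

    IC = log2(20) - H(non-gap frequencies); all-gap columns get IC 0 and are
    flagged.  The optional small-sample correction subtracts the plug-in
    entropy bias (19 / (2 n ln 2)) from each column, floored at zero.
    """
    if window is None:
        window = (0, block.n_columns)
    start, stop = window
    if not (0 <= start < stop <= block.n_columns):
        raise ValueError(f"window {window} outside block columns")
    alphabet = list(AA20) + [GAP]
    width = stop - start
    counts = np.zeros((len(alphabet), width), dtype=int)
    index = {c: r for r, c in enumerate(alphabet)}
    for row in block.rows:
        for j in range(start, stop):
            c = row[j]
            counts[index.get(c, index[GAP]), j - start] += 1
    counts_df = pd.DataFrame(counts, index=alphabet, columns=range(width))
    info = np.zeros(width)
    all_gap: List[int] = []
    max_ic = math.log2(len(AA20))
    for j in range(width):
        res_counts = counts[: len(AA20), j]
        total = res_counts.sum()
        if total == 0:
            all_gap.append(start + j)
            info[j] = 0.0
            continue
        freqs = res_counts[res_counts > 0] / total
        entropy = float(-(freqs * np.log2(freqs)).sum())
        ic = max_ic - entropy
        if small_sample_correction:
            ic -= (len(AA20) - 1) / (2 * total * math.log(2))
        # scale by the non-gap fraction so sparse, mostly-gap columns do not
        # masquerade as conserved (column height convention of sequence logos)
        info[j] = max(ic, 0.0) * (total / block.n_rows)
    return PositionFrequencyMatrix(
        counts=counts_df,
        n_rows=block.n_rows,
        window=(start, stop),
        information=info,
        all_gap_columns=tuple(all_gap),
    )


def select_motif_window(
    block: AlignedBlock, width: int = DEFAULT_WINDOW_WIDTH
) -> Tuple[int, int]:
    """The contiguous ``width``-column range maximising summed information
    content; ties broken by the leftmost range."""
    if width > block.n_columns:
        raise ValueError(
            f"window width {width} exceeds block columns {block.n_columns}"
        )
    info = column_information(block)
    best_start = 0
    best_sum = -math.inf
    current = float(info[:width].sum())
    best_sum = current
    for start in range(1, block.n_columns - width + 1):
        current += float(info[start + width - 1] - info[start - 1])
        if current > best_sum + 1e-12:
            best_sum = current
            best_start = start
    return (best_start, best_start + width)


def derive_consensus_motif(
    pfm: PositionFrequencyMatrix,
    conservation_threshold: float = DEFAULT_CONSERVATION,
    label: str = "",
) -> MotifSignature:
    """Collapse a PFM to a literal/wildcard pattern.

    A position becomes a literal when one residue's frequency (over all rows,
    gaps included in the denominator) reaches the threshold; leading and
    trailing wildcards are trimmed and the trimmed window recorded.
    """
    if not (0.5 < conservation_threshold <= 1.0):
        raise ValueError("conservation threshold must be in (0.5, 1]")
    freqs = pfm.frequencies.loc[list(AA20)]
    pattern_chars: List[str] = []
    for j in range(pfm.width):
        col = freqs.iloc[:, j]
        best = col.idxmax()
        if col[best] >= conservation_threshold - 1e-12:
            pattern_chars.append(str(best))
        else:
            pattern_chars.append(WILDCARD)
    pattern = "".join(pattern_chars)
    stripped = pattern.strip(WILDCARD)
    if not stripped:
        raise ValueError("no signature: all positions below the threshold")
    lead = len(pattern) - len(pattern.lstrip(WILDCARD))
    start = pfm.window[0] + lead
    return MotifSignature(
        label=label,
        pattern=stripped,
        window=(start, start + len(stripped)),
        pfm=pfm,
    )


def _welch(xa: np.ndarray, xb: np.ndarray) -> Tuple[float, float]:
    na, nb = len(xa), len(xb)
    ma, mb = float(xa.mean()), float(xb.mean())
    va = float(xa.var(ddof=1))
    vb = float(xb.var(ddof=1))
    sa, sb = va / na, vb / nb
    denom = sa + sb + EPSILON_VARIANCE
    t = (ma - mb) / math.sqrt(denom)
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
    else:
        df = (sa + sb) ** 2 / (
            (sa**2 / (na - 1) if na > 1 else 0.0)
            + (sb**2 / (nb - 1) if nb > 1 else 0.0)
        )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, min(p, 1.0)


def two_sample_logo(
    block_a: AlignedBlock,
    block_b: AlignedBlock,
    alpha: float = 0.05,
    correction: Optional[str] = None,
) -> TwoSampleLogoResult:
    """Per-column, per-residue Welch t-test between two aligned groups.

    For each column and residue, the per-sequence presence indicator (0/1) is
    compared between groups.  ``correction`` is ``None`` (default, matching
    the t-test mode of the classic two-sample logo tool) or ``"bonferroni"``
    over columns × residues.
    """
    if block_a.n_columns != block_b.n_columns:
        raise ValueError("blocks must share the same window width")
    if block_a.n_rows < 2 or block_b.n_rows < 2:
        raise ValueError("each group needs at least two sequences")
    if correction not in (None, "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    n_tests = block_a.n_columns * len(AA20)
    rows = []
    for j in range(block_a.n_columns):
        col_a = block_a.column(j)
        col_b = block_b.column(j)
        for residue in AA20:
            xa = np.array([1.0 if c == residue else 0.0 for c in col_a])
            xb = np.array([1.0 if c == residue else 0.0 for c in col_b])
            fa, fb = float(xa.mean()), float(xb.mean())
            t, p = _welch(xa, xb)
            p_adj = min(p * n_tests, 1.0) if correction == "bonferroni" else p
            if fa > fb:
                direction = "enriched"
            elif fa < fb:
                direction = "depleted"
            else:
                direction = "none"
            rows.append(
                {
                    "column": j,
                    "residue": residue,
                    "freq_a": fa,
                    "freq_b": fb,
                    "t": t,
                    "p": p,
                    "p_adjusted": p_adj,
                    "direction": direction,
                    "significant": bool(p_adj < alpha and direction != "none"),
                }
            )
    return TwoSampleLogoResult(
        table=pd.DataFrame(rows),
        alpha=alpha,
        correction=correction,
        n_tests=n_tests,
    )


def write_meme(
    pfms: Mapping[str, PositionFrequencyMatrix], path: Path
) -> Path:
    """Write PFMs in MEME minimal motif format (non-gap frequencies)."""
    uniform = 1.0 / len(AA20)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write(f"ALPHABET= {AA20}\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{a} {uniform:.5f}" for a in AA20) + "\n\n"
        )
        for name in sorted(pfms):
            pfm = pfms[name]
            freqs = pfm.nongap_frequencies()
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= {len(AA20)} "
                f"w= {pfm.width} nsites= {pfm.n_rows} E= 0\n"
            )
            for j in range(pfm.width):
                fh.write(
                    " ".join(f"{freqs.iloc[r, j]:.6f}" for r in range(len(AA20)))
                    + "\n"
                )
            fh.write("\n")
    return Path(path)


def write_information_tsv(
    pfms: Mapping[str, PositionFrequencyMatrix], path: Path
) -> Path:
    rows = []
    for name in sorted(pfms):
        pfm = pfms[name]
        for j in range(pfm.width):
            rows.append(
                {
                    "subgroup": name,
                    "column": pfm.window[0] + j,
                    "information_bits": pfm.information[j],
                }
            )
    pd.DataFrame(rows, columns=["subgroup", "column", "information_bits"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)
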