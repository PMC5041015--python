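# Methods

## The problem

Multigene families frequently contain paralogs — genes descended from a
duplication — and paralogs need not share a function: a handful of
substitutions can redirect an enzyme to a different substrate or pathway.
Annotation transfer by sequence similarity therefore over-annotates such
families, and the error propagates to every newly sequenced genome.  The
6-pyruvoyl-tetrahydropterin synthase fold family (COG0720) is the canonical
example: its PTPS-I, PTPS-II and PTPS-III subfamilies act in the queuosine,
biopterin and folate pathways respectively, are distinguished by short
signature motifs (CxxxHGH, CxxxxxHGH, ExxHGH), and cannot be separated by
similarity thresholds alone.

`parasign` implements the comparative-genomics workflow that resolves such
families in prokaryotes:

1. **Flag.**  Any genome with ≥ 2 members of a family necessarily encodes
   paralogs; every member of such a family receives an annotation-confidence
   downgrade (`paralog_in_same_genome` takes precedence over
   `family_has_paralogs_elsewhere`).
2. **Partition by context.**  Each member's gene neighbourhood — the family
   labels of up to *k* genes per side on the same contig — is summarised as a
   set.  Members whose neighbourhood Jaccard similarity reaches τ are linked;
   single-linkage connected components with ≥ 2 members from ≥ 2 genomes
   become provisional isofunctional subgroups.  Conserved context across
   distant genomes is the evidence of shared function; everything else is
   left unplaced.
3. **Signature motifs.**  Each subgroup's members are aligned, the
   contiguous window with the greatest summed information content is
   selected, and columns where one residue reaches the conservation
   threshold become literals of a consensus pattern (wildcard `x`
   elsewhere, flanking wildcards trimmed).  A per-column, per-residue Welch
   *t*-test between subgroups (the two-sample-logo statistic) reports the
   discriminating residues.
4. **Propagate.**  Members without context evidence are matched against the
   signature patterns.  Context evidence always overrides motif evidence;
   exactly one motif match propagates that subgroup (medium confidence);
   two or more matches produce an explicit *hybrid* call (bifunctional
   hybrids such as CExxHGH sequences genuinely occur); no match leaves the
   member unresolved, with a "short, possible wrong start call" note when
   the sequence cannot contain any signature.

A sequence-similarity-network (SSN) diagnostic accompanies the workflow: it
computes all-vs-all Smith–Waterman bit scores, sweeps every observed score
as an edge threshold, and reports cluster purity and the number of subgroups
split across clusters.  On families whose between-subgroup similarity
overlaps within-subgroup similarity, no threshold achieves purity 1 with
zero splits — the quantitative form of why similarity alone fails.

## Parameters

| Parameter | Default | Meaning / rationale |
| --- | --- | --- |
| `window_k` | 5 genes/side | Neighbourhood radius; matches common "pinned region" practice in prokaryotic context browsers. |
| `tau` | 0.3 | Jaccard threshold for linking profiles.  Deliberately permissive: single-linkage then merges everything that shares a conserved context core.  No published quantification of "similar neighbourhood" exists, so a τ sweep is always reported alongside the partition. |
| subgroup support | ≥ 2 members, ≥ 2 genomes | Context conserved across multiple species is the evidence; single-genome components stay unplaced. |
| `motif_width` | 16 columns | Width of the conserved window, mirroring the 16-residue region (positions 23–38 of the *E. coli* reference) used in published PTPS logos. |
| `conservation` | 0.9 | Column frequency for a literal.  Tolerates rare miscalled members (mistranslations, wrong start calls, which affect an estimated 15–20 % of database entries for this family). |
| `alpha` | 0.05, uncorrected | Two-sample logo significance, matching the *t*-test mode of the classic tool; Bonferroni over columns × residues available by flag. |
| gap scores | open 11, extend 1 (BLOSUM62) | Local-alignment scoring for the SSN. |
| bit scores | λ = 0.267, K = 0.041 | Standard gapped BLOSUM62(11,1) constants; bits = (λ·S − ln K)/ln 2, clamped at 0.  The classic EFI thresholds 15/25/30 are kept as named presets but are expressed in that tool's units, so only the exhaustive sweep — not any single preset — is interpreted. |

## Numerical choices

- **Information content.**  IC = log₂ 20 − H(non-gap frequencies), scaled by
  the column's non-gap fraction (the column-height convention of sequence
  logos).  Without the scaling, a column containing a single residue and
  otherwise gaps would score the maximal 4.32 bits and attract the window to
  alignment debris.  Gap-free blocks are unaffected.  An optional
  small-sample correction subtracts the plug-in entropy bias 19/(2n ln 2).
- **Window selection.**  Exhaustive scan of all contiguous windows; ties go
  to the leftmost.  All-gap columns carry IC 0 and are flagged.
- **Consensus.**  Literal frequency uses all rows in the denominator (gaps
  count against conservation).  An all-wildcard pattern after trimming is an
  error ("no signature"), not a silent empty result.
- **Welch t with ε.**  Perfectly conserved columns have zero variance in
  both groups; ε = 1e−9 added to the pooled variance keeps the statistic
  finite (≈ 3·10⁴ for a 10-vs-10 fully opposed column).  When both variances
  vanish the Welch–Satterthwaite degrees of freedom are undefined and
  n₁+n₂−2 is used.
- **Built-in aligner.**  The default multiple aligner is a deterministic
  center-star: the sequence with the greatest summed global score is the
  center and pairwise alignments are merged on center coordinates.  Gap
  opening is stiffened to 20 (extension 1) relative to the local-scoring
  convention because progressive merging amplifies every spurious pairwise
  gap into a full MSA column; for the ~25–40 % identity, equal-length
  sequences this package aligns, the stiffer penalty makes the column
  coordinates stable.  `mafft` can be selected (`--aligner mafft`) and gives
  the same conserved columns on the synthetic regime; the built-in default
  keeps results identical on machines without it.
- **PSSM backstop.**  Best-window log-odds with pseudocount 0.5/20 and a
  uniform background, reported as supplementary evidence only — the decision
  rule is the literal/wildcard pattern, because that is what the curated
  signatures are.
- **Context graph at τ = 0.**  An edge requires similarity ≥ τ, so τ = 0
  links every pair including disjoint profiles; the first informative
  threshold is any τ > 0.

## The synthetic study

The generator (`parasign.synth`) emulates the structure the workflow
exploits.  Default conditions: 20 genomes; 3 subgroups planted with the
CxxxHGH / CxxxxxHGH / ExxHGH patterns; 3 context families per subgroup;
window k = 5; protein length 120; neighbour gene loss 0.1; neighbour-order
rearrangement 0.2; per-literal motif mutation 0.02; 30 decoy families at
label density 0.15 among spacer loci; half of the genomes carry members of
≥ 2 subgroups (the workflow's entry point); seed 42.

Member proteins are ungapped copies of a per-subgroup template.  The
template is background-sampled (uniform over the 20 residues); the motif's
literal residues are written at a subgroup-specific offset; wildcard
positions keep their one-off background draw.  Each member then re-samples
every non-literal position with probability 0.55.  Two constraints pin that
divergence value, chosen by analysis before any end-to-end run:

- *Alignability.*  At divergence 0.55 members share ≈ 24 % identity with an
  expected positive per-site BLOSUM62 score, so the gap-free alignment is
  optimal and the motif columns line up.  Much beyond 0.6 the backbone
  signal vanishes and no aligner can recover columns.
- *Window contrast.*  The max-summed-IC window must prefer the full motif
  span over partial windows that drop a leading literal in favour of
  moderately conserved backbone columns.  This requires literal-column IC to
  exceed backbone-column IC by a clear margin, i.e. backbone conservation
  must stay low; divergence 0.55 leaves backbone columns at ≈ 1–2 empirical
  bits against ≈ 4.2 for literals.  For the same reason wildcard positions
  are inherited from the template (diverging like backbone) rather than
  resampled fresh per member: fresh sampling would make the five wildcard
  columns of CxxxxxHGH cheaper to exclude than backbone columns, and the
  selected window would truncate the pattern.

What the generator does **not** emulate: insertions/deletions and length
variation (real subfamilies align with gaps), substitution-rate structure
along a phylogeny, operon strand conventions, compositional bias, and
fusion genes.  Passing the synthetic recovery checks therefore demonstrates
that the workflow's logic is correct under its stated assumptions, not that
it is robust to every property of real genomes — in particular the
alignment and window-selection stages face easier inputs here than in
curated-family practice.

Known sensitivity: with the default noise, a subgroup realised with ≤ 9
members sits on the conservation knife edge — a single mutated literal
yields 8/9 ≈ 0.889 < 0.9 and that literal degrades to a wildcard, so the
recovered pattern loses one position.  With ≥ 10 members a single mutation
survives the threshold.  Partition recovery (adjusted Rand index) is
unaffected; across replicate seeds it is consistently 1.0.

## Evaluation conventions

- **Partition ARI** is computed over context-placed members against the
  planted labels.  Members that lose their entire context to gene-loss noise
  have no context evidence *by construction*; the workflow's answer to them
  is motif propagation, which is scored separately.  A singleton-inclusive
  ARI over the final calls is also reported.
- **Held-out classification.**  A fraction (default 20 %) of members is
  stripped of context; signatures are rebuilt from the rest; held-out
  members are classified by motif alone.  *Precision* is scored over members
  that receive a subgroup call, with a hybrid call counted correct when it
  contains the planted label — an abstention ("unresolved") is the
  family-level fallback a curator would record, not a misannotation.  The
  strict rate (abstentions as failures) and coverage are reported alongside;
  under the default noise the strict rate is bounded near (1−0.02)⁴ ≈ 0.92
  by motif mutation alone.
- **Subgroup naming.**  Recovered labels (SG1, SG2, …, ordered by smallest
  member gene id) are mapped to planted labels by member majority before
  pattern comparison.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
desk scale: 20-genome pan-genomes (≈ 1 400 genes, 26–47 focal members), one
16-sequence family for the SSN overlap diagnostic, and ≤ 6-sequence inputs
for the dynamic-programming cross-checks.  These sizes exercise every code
path while keeping a full run in the low seconds; the all-vs-all scorer is
quadratic and intended for families up to a few thousand members, not for
proteome-wide scans.

## Limitations

- Neighbourhood similarity ignores gene order, strand and intergenic
  distance; operon-aware variants would be stricter.
- Single-linkage components are deterministic and oracle-checkable but can
  chain distinct contexts through intermediate members at permissive τ; the
  τ sweep is the guard.
- Fusion/multi-domain genes are rejected at input rather than handled.
- Signature matching is literal/wildcard only; families whose subgroups
  differ by combinations of weakly conserved positions need the PSSM score
  or profile methods, which are reported here but never decide.
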