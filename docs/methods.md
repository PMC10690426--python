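# Methods

`taxogen` implements a genome-based taxonomic decision pipeline for
prokaryotes: from assemblies and predicted proteomes it builds a pangenome
by Markov clustering, derives a trimmed core-genome supermatrix, computes
overall genome relatedness indexes (OGRIs), detects clade-specific signature
genes, evaluates genus-level clade proposals, and calls heterotypic
synonyms.  This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic data generator does and does
not emulate.

## Pangenome inference

All-vs-all protein similarity is computed by exhaustive pairwise
Smith–Waterman local alignment (BLOSUM62, affine gaps open 11 / extend 1,
via biotite's C implementation) behind a shared-k-mer prefilter (two shared
4-mers): pairs with no shared k-mers are never aligned, which removes the
vast majority of unrelated comparisons without affecting edges near the
identity floor.  An edge is kept when the local alignment reaches the
identity floor (default **40%**, percent identical columns over alignment
columns) and covers at least **50%** of the shorter sequence.  The coverage
floor is this package's convention — commonly used clustering tools do not
document a single canonical value — and is exposed as a flag.

Markov clustering runs on the column-stochastic identity matrix with
self-loops equal to each node's largest incident weight (1 for isolated
genes).  Expansion is matrix squaring; inflation (default **5**, the
granularity dial) is entrywise power followed by column renormalisation;
entries below 1e−6 are pruned; iteration stops when the largest entry change
falls below 1e−8, with an error after 200 iterations.  Clusters are read off
the converged matrix's nonzero structure; isolated genes become singleton
families.  Edge weight is percent identity, not bitscore — identity is the
quantity the thresholds above are defined on.

The `core90` set contains families present in at least
`ceil(0.9 × n_genomes)` genomes with copy number ≤ 1 in every genome
(absence allowed, duplication not).

## Core-family alignment and trimming

Each core family is aligned with a progressive guide-tree multiple aligner
(biotite `align_multiple`; any callable with the same contract can be
substituted, e.g. a MAFFT wrapper).  Trimming is per family, before
concatenation, in two stages:

1. columns with strictly more than 50% gaps are removed;
2. of the survivors, exactly `floor(0.2 × n_surviving)` columns with the
   lowest chi-squared conservation score are removed.

The chi-squared score compares a column's residue counts (gaps excluded)
with expected counts under the alignment-wide residue frequencies.  A column
dominated by one residue deviates strongly from the mixed background and
scores high; "least conserved" therefore means lowest score.  Ties at the
cut are broken by column index, left to right; residues absent from the
background contribute nothing (their expected count is zero).  Note the
score is background-relative: in degenerate alignments whose background is
itself concentrated, a conserved column of a *rare* residue outranks a
conserved column of the dominant one, which is the intended behaviour.

Concatenation fills genomes missing from a family with all-gap blocks and
records a 1-based inclusive partition map.

## Overall genome relatedness indexes

**ANIb** — the query assembly is cut into consecutive fragments (default
**1,020 bp**, final short fragment kept).  Each fragment is aligned to the
subject by seed-and-extend: exact 12-mer seeds on both strands are binned by
diagonal, windows with ≥ 2 co-diagonal seeds are aligned with edlib's
bit-vector aligner, and the highest-scoring contiguous run of the alignment
path is kept (column scores +1 match, −2 mismatch, −2.5 gap; the breakeven
identity of 2/3 sits above the ~55–60% an optimal edit-distance alignment
reaches on random DNA, so non-homologous stretches are clipped).  Fragments
below **30%** identity or **70%** fragment coverage are discarded; ANI is
the mean identity of retained fragments, directional by construction, and
explicitly missing (never 0) when nothing is retained.  The 30/70 retention
floors follow the fragment-ANI literature convention; the fragment size is
the method's defining parameter.

**AAI** — reciprocal-best-hit protein pairs (same aligner as the pangenome
stage) with coverage ≥ 0.7 of the shorter sequence; the value is the mean
percent identity over reciprocal pairs.

**cAAI** — the same statistic restricted to shared core families, one best
cross-genome pair per family.  Because core families are vertically
inherited, cAAI is less sensitive to horizontally acquired accessory genes;
on data where accessory divergence exceeds core divergence, cAAI ≥ AAI.

**dDDH (formula 2)** — the fragment HSPs (runs of ≥ 50 columns) are pooled
and the distance is `d = 1 − Σ identities / Σ HSP lengths`.  The mapping
from d to a dDDH percentage is configuration, not part of the distance: the
default transform is `100 × (1 − d)^10.5`, a strictly decreasing curve that
is exactly 100 at d = 0 and places the 70% species boundary near d ≈ 0.033
(~96.7% summed identity), consistent with published ANI–dDDH
correspondences.  The raw distance is always reported alongside the
transformed value so downstream analyses (and tests) can target the
distance itself.

All-vs-all matrices store ANI in both directions, AAI/cAAI once per
unordered pair, and dDDH once per pair mirrored (treated as symmetric).  A
cache keyed by (index, pair, parameters) makes reruns resume without new
alignments.

## Signature genes and phylogroups

A signature family of a clade is present (copy ≥ 1) in **all** clade members
and absent from **all** other genomes in the matrix — presence, not
single-copy presence, is the criterion.  Pattern tables group families by
identical presence vectors, drop the two trivial patterns (all-present =
core; single-genome = singleton), and sort by descending family count with
lexicographic tie-break, ready for UpSet-style display.

Phylogroup assignment: each genome joins the phylogroup of the
representative species with which it shares the most recent common
ancestor.  "Most recent" is measured by MRCA node depth in edges from the
root — robust to branch-length scale.  Depth ties raise an error naming the
leaf; silent tie-breaking would hide a genuinely ambiguous placement.
Outgroup genomes are excluded from clades via an explicit list but stay in
presence vectors.

## Clade evaluation and proposal ranking

**RED** (relative evolutionary divergence) normalises node depth to [0, 1]:
root 0, leaves 1, and for an internal node
`RED = p + (d/u)(1 − p)` with `p` the parent's RED, `d` the branch to the
parent and `u` the mean branch-length distance from the parent to the
node's descendant leaves.  RED is invariant under uniform branch scaling and
non-decreasing along every root-to-leaf path.  The genus RED interval is
configuration (default: median clade RED ± 0.1).

Per clade, the evaluator reports monophyly, the MRCA's bootstrap support,
RED against the interval, and for each OGRI the intra-clade and inter-clade
pair distributions summarised as `min_intra`, `max_inter` and
`overlap_count` (inter pairs reaching the clade's minimum intra value).  A
well-delimited genus shows zero overlap.  Directional matrices contribute
the mean of both directions per pair; missing values are skipped, never
zero; single-member clades have undefined intra statistics.

**Synonym rule** — two genomes are conspecific when *both* directional ANI
values are ≥ 96% and dDDH is ≥ 70%.  Synonym sets are connected components
(size ≥ 2) of the passing-pair graph, so pairwise evidence chains into
larger sets — the semantics required for a three-species set supported only
by pairwise values.  Pairs with missing values are skipped with a warning.

**Proposal ranking** is deterministic: proposals failing a hard constraint
(non-monophyletic clade, support below the floor, RED outside the interval)
sort last; among the rest, fewer multi-species clades without any signature
gene is better, then more clades (keeping signature-rich sub-clades
separate), then more total signature genes.  Equal keys are reported as an
explicit tie with a per-proposal justification trail.

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
planted ground truth for every stage.

* **Tree** — rooted binary; planted clades are monophyletic subtrees hanging
  off a short spine; every internal node carries support 100.  Pendant
  branches are drawn uniform(0.04, 0.05), within-clade internal branches
  uniform(0.01, 0.02), clade stems uniform(0.08, 0.10) and spine branches
  uniform(0.015, 0.03), in units of expected substitutions per site (scaled
  by 1/rate).  These scales were chosen to reproduce the relatedness regime
  of a bacterial family spanning several genera: within-clade AAI ≈ 85–93,
  cross-clade AAI ≈ 63–76, within-clade ANI ≈ 90–94.  Synonym pairs are
  cherries whose two pendant edges each measure
  `synonym_divergence / substitution_rate` (default divergence 0.005),
  giving ANI ≈ 99 — clearly above the 96% species boundary while every
  non-synonym pair stays clearly below it.
* **Gene content** — core families universal single-copy; exactly
  `n_signature_per_clade` exclusive families per clade; accessory families
  present per genome with independent probability `accessory_presence_prob`
  (default 0.3); singletons genome-unique.  Accessory presence vectors are
  rejection-sampled so none collides with a clade indicator (or is empty or
  all-present): without this, accidental clade-exclusive accessory patterns
  would make exact signature recovery impossible by construction, not by
  failure of the detector.
* **Sequences** — per branch, each protein site mutates with probability
  `1 − exp(−rate × length)` to a uniformly chosen different residue (a
  uniform-exchange process; empirical substitution matrices are out of
  scope and the downstream stages only require a monotone divergence
  gradient).  Codons follow the standard genetic code: a mutated site takes
  a uniform codon of the new residue, unmutated sites take synonymous
  switches at the per-codon synonymous rate (default = substitution rate),
  so nucleotide identity decays faster than protein identity, as in real
  genomes.  The mutation log records every (site, ancestral, derived) event
  root-to-leaf and replays exactly.
* **Genome architecture** — each family carries a 100-bp intergenic spacer
  evolving as neutral DNA under the same clock.  Gene order and strand
  evolve along the tree by 1–3-gene block inversions and transpositions at
  `rearrangement_rate` events per unit branch length (default 30): close
  genomes stay syntenic (so fragment ANI has the local collinearity it
  needs), distant genomes drift towards shuffled order (so ANI alignments
  are not trivially end-to-end collinear).
* **Determinism** — every draw flows from the single config seed through
  per-stage `numpy` generators; identical configs give byte-identical
  output files.

**What the generator does not emulate** — indels within genes (alignments
of simulated families are gap-free), horizontal transfer, rate variation
across sites or lineages, GC skew, compositional bias, paralog expansion,
assembly fragmentation or contamination.  Passing tests therefore show that
the decision logic is correct under the assumed regime — clade-structured
divergence with planted signatures and near-identical synonym pairs — not
that the pipeline is robust to artefacts of real draft assemblies.

## Problem sizes and numerical conventions

The default synthetic study conditions are 12 genomes in 3 clades of 4,
12 core + 9 signature + 24 accessory families and 2 singletons per genome
(~25 genes, ~14 kb per genome), one planted synonym pair.  At this scale the
full pipeline (pangenome → supermatrix → four OGRI matrices → signatures →
evaluation → synonyms) runs in well under a minute per seed on one CPU, and
recovery checks are run across 5 seeds.  Degenerate inputs are errors, not
silent results: empty proteomes and assemblies, alignments trimmed to
nothing, zero-length terminal branches under RED, MRCA depth ties,
representatives missing from the tree, overlapping proposal clades, and
genomes absent from every family all raise with a message naming the
offender.
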