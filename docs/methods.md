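# Methods

This note describes the models and procedures implemented in `ribophy`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Problem setting

Deep bacterial phylogenies inferred from concatenated small- and
large-subunit (SSU/LSU, i.e. 16S/23S-like) rRNA genes are attractive because
rRNA is universally conserved and, being under strong structural constraint,
varies far less in GC content than whole genomes do. The residual risk is
*compositional attraction*: unrelated lineages that have converged on
similar (typically AT-rich) base composition can be drawn together by
methods that model a single stationary composition. `ribophy` packages the
standard counter-measures — quantifying the GC bias, recoding characters so
GC information is erased, and stress-testing a topology by perturbing the
dataset and re-summarising bootstrap support — as a reproducible pipeline
over partitioned alignments.

## Data model

A `PartitionedAlignment` holds equal-length residue rows keyed by taxon with
named half-open column partitions (`ssu`, `lsu` for a two-locus
concatenation). Two distinct missing symbols are carried: `-` is an
alignment gap, `?` marks data absent by design (e.g. a taxon with no LSU
sequence gets `?` across the whole LSU partition). Both are treated as
missing states by every downstream consumer; keeping them distinct preserves
the provenance of the missingness.

Length QC keeps SSU sequences with at least 1200 ungapped bases and LSU
sequences with at least 2000 (boundary inclusive, thresholds configurable).
When a species carries several rRNA operon copies, the representative is the
modal residue string; frequency ties resolve to the lexicographically
smallest string so selection is order-independent and idempotent. The
comparison is on exact strings — paralogs that differ only in length count
as distinct variants.

## Character recoding

RY recoding maps A,G→R and C,T→Y; MK recoding maps A,C→M and G,T→K. Either
erases GC-content signal (a G↔A or C↔T exchange is invisible to RY; A↔C and
G↔T to MK) at the cost of halving the state space. RYMK recoding
concatenates the RY- and MK-recoded copies of the same alignment — GC signal
is still erased, but the character count doubles instead. The RY block is
written first; because sites are modelled independently, block order cannot
affect any likelihood or distance computed here. IUPAC ambiguity codes and
`?` map to `?` in both halves (R/Y inputs could be kept meaningfully under
RY but not under MK; uniform treatment keeps the halves consistent). Gaps
stay gaps. Recoding is applied after column filtering.

## Conserved-block filtering

`blocks.select_blocks` re-implements the widely used conserved-block policy
for rRNA alignments with thresholds b1–b5 derived from the sequence count n:
b1 = b2 = ⌊n/2⌋+1 (minimum count of the most frequent residue for a
conserved/flank column), b3 = ⌊n/2⌋ (longest tolerated run of nonconserved
columns inside a block), b4 = 2 (minimum block length), b5 = `half` (columns
with gaps — `-` or `?` — in more than half the rows are excluded outright).
Gap-excluded columns terminate blocks; stretches of more than b3 contiguous
nonconserved columns split blocks; block ends are trimmed back to
flank-or-better columns; blocks shorter than b4 are dropped. With b1 = b2
the conserved/flank distinction collapses, but both thresholds are
implemented so other policies work. The goal is policy fidelity, not
byte-exact replication of any particular Gblocks build (whose outputs also
depend on the upstream aligner); a saturated alignment legitimately filters
to zero columns, returned as a degenerate empty alignment rather than an
error.

## GC-bias analytics

`gc_fraction` is (G+C)/(A+C+G+T) with gaps, `?` and all ambiguity codes
(including S = G/C) excluded from numerator and denominator. The
locus-vs-genome relationship is summarised by ordinary least squares of
rRNA GC on genomic GC; a structurally constrained locus shows a strongly
attenuated slope (the generator's `make_gc_pairs` produces pairs with a
known slope for calibration). Group comparisons use the two-sided Wilcoxon
rank-sum test: the exact null distribution when both samples have ≤ 12
observations and no ties, otherwise the normal approximation with tie and
continuity corrections. Box summaries use type-7 (linear interpolation)
quartiles and Tukey 1.5×IQR whiskers; the quartile convention is stated here
because plotting toolchains differ and the numbers should be reproducible.

## Tree-set analytics

Trees are dendropy objects; bootstrap supports ride on internal-node labels
as percentages (0–100, as printed in the field's tables). Rerooting places
the root on the edge separating a monophyletic outgroup; a non-monophyletic
outgroup roots at the smallest spanning cluster with a warning.

Monophyly support follows the rename/condense recipe: each replicate is
rooted to the outgroup, leaves are renamed to their group labels, maximal
single-label clades are condensed, and a group is monophyletic in that
replicate iff its label then occurs exactly once. The implementation counts
maximal label-pure clades directly, which is equivalent; a separate direct
clade-check oracle is asserted against it in the tests. Robinson–Foulds
distances are unnormalised bipartition symmetric differences;
`rf_within` reports mean ± SD (sample SD, ddof = 1) over all unordered pairs
of a replicate set. Mean node support averages internal-node supports,
excluding the root and the outgroup-incident edge (whose support merely
duplicates the root split); per-tree means are reported, and matrix rows
additionally aggregate across the trees of a dataset cell.

Dataset perturbation operators: clade jackknifing (one subset per named
clade, with or without the mitochondria-like taxa), post-alignment row
pruning (the `mtDel` design: remove rows, keep columns — isolating the
effect of taxon content from the effect of re-filtering), a 16S-only
augmentation (`combo`: taxa lacking the LSU get `?` across that partition),
and taxon trimming. The trimming rule had to be operationalised: within each
maximal clade whose support exceeds the threshold (default 95%) and whose
leaves share one group label, the survivor is the leaf with the longest
terminal branch, ties breaking to the smallest taxon id. This is one
deterministic reading of "thin densely sampled, well-supported clades";
alternatives can be compared against it because the rule is a pure function
of the annotated tree.

## Likelihood engine and topology tests

Per-site log-likelihoods are computed by Felsenstein pruning under a
reversible k-state model (k = 2 or 4) with optional discrete-Gamma rate
mixing (default 4 equal-probability categories using bin means; rates are
normalised to mean 1, as is the rate matrix). The rate matrix is
diagonalised once via the √π similarity transform, so per-branch transition
matrices are cheap and numerically stable; per-node partial scaling guards
against underflow on larger trees. Gap, `?` and ambiguity cells contribute
all-ones partials; an all-missing column has likelihood exactly 1. RYMK
alignments are scored as a two-state problem with R,M sharing one state and
Y,K the other, which makes the RYMK log-likelihood decompose exactly into
the RY half plus the MK half under a shared model.

Desk-scale tree inference is neighbor joining on p, Jukes–Cantor (4-state)
or Cavender–Farris (2-state) distances, with per-pair deletion of missing
sites, saturated distances capped (default 5 substitutions/site, with a
warning), deterministic tie-breaking in the Q criterion and negative branch
lengths clamped to zero. Heavy maximum-likelihood searches are delegated to
an external program through a command-template adapter that writes relaxed
PHYLIP, forwards the bootstrap count and seed verbatim, and fails loudly —
never silently falls back — when the executable is absent.

Topology tests operate on the per-tree × per-site log-likelihood matrix via
RELL (resampling estimated log-likelihoods): site sums are bootstrapped
without re-optimisation, realised as multinomial column weights so each
replicate is one matrix product. KH compares each tree against the
maximum-likelihood tree using centered replicates of the log-likelihood
difference; SH compares against the per-replicate maximum of the centered
sums, which by construction never rejects the best tree. The AU test uses
the multiscale bootstrap: for ten scale factors r from 0.5 to 1.4, the
bootstrap proportion BP_r of the tree being best is estimated
(default 1000 replicates per scale), z(r) = d√r + c/√r is fitted to
Φ⁻¹(1−BP_r) by weighted least squares with the usual binomial-variance
weights, and p = 1 − Φ(d − c). Scales with degenerate BP (0 or 1) are
excluded from the fit; with fewer than three informative scales the KH
p-value is returned with a `kh_fallback` flag, and fully degenerate BP
profiles clamp p to 0 or 1 with a flag. Candidate trees are evaluated with
branch lengths as given; per-alignment branch-length re-optimisation before
testing is a possible extension, not currently performed.

## Synthetic generators

`simulate_alignment` evolves sites independently down a guide tree. The root
sequence is drawn from the root composition; along each branch, sites evolve
under P = exp(Qt) with Q assembled from shared exchangeabilities and that
branch's stationary-frequency target, discrete-Gamma site rates (shape 0.5
by default — rRNA-like heterogeneity), and optional per-clade branch-length
multipliers. Nonstationarity is therefore branch-local equilibrium shift:
a clade drifts toward its own composition at a speed set by its branch
lengths. All generators are bit-reproducible given (profile, seed).

`make_study_fixture` emulates the structure of a two-locus bacterial study:
a crown-like clade at ~54% rRNA GC, a Rickettsiales-like clade at ~50%, a
mitochondria-like clade at ~40% GC riding on branches three times longer,
and an outgroup; SSU/LSU lengths default to 1400/2700 so the fixture passes
length QC by construction, and the true tree is returned for recovery
scoring. `make_treeset` manufactures bootstrap-like replicate sets with a
prescribed clade-monophyly frequency by prune-and-regraft edits, closing the
loop with the monophyly summariser. `make_gc_pairs` produces regression
inputs with known slope and noise.

The compositional-attraction fixture is the headline demonstration: eight
taxa in four cherries on *equally long* stems, with two non-sister cherries
shifted to GC 0.15 against a background of 0.55 and a deliberately short
internal edge (0.03 substitutions/site, 600 sites). Equal stem lengths are
the key control — any systematic tendency of standard-coded inference to
unite the shifted cherries is compositional, not long-branch, attraction.
Under standard coding NJ unites the AT-rich cherries in most seeds; under
RY or RYMK coding the error rate drops to roughly the level expected from
the weak true signal alone. The paired comparison over ≥ 50 seeds is
asserted as a strict inequality.

What the generators do *not* emulate: indels and alignment error (sequences
are simulated pre-aligned), rRNA secondary-structure pairing (sites are
independent), rate variation correlated along the sequence, and database
artefacts such as chimeric contigs. Passing tests therefore demonstrate the
correctness and calibration of the analytics under the stated generative
assumptions, not the real-data conclusions of any particular study.

## Experiment matrix

`pipeline.run_matrix` executes variant × coding × alignment-source ×
distance-model cells: QC → concatenate → block-filter → recode → NJ →
column bootstrap → monophyly/RF/support summaries, each cell in its own
directory, failures isolated per cell. Per-cell seeds are derived from the
base seed and the cell name (CRC32 mixing), so adding or removing cells
never perturbs the others. The master table has one row per
variant × coding, with character counts per alignment source, mean ± SD of
per-tree node supports, and the within-row RF mean ± SD over the cell's
final trees. Default sizes (≈ 20 taxa, 4.1 kb concatenated, 20–1000
bootstrap replicates) were chosen so a full 32-cell matrix is a
minutes-scale computation on one core.

## Known limitations

- The built-in inference engine is distance NJ; likelihoods are used for
  evaluation and testing, not tree search. ML search quality is the
  external program's responsibility.
- The block filter is a policy re-implementation, not a clone of a specific
  Gblocks binary; on real exports the kept-column counts will differ from
  any particular build's.
- The AU implementation follows the standard multiscale-bootstrap recipe
  but is not a drop-in replacement for Consel's numerics (e.g. no
  second-order curvature refinement).
- Exact Wilcoxon p-values are only used for tie-free samples of ≤ 12; tied
  small samples fall back to the corrected normal approximation.
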