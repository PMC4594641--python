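# Methods

## The relative-rate statistic

Each gene family is summarised by its patristic distance matrix: the sum of
branch lengths along the tree path between every pair of leaves, in
expected amino-acid substitutions per site.  The per-gene statistic divides
the focal taxon's mean distance to the other taxa present in that gene by a
grand mean taken, unweighted, over genes of the within-gene mean over all
unordered taxon pairs (pairs involving the focal taxon included).  Genes
missing a taxon contribute the pairs among the taxa they retain; genes
missing the focal taxon are excluded from both numerator and denominator
with a warning.  The statistic is dimensionless and invariant to rescaling
all distances, and equals 1 exactly when the focal taxon's mean distance
matches the grand mean.

Two readings of the denominator were possible (exclude focal pairs; weight
genes by pair counts).  The implemented one — all pairs, unweighted across
genes — is the most literal "average branch length for all seven taxa
across all genes" and is fixed throughout; the alternatives change the
denominator by a few percent but none of the group-level conclusions.

Because the statistic is a ratio of means over the *same* tree set, it is
below 1 for any shallow tip even at equal rates: with the default study
geometry (focal terminal branch 0.1, deep outgroups) the null value is
~0.75, not 1.  Tests of the estimator therefore compare estimates against
the value implied by the true trees rather than against 1.

## Group statistics

One-sample two-sided *t* tests compare each group's mean rate with 1.0
(df = n−1).  Model-usage comparisons are Fisher exact tests computed by
full enumeration of the conditional (multivariate hypergeometric)
distribution with probability-mass ordering; this generalises the classic
2×2 test to 2×k and matches R's `fisher.test` on r×c tables.  Two
tabulations are provided: the 2×k table over distinct full model strings
("JTT+G" ≠ "JTT+G+F"), and a 2×2 table of (number of distinct best-fit
models, remaining genes) per group — the "how many different models did
each group need" comparison.  On the packaged table these give p = 0.7408
and p = 1.000 respectively.  Length adjustment uses OLS (rate on
nucleotides), an ANCOVA `rate ~ group + nucleotides` whose group-term |t|
is invariant to indicator coding (df = n−3), and a one-way ANOVA on the
pooled regression residuals, whose F equals the square of the pooled t for
two groups.  All tests are two-sided at α = 0.05 with no multiplicity
correction.  A note on the packaged dataset: the group-term |t| computed
from the packaged per-gene table is 1.417; the value originally reported
alongside these data (0.621) is not recoverable from the printed table
under any model form we tried, so the packaged-data ANCOVA should be read
from the computed value.

## Ortholog assignment

Transcripts are translated via their longest open reading frame (both
strands, three frames; ATG required, open 3' ends allowed; ties broken
longest → '+' strand → smallest start) and UTRs are discarded by keeping
exactly the ORF translation.  Candidate-to-gene matching uses
Smith–Waterman local alignment with affine gaps (BLOSUM62, gap open 11,
extend 1 — the standard protein-search defaults; a gap of length L costs
11 + L).  E-values are deliberately not computed: hits are ranked by raw
score, and a hit is "uniquely best" when it beats the runner-up by at
least 10% of the top score.  Genes failing the margin, or belonging to
declared multi-gene families, are deferred to tree-based assignment; genes
with no hit above threshold are reported absent, which is biologically
legitimate (several clock genes are missing from particular insect
lineages).  For deferred families the gene tree is rooted on a designated
outgroup clade (unassigned candidates are allowed to nest inside it) and
each candidate is assigned to the reference gene of the smallest enclosing
clade that contains references of only that gene, or reported ambiguous.

## Alignment trimming

Columns are classified by their maximum identical-residue count: below b1
nonconserved, at or above b2 highly conserved, otherwise conserved.  Blocks
are then carved in four ordered steps: stretches of more than b3
contiguous nonconserved columns are rejected; flanks are trimmed until
blocks start and end highly conserved; gapped columns are removed (with
re-splitting); blocks shorter than b4 are dropped.  Defaults follow the
canonical trimming tool: b1 = ⌊n/2⌋+1, b2 = max(b1, ⌊0.85·n⌋), b3 = 8,
b4 = 10, no gaps tolerated.  With 7 sequences these are b1 = 4, b2 = 5.
b2 below b1 is clamped up with a warning.

## Substitution models and likelihood

Empirical exchangeability matrices (JTT, LG, Dayhoff, WAG) ship as
plain-text PAML-format files; the generator Q(i,j) = s(i,j)·π(j) is
normalised to one expected substitution per unit branch length at
equilibrium and exponentiated through the symmetric similarity transform
(eigendecomposition of diag(√π)·Q·diag(1/√π)), with round-off clamped and
rows renormalised.  Rate heterogeneity uses the k = 4 equal-weight
mean-of-bin discrete gamma (bin means via regularised incomplete gamma
functions, renormalised to mean exactly 1); invariant sites mix a point
mass at rate 0 with weight p_inv; +F replaces model frequencies with
alignment frequencies smoothed by one pseudo-count per residue.  Site
log-likelihoods come from Felsenstein pruning with gaps and 'X' treated as
missing data.  Model selection minimises AIC = 2k − 2 logL on a fixed
guide tree, with α and p_inv optimised per candidate by bounded 1-D
searches (the +I+G pair starts from the +G profile and keeps the best
visited point, so a richer model never scores below its nested neighbour);
k counts α, p_inv and 19 free frequencies for +F.  Ties break toward fewer
parameters, then name.  AIC (not AICc/BIC) is used as the conventional
default ranking for this kind of model choice.

## Tree building and distances

Topologies come from Saitou–Nei neighbor joining on maximum-likelihood
pairwise distances (two-sequence likelihood maximised over t ∈ [1e-8, 20]
by bounded search, tolerance 1e-7; jointly missing sites skipped).  NJ
tie-breaks are deterministic (lexicographically smallest cluster pair) and
negative branch estimates are clamped to zero with the deficit moved to
the sibling so path lengths are preserved.  Branch lengths can be
re-optimised on the fixed topology by coordinate-wise bounded search
(sweeps until the log-likelihood gains < 1e-6 or 20 sweeps; only improving
moves are accepted, so the log-likelihood is monotone).  A full
maximum-likelihood topology search is intentionally out of scope: the
statistic consumes only patristic distances, NJ is consistent on additive
matrices (verified exactly in tests), and externally inferred trees can be
supplied as Newick at any stage.  Rooting is used only for clade
assignment; patristic distances are rooting-invariant.

## Synthetic data

The generator emulates the study design: seven taxa on the topology
(((((focal, (Aedes, Culex)), Anopheles), Drosophila)), Danaus, Nasonia)
with branch lengths giving a mean pairwise distance near 1
substitution/site and a focal terminal branch of 0.1 — the saturation
regime of deep insect divergences.  The default gene set is the 17 study
genes with per-gene site counts equal to the study's transcript lengths
divided by three, simulated under JTT with gamma heterogeneity (α = 1, a
mid-range value; the study's genes had heterogeneous best-fit models).
Dropout removes cry2 from the fly-like taxon and the pair (tim, cry2) from
the wasp-like taxon, mirroring the real lineage losses of one gene in one
taxon and two in another (the second wasp loss stands in for a
cryptochrome not among the 17 genes).  Per gene, the focal terminal branch
is scaled by a multiplier before simulation, so ground-truth rate shifts
are known.  Paralog fixtures duplicate the species tree beneath a
caterpillar backbone (default stem depths 0.6 and 1.2 for the three-copy
cryptochrome-like family), relabel the focal leaf of each copy as an
anonymous candidate and emit the reference map and truth.

Simulated alignments are gap-free (no indel process), sites are
independent with at most discrete-gamma rate variation, and composition is
stationary — so passing recovery tests demonstrate the pipeline's
correctness under its own model class, not robustness to alignment error,
indels or compositional drift in real data.

All randomness flows from a single integer seed through one numpy
generator; identical seeds give byte-identical outputs.

## Numerical choices and edge cases

Distances are bounded at 20 substitutions/site (saturation); identical
sequences return the lower bound 1e-8.  Pruning clamps site likelihoods at
1e-300 before logs.  All-missing columns carry likelihood 1.  Empty block
selections raise with advice to relax thresholds rather than silently
passing an empty alignment on.  The degenerate residual-ANOVA case of a
perfect regression fit returns F = 0 when groups are identical.  PHYLIP
identifiers are truncated to ≤ 10 characters preserving the trailing
gene/contig number, with collisions raised as errors.

## Problem sizes used in the shipped experiments

Recovery experiments run the full study (17 genes, study-sized alignments)
over 100 seeded replicates for the group-ordering check in the test suite
(50 in the acceptance script) and 20 replicates per paralog-family layout;
these sizes give binomial resolution well beyond the thresholds being
asserted while keeping each experiment in the tens of seconds.

## Known limitations

- ML pairwise distance estimates at deep divergences are convexly biased
  upward; through the NJ + patristic pipeline the estimated relative rate
  carries a small positive bias (~0.03 at the default geometry, ~4% of the
  null value).  Group contrasts, which difference this bias away, are
  unaffected; absolute per-gene rates from short alignments should be read
  with this in mind.
- Per-gene relative rates of the packaged real dataset cannot be
  recomputed from sequences here: the underlying ortholog sequences and
  distance matrices were never deposited.  The packaged table carries the
  published per-gene rates; all statistics on them are recomputed.
- The 2×k Fisher enumeration is exponential in k for large margins; at
  study sizes (k ≤ 8, n = 17) it enumerates a few thousand tables.
- No codon-level modelling, dN/dS, branch-specific likelihood rate tests
  or divergence-time estimation; those are different instruments for the
  same question.
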