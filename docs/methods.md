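# Methods

## Recoding

A gene's general secondary structure (one dot-bracket string per gene,
aligned to the alignment columns; one pseudoknot tier `[]` is accepted) is
parsed into a pair table. Encoding walks the alignment columns in order:
each pair (i, j) emits one pair-state symbol at the 5' position i and drops
column j; unpaired columns pass through as nucleotides (U written as T so
coded files stay readable by protein software). The pair-symbol table is a
fixed bijection of the 16 ordered pairs into amino-acid letters

```
AA→R  AC→N  AG→D  AU→Q    CA→E  CC→H  CG→I  CU→L
GA→K  GC→F  GG→M  GU→P    UA→S  UC→W  UG→Y  UU→V
```

so the Watson-Crick/wobble letters are {Q,S,F,I,P,Y} and the ten mismatch
letters include M (GG). Any fixed bijection carries the same information;
results should be compared at the level of state categories, not glyphs.
The 7-state alphabet rewrites all ten mismatch letters to the joint symbol
`M`; the 6-state alphabet rewrites `M` to `-`. Gap rule: if either pair
partner is a gap or an ambiguity code the coded symbol is `-` (pair
identity is undefined with a missing partner); unpaired ambiguity codes
also become `-`. `-` is missing data everywhere downstream.

## Substitution models

Models are reversible with Q_ij = S_ij π_j, rows summing to zero, scaled to
one expected substitution per site (−Σ π_i Q_ii = 1). Because one general
structure assigns every column to exactly one of {loop, stem},
exchangeabilities across the 4-state unpaired block and the k-state paired
block are structurally zero: the model is block-diagonal ("4×4 + k×k") and
one engine serves both partitions. Zero-count states receive a
pseudo-frequency of 1e-6 before normalization so Q stays non-singular;
exchangeabilities may be exactly zero. P(t) = exp(Qt) is computed by
eigendecomposition of the symmetrized generator diag(√π)·Q·diag(1/√π), with
a scipy `expm` fallback if the reconstruction is numerically defective
(row sums off by > 1e-8).

Rate heterogeneity is the usual +I+G4 mixture: invariant fraction p_inv
plus an equal-weight 4-category discrete gamma whose category rates are the
conditional means of the quantile slices (mean method, not medians), so the
weighted mean rate is exactly 1.

## Likelihoods

Felsenstein pruning runs per block: a column of kind UNPAIRED/PAIRED is
evaluated over its own block's states, with root frequencies the stationary
frequencies conditional on the block (so an all-missing column has
likelihood exactly 1) and missing data a uniform partial likelihood over
the block. Site patterns are compressed per block; per-node rescaling with
logged scale factors prevents underflow. The +I term uses the standard
invariant contribution (Σ π_s over states compatible with every observed
leaf). AIC counts branch lengths plus p_inv/alpha when optimized; a fixed
empirical exchangeability matrix and count-based frequencies count zero,
matching the usual convention for empirical models.

Pairwise distances maximize the closed two-taxon likelihood by bounded
Brent search on [1e-9, 20] (identical sequences short-circuit to 0); NJ
topologies come from dendropy's neighbor joining with negative branch
lengths clamped to 0. Branch-length optimization is coordinate-wise Brent,
sweeping all edges until the lnL gain of a sweep falls below the tolerance;
a proposed length is kept only if it improves the objective, so lnL never
decreases. (p_inv, alpha) are fitted by Nelder-Mead on (logit, log)
transformed coordinates.

`compare_fit` evaluates each model on each shared (tree, alignment) subset
and reports, per ordered model pair, the mean per-site lnL difference
(positive favors the first model) and mean per-site AIC difference
(negative favors the first model).

## Empirical matrix estimation

Training taxa are split into subsets of up to k taxa (default 16): randomly
(shuffle + chunk; a trailing remainder is folded into the previous subset,
keeping every subset ≥ 4 taxa) or by a guide NJ tree, rooted at its longest
internal edge and cut top-down into complete clades of ≤ k leaves — a
clade that fits under k is emitted whole, a larger one recurses into its
children, so well-separated clades are never split or mixed. (Greedy
post-order accumulation was tried first and rejected: walking up an
unrooted ladder it absorbs stray neighbouring leaves into a finished
clade's group, splitting the neighbouring clade.) Estimation
then alternates (a) per-subset NJ topology + branch-length optimization
under the current model — a new topology is accepted only if it improves
the subset lnL over the previous one re-optimized under the same model, so
the trace is monotone — and (b) L-BFGS-B maximization of the pooled lnL
over log-exchangeabilities with trees fixed. Frequencies are count-based
(+F style), fixed at the smoothed observed counts: the convention for
empirical matrices, and it keeps the optimization well-conditioned. State
pairs never observed together in any column are pinned at exchangeability
0 (real pair-state data genuinely contain such zeros). Defaults tol = 0.1
lnL units, max_iter = 10, both configurable; the recovery experiments below
converge in 3 iterations.

Parameter robustness between two models is summarized by Pearson r (and p)
for the frequency vectors and for the within-block upper-triangle
exchangeabilities (cross-block zeros excluded), plus a paired t test on the
mean-normalized exchangeabilities — Pearson is scale-free, the t test needs
a common scale.

## Partition statistics

Tajima's D uses the 1989 constants verbatim with complete deletion of
columns containing any gap or ambiguity (the common default in popular
polymorphism software; configurable by pre-filtering columns). With no
segregating site D is reported as NA rather than raising. The p
classification — p>0.10, 0.10>p>0.05, p<0.05 — uses Tajima's beta
approximation: D is bounded in [Dmin, Dmax] (all-singleton vs
half-frequency configurations), rescaled to (0,1), and treated as a beta
with mean 0 and variance 1 on the D scale; exact p-values are deliberately
out of scope. MPI averages, over all sequence pairs, identical columns
divided by columns where neither sequence is gapped; a pair with no
comparable columns contributes 0 with a warning.

## Tree distances

RF is the plain symmetric-difference count of nontrivial splits (not
halved); MS is the minimum-cost perfect matching between split multisets,
cost n − (best agreement over the two orientations), padded with trivial
splits (an unmatched split costs min(|A|,|B|)) and solved exactly with the
Hungarian algorithm. MS here is topology-only: the metric's standard
definition does not use branch lengths. Both are normalized by the
Monte-Carlo mean distance between independent random Yule topologies on the
same leaf count (sequential random joins; default 1 000 replicate pairs,
seeded), under which the RF convention (halved or not) cancels.

## Simulation and fixtures

`simulate_coded` draws root states from the block-conditional stationary
frequencies and evolves children via P(rate·t), with per-column rates from
the +I+G mixture; all randomness flows from explicit integer seeds.
`generate_fixture` produces a complete synthetic study unit: an ultrametric
Yule tree (rescaled to a configurable root-to-tip height, default 0.5
substitutions/site — a realistic family-level depth), a 74-column
cloverleaf template (acceptor stem + three stem-loops, 20 pairs), stem
columns simulated as pair-states and expanded into both nucleotide
partners, loop columns simulated as nucleotides. The default stem model is
WC/wobble-enriched (AU > UA > GC > CG > UG > GU, echoing observed stem
composition in mitochondrial RNAs) with a tunable mismatch frequency
(default 0.10) and explicit pair-to-pair exchanges — double substitutions
at rate `compensatory_rate`, doubled between WC pairs — which is what
compensatory evolution looks like after recoding. The default loop
composition is A > U > G > C.

What the fixtures do **not** emulate: indels (fixture alignments are
gapless; gap handling is tested separately on hand-made cases), alignment
error, per-species structure deviation from the general structure,
base-composition heterogeneity across lineages, and real taxon sampling.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generating process, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The recovery experiments use 16 taxa × 5 000 columns (6-pair-state
alphabet), which is ample for r ≥ 0.95 exchangeability recovery; the
enumeration cross-checks use all 4- and 5-leaf topologies × 50 columns,
where brute force is exact and fast. Pruning underflow is handled by
per-node max rescaling. Brent tolerances are 1e-6 (branch lengths) and
1e-7 (pairwise distances); the rate-model fit uses 1e-6 lnL units.
Degenerate inputs: all-identical subsets are rejected in estimation with
the subset named; S = 0 yields an NA Tajima's D; t = 0 yields an exact
identity P matrix.

## Known limitations

* Full ML topology search, bootstrap and SH-aLRT are out of scope; trees
  are given, or NJ-derived for estimation subsets.
* The 6-state alphabet discards mismatch information by construction;
  comparisons across alphabets must transform models (see
  `expand_collapsed_model`), since likelihoods over different codings are
  not directly commensurable.
* Exchangeability optimization uses numerical gradients; for the 20-letter
  alphabet (126 free parameters) estimation is substantially slower than
  for the 10/11-letter alphabets.
* One general structure per gene: per-species structural variation is not
  modeled.
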