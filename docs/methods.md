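# Methods

## The branch-site test

`branchsight` implements Test 2 of the branch-site codon model
("Model A").  One edge of an unrooted phylogeny is designated the
*foreground* branch; every other edge is *background*.  Codon sites are
assigned to four latent classes:

| class | proportion | background ω | foreground ω |
|-------|-----------|--------------|--------------|
| 0     | p0        | ω0 < 1       | ω0           |
| 1     | p1        | 1            | 1            |
| 2a    | (1−p0−p1)·p0/(p0+p1) | ω0 | ω2 ≥ 1 |
| 2b    | (1−p0−p1)·p1/(p0+p1) | 1  | ω2 ≥ 1 |

ω is the nonsynonymous/synonymous rate ratio of a Goldman–Yang style
61-state codon substitution process: the rate from codon *i* to codon
*j* is nonzero only for single-nucleotide changes and proportional to
the target codon's equilibrium frequency, multiplied by κ for
transitions and ω for nonsynonymous changes.  Codon frequencies default
to F3x4 (position-specific nucleotide frequencies estimated from each
gene's alignment, renormalized over the 61 sense codons); uniform
frequencies are available for testing.  Gap codons (`---`) and codons
containing `N`/`?` are fully ambiguous (summed over all 61 states).
In-frame stop codons are an input error — coding alignments are assumed
to have been screened upstream.

The likelihood of a gene is the product over codon sites of the class
mixture, each class evaluated by Felsenstein pruning.  The alternative
model estimates ω2 ∈ [1, 999]; the null fixes ω2 = 1.  The test
statistic is 2·(lnL_alt − lnL_null), clamped at zero, referred to
χ²(df = 1).  Because ω2 = 1 lies on the boundary of the alternative's
parameter space, the statistic is asymptotically a 50:50 mixture of a
point mass at 0 and χ²₁; statistics below 1e-6 are reported as exactly
zero with p = 1.  Following the workflow this package reproduces,
p-values are left *unhalved* by default and significance is judged at
p < 0.05.

### Branch-length scaling across site classes

Branch lengths are expected substitutions per codon *averaged over the
site-class mixture*, the convention of the standard codeml
implementation: each class's rate matrix is divided by the
mixture-average substitution rate of its branch type (background or
foreground), so a class with ω2 = 4 genuinely accumulates more
substitutions per unit branch length than a purifying class.  A
standalone `CodonSubstModel` from `build_q_matrix` is scaled to one
expected substitution per unit time, which is the same thing for the
single-class M0 model.

### Optimization

Fits use bounded L-BFGS-B.  Bounds: κ ∈ [0.1, 20], ω0 ∈ [1e-4, 0.999],
ω2 ∈ [1, 999], branch lengths ∈ [1e-7, 20]; the two free class
proportions travel through an unconstrained softmax transform.
Defaults: three seeded random restarts on top of a deterministic start,
convergence tolerance 1e-10 (relative) on the negative log-likelihood,
branch lengths optimized jointly with the model parameters
(`branch_mode="joint"`).  M0 is fitted first and seeds the Model A
starts; M0's branch-length gradient is computed analytically by the
standard downpass/uppass scheme, which is what makes joint optimization
affordable.  The alternative fit always starts from the null optimum
(plus an ω2 = 3 probe), so the clamped statistic can only be corrupted
by numerical noise, never by a lost optimum; conversely, if the
alternative search ends on the ω2 = 1 boundary with a better value than
the fitted null, the null is re-polished from that point before the LRT
is formed.  Both safeguards keep the empirical point mass at zero
honest.

For simulation cohorts of tens to hundreds of genes the package uses
`branch_mode="m0"`: branch lengths are estimated once per gene under M0
and held fixed — identically — in the null and alternative fits.  The
comparison remains nested, and per-gene cost drops by roughly an order
of magnitude.  Cohort sizes used by the test suite (50 correct-null
genes of 300 codons, 30 conserved-only genes, 20 positive genes of 500
codons, on an 8-taxon tree) were chosen as desk-scale stand-ins for the
full-genome screen.

### Site posteriors

Site classification uses empirical Bayes at the MLEs (often called
NEB): the posterior of class *k* at a site is the fitted proportion
times the class site likelihood, normalized over the four classes.
Full Bayes empirical Bayes — integrating over a prior on the
parameters — is deliberately not re-implemented; the downstream filter
consumes a posterior table regardless of its estimator, and externally
produced BEB tables can be supplied to it directly.  NEB posteriors are
known to be slightly overconfident relative to BEB at small sample
sizes; at the cohort sizes used here the difference does not affect the
filtering behavior being tested.

## Synthetic data

### Codon regimes

The generator evolves codon alignments site by site along a labeled
tree: the root codon is drawn from the equilibrium frequencies and each
edge applies the class-appropriate transition matrix, with the class
held constant across the tree (Model A's own generative assumption).
Three regimes define the benchmark:

* **correct-null** — the null model itself: p0 = 0.55 (ω0 = 0.1),
  p1 = 0.30, remaining 15% in classes 2a/2b with ω2 = 1.  LRT
  statistics should follow the boundary 50:50 mixture.
* **conserved-only** — two purifying classes, ω = 0.05 (70%) and
  ω = 0.3 (30%), and *no* neutral class.  This is the situation of most
  real proteins, for which the null model is misspecified with the true
  parameter inside the forbidden zone; it inflates the share of zero
  statistics (p = 1) and is the central mechanism the package
  reproduces.
* **positive** — as correct-null but ω2 = 4 on the foreground for the
  15% class, supplying true positives.

The default tree has 8 leaves, branch lengths 0.05–0.3, and an internal
foreground branch (the stem of a four-taxon clade, length 0.15); κ = 2
and uniform codon frequencies.  These are declared desk-scale choices,
not estimates from any data set.  What the generator deliberately does
not emulate: indels and alignment error, among-site rate variation
beyond the ω classes, codon usage bias beyond F3x4, and selection on
more than one branch.  Consequently, passing tests demonstrate the
statistical behavior of the test under its own model assumptions — not
robustness to the alignment artifacts that the BEB spacing filter
targets in real data.

A note on detectability: a truly selected site leaves no trace unless
it actually substituted on the single foreground branch.  At foreground
length 0.15 the probability of an observable change for an ω2 = 6 site
is ≈ 0.43, which caps the achievable site-flagging rate well below one
regardless of estimator; the posterior tests therefore assert
enrichment relative to background rather than an absolute detection
rate.

### Normal boundary-condition scenarios

The second simulator reproduces the closed-form illustration of the
same boundary phenomenon.  Samples of size n = 100 are drawn from
N(μ, 1) and tested for H0: μ = 0 against H1: μ > 0 with σ known:
stat = n·max(x̄, 0)²/σ², p = upper χ²₁ tail, and x̄ ≤ 0 gives stat = 0,
p = 1 exactly.  (A σ-estimated variant sits behind
`ScenarioSpec.estimate_sigma`.)  Scenario 1 draws 10,000 correct nulls;
scenario 2 replaces 1,000 of them with alternatives; scenario 3 draws
4,500 misspecified nulls (μ < 0), 4,500 correct nulls and 1,000
alternatives.  The alternative and misspecified means are not pinned
down by any printed number and default to μ_alt = +0.35 and
μ_mis = −0.23 (configurable); quantities that depend on their exact
values are reported but not asserted.

## P-value machinery

* `mass_at_one` — fraction of p-values within tolerance of 1, the
  diagnostic for the zero-statistic point mass.
* `adjust` — halving (the standard boundary correction) or scaling by
  the observed nonzero-mass fraction; both are monotone.
* `bh_fdr` — Benjamini–Hochberg step-up (delegated to statsmodels,
  cross-checked in the tests against a hand-written step-up rule).
* `robust_fdr` — the robust FDR estimator applied to the pool of
  p-values below a cutoff (default 0.98, excluding the artifactual
  right-tail mass): π̂0 = min(1, 2·mean(p)) over the pool,
  q(i) = π̂0·m·p(i)/i, monotonized downward from the largest p.  The
  π0 multiplier and cutoff are exposed in `AdjustmentConfig`.  The
  estimator's authors caution against correcting nonuniform p-values;
  the module reports diagnostics and leaves that judgement to the user.

## PSG calling

A gene is a positively selected gene (PSG) when its unhalved LRT
p-value is strictly below 5% *and* it survives the site filter: at
least one site in class 2a or 2b with posterior strictly above 0.5;
and, when more than five such sites exist, a median interval between
successive qualifying sites of at least 10 amino acids (clusters of
flagged sites are the signature of local misalignment).  "Interval" is
read as the difference of successive qualifying positions (n sites give
n−1 intervals; an even count takes the mean of the two central values)
— the plain reading, flagged for sensitivity analysis since all-pairs
distances are also defensible.  Category cross-referencing counts a
gene once per category it belongs to; categories may overlap.

## Alignment QC

Orthology uses reciprocal best BLAST hits at e ≤ 1e-06 resolved from
tabular hit files; equal-scoring conflicting top hits are an error, not
a silent choice.  One representative per species is the sequence with
the fewest gap characters (ties to input order).  Masking runs three
ordered passes: drop codon columns gapped in the reference sequence
(default `Homo_sapiens`); drop sequences more than 50% gap/missing
*measured on the surviving columns* (the ordering is a declared choice);
convert columns more than 50% missing to fully missing.  Every removal
is logged.  Eligibility requires ≥ 10 taxa and ≥ 2 descendants of each
focal clade, except branches on the single-taxon exemption list (a
lineage represented by one extant tip), which require 1.  Tree trimming
prunes to the gene's taxa, collapses degree-2 nodes with lengths summed
(pairwise path lengths between survivors are preserved exactly), and
re-derives the foreground bipartition from the surviving taxa; losing
an entire side of the bipartition is a reported error.

## Numerical notes

* Pruning peak-normalizes internal messages per site pattern and
  accumulates log scales, so deep or long trees cannot underflow.
* Site patterns are deduplicated; per-gene work is proportional to the
  number of unique codon columns.
* Classes 2a/2b share every background message with classes 0/1; only
  the path from the foreground edge to the root is recomputed.
* Degenerate inputs: alignments with zero observed codons, trees whose
  foreground bipartition matches no edge, proportions leaving the
  simplex, and negative branch lengths all raise immediately rather
  than propagating NaNs.

## Known limitations

* NEB rather than full BEB posteriors (see above).
* Only M0 and branch-site Model A; no site models (M1a/M2a/M7/M8) or
  clade models.
* One foreground branch per test; foreground lineages are tested
  independently, as in the workflow this mirrors.
* The robust-FDR estimator is applied to truncated pools whose
  uniformity assumption is knowingly violated; it is reported as a
  ranking device, not a calibrated error rate.
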