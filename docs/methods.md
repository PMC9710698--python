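# Methods

This note records the model, the numerical conventions, the synthetic-data
generators and the open design choices behind `cytocomb`, in the spirit of a
statistical-software methods appendix.

## Discretization and the phenotype space

Each marker `k` is cut into `n_k ≥ 2` ordered states by `n_k − 1` strictly
increasing intensity thresholds supplied by the user (from manual gating).
The binning convention is half-open with the boundary assigned to the
*higher* state — a value exactly on a gate line belongs to the positive
population, matching manual-gating practice. Discretization is therefore
monotone per marker. Non-finite intensities are a hard error rather than
silently dropped, so upstream parsing problems surface immediately.

An optional Out-of-Bound ceiling per marker removes cells whose intensity
strictly exceeds it on **any** limited channel; OOB events are treated as
acquisition artifacts that invalidate the whole cell, and filtering happens
before discretization as the first pipeline step.

A *phenotype* assigns each marker a state or leaves it neutral; with the
all-neutral assignment excluded there are `prod_k (n_k + 1) − 1` phenotypes.
Phenotypes are identified by their mixed-radix integer code (base `n_k + 1`
per marker, last marker least significant). The code is bijective, compact,
and its ascending order is the canonical on-disk order. 64-bit codes limit a
single analysis to panels with `prod (n_k + 1) ≤ 2^63`, i.e. ~39 two-state
markers; larger panels are analyzed per parent lineage, which is also what
run time dictates in practice.

## Counting

Full-length phenotype counts are a single grouped aggregation of each
sample's encoded state vectors; only phenotypes observed in at least one
sample are ever materialized. Every neutral-state phenotype is then an exact
marginal sum of full-length counts over the neutralized markers. The
marginalizations (one per marker subset) are independent: they may run on a
thread pool, and results stream to gzip text chunks of a configured row
count, so peak memory is bounded by the largest single marginalization and
never by the output size. Output is identical for any worker count because
masks are enumerated in a fixed order (by phenotype length, then
lexicographic marker sets) and rows are sorted by code within chunks.

Filters follow the conventions of threshold-based gating analysis: a
phenotype is kept when it has at least `min_count` cells in at least
`min_sample_fraction` of samples (both comparisons inclusive, so "100 cells
in 50% of samples" retains the exactly-half case). The filter is applied per
phenotype after marginalization, not transitively: a dropped short phenotype
does not remove refinements that pass on their own. A parent phenotype
restricts counting to its refinements; parent markers remain part of each
child's definition and the parent itself survives the filter.

## Statistics

All tests operate on frequencies — counts over the sample's total cells, or
over the parent's per-sample counts when conditioning — since acquisition
depth varies across samples. Samples with a zero denominator are excluded
with a warning.

* **Group mode** (two levels, ≥ 2 samples each): two-sided Mann–Whitney U,
  exact null distribution when both groups have ≤ 25 samples and the pooled
  frequencies are tie-free, otherwise the tie-corrected normal
  approximation. The effect size is the rank-biserial correlation
  `2U/(n₁n₂) − 1` computed from the reference group's U — bounded in
  [−1, 1], sign-flipping under label swap. The fold change is
  `log₂(mean₂/mean₁)`; only when a group mean is zero is a pseudocount
  (half the smallest nonzero frequency in the table) added to both means,
  giving finite, comparable values without distorting nonzero ratios.
* **Correlation mode** (≥ 3 samples): Kendall τ-b with its two-sided
  p-value; constant frequency or covariate vectors are flagged and skipped.
* **Survival mode** (positive times, ≥ 1 event): Cox proportional hazards
  with the frequency as the sole, unscaled covariate, Efron tie handling
  (via lifelines); the statistic is the fitted log-hazard coefficient with
  its Wald p-value. Zero-variance designs and non-converging fits are
  flagged per phenotype, never fatal.

P-values are never adjusted for multiplicity. Enumerated phenotypes are not
independent observations — a phenotype, its refinements and its marginals
count overlapping cells — so the number of comparisons does not translate
into an error-rate correction, and the inflation of type-I errors is instead
mitigated downstream by the independence analysis. The significance filter
is a raw `p ≤ threshold`.

## Independence analysis

Significant phenotypes form an undirected network weighted by

    ps(p_i, p_j) = ℓ(p_i ∩ p_j) / (ℓ(p_i) + ℓ(p_j)) ∈ [0, 0.5].

The intersection counts markers on which both phenotypes specify the *same*
non-neutral state: A+ and A− describe disjoint cell sets, so sharing a
marker name alone is not similarity. A `match_states=False` switch restores
name-only counting for users who prefer it.

`n` sub-networks (default 10) are produced by pruning edges below
`t_i = i·max(S)/(n+1)`, `i = 1..n` — strictly increasing, never reaching
`max(S)`, inclusive at the threshold. Each sub-network is clustered with the
Louvain modularity algorithm (igraph's multilevel implementation, resolution
1, seeded RNG; labels renumbered by smallest member for reproducibility);
isolated nodes are singleton clusters. Within each cluster the representative
maximizes the ranking statistic — in group mode
|effect size|·|log₂ fold change| with each factor min–max normalized to
[0, 1] over the phenotype set before multiplication (a degenerate range maps
to 1); |τ| or |Cox coefficient|, normalized, in the other modes. Exact ties
are broken deterministically: shorter phenotype first, then smaller code.
The confidence score of a phenotype is the fraction of the `n` sub-networks
in which it was selected, so it lives on the grid `{0, 1/n, …, 1}`. When the
similarity matrix has no positive entry (including the single-phenotype
case) every phenotype is trivially its own representative at confidence 1.

Two points were genuinely open and are resolved as follows. First,
normalization is applied per factor rather than to the product; the choice
does not affect which phenotype ranks first when a single phenotype
dominates both factors, and factor-wise normalization keeps the two scales
commensurate. Second, on well-powered cohorts the exact Mann–Whitney
p-value saturates at its combinatorial floor (`2/C(n₁+n₂, n₁)`) for nearly
every phenotype, so a p threshold cannot bound the size of the selected
set; the network therefore admits at most `max_network_size` phenotypes
(default 500), taking the top-ranked ones when more are significant. This
keeps the dense similarity graph tractable and focuses deduplication on the
candidates that could be reported anyway.

## Synthetic data

Two generators provide ground truth. Intensities are always drawn uniformly
inside unit-width state intervals with thresholds on the integer grid, so
discretization recovers the generating states exactly; the same seed yields
byte-identical outputs.

* **Worst case**: every one of the `n^m` full-length phenotypes present in
  every sample with counts differing by at most one (the integer-division
  remainder lands on a seeded random subset). This is the hardest counting
  input — real panels are far sparser because biology forbids most
  co-expression patterns — and is the substrate for the oracle-equivalence
  and conservation tests.
* **Planted cohort**: a two-group cohort sharing one background multinomial
  over full-length phenotypes, drawn once per cohort from a symmetric
  Dirichlet with concentration 5 (moderately uneven, as gated subsets are).
  In group 2 the mass of every full-length refinement of a chosen planted
  phenotype is multiplied by `effect` and renormalized, which makes the
  expected attenuated fold change closed-form:
  `effect / (1 + (effect − 1)·f)` with `f` the planted phenotype's baseline
  mass. `effect = 1` reduces exactly to the null generator. Optional
  survival times are exponential with log-hazard `β · frequency`. The
  standard validation cohort uses 8 two-state markers, 20 000 cells per
  sample, 20 + 20 samples and a four-fold effect on A+B+; calibration
  studies use the same generator at `effect = 1` with 3 markers and 2 000
  cells, sizes at which 500 replicates run in seconds.

The generators emulate pre-gated, compensated data. They do not model
spillover, acquisition drift, batch effects, doublets or non-uniform
within-state intensity distributions — so passing tests demonstrate the
correctness of counting, testing and deduplication on clean discretizable
data, not robustness to instrument artifacts. Note one consequence of the
multiplicative planted effect: renormalization shifts *every* phenotype's
frequency between groups, so on deeply sampled cohorts nearly all phenotypes
are genuinely (if weakly) differential; recovery is judged by whether the
planted lineage is the top-confidence representative, not by counting
significant phenotypes.

## Workflows, limits, degenerate inputs

The local workflow holds the count table in memory and refuses to start when
the projected phenotype count (an exact coefficient-sum bound given
`max_length`) exceeds a configurable budget (default 2·10⁶ phenotypes); the
server workflow streams chunks and computes statistics chunk by chunk, with
the fold-change pseudocount pinned by a first pass so both workflows produce
identical tables on inputs small enough for either. Degenerate inputs are
handled explicitly: zero-cell samples yield all-zero columns; a parent with
zero cells in some sample triggers a warning (frequencies undefined there,
the sample is excluded at the frequency step); empty significant sets yield
empty reports. FCS support covers the common 3.0/3.1 list-mode case
(uniform bit width, F/D/I data types, both byte orders); CSV matrices are
the fully equivalent text dialect.
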