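# cytocomb

Exhaustive combinatorial phenotype discovery for gated flow and mass
cytometry data.

High-dimensional cytometry panels measure dozens of markers per cell, but
manual gating only ever inspects a handful of marker combinations chosen in
advance. `cytocomb` takes the opposite, agnostic route: given per-marker
gating thresholds it discretizes every channel into states (−/+, or
−/+/++ …), enumerates **every** marker-state combination — including
phenotypes that leave markers unconstrained ("neutral") — counts the cells
matching each phenotype in each sample, screens the phenotype frequencies
statistically between sample groups (or against a covariate, or a survival
endpoint), and finally collapses the heavily redundant significant set down
to a handful of independent candidate phenotypes via a similarity-network
clustering procedure with confidence scoring.

## The method

With `m` markers discretized into `n_k` states each, the number of
phenotypes (each marker either assigned a state or left neutral, minus the
all-neutral assignment) is

    N = prod_k (n_k + 1) − 1,

e.g. 531,440 for 12 two-state markers. Counting is done the only way that
scales: cells are first aggregated into the full-length phenotypes actually
present in the data (at most `min(total cells, prod n_k)`), and every
neutral-state phenotype is then a marginal sum over those counts. Each
marginalization is independent, so the step parallelizes and can stream to
bounded-size disk chunks (the *server* workflow) so that memory never grows
with the phenotype count.

Frequencies (counts over sample totals, or over a parent population's
counts) are screened per phenotype by the Mann–Whitney U test (two groups),
Kendall's τ-b (continuous covariate), or a Cox proportional-hazards fit
(survival). P-values are deliberately **not** corrected for multiplicity:
enumerated phenotypes overlap massively, so comparisons are not independent
and standard corrections do not apply — results are discovery candidates.

To deduplicate, significant phenotypes `p_i` are joined in a network weighted
by phenotypic similarity

    ps(p_i, p_j) = ℓ(p_i ∩ p_j) / (ℓ(p_i) + ℓ(p_j)),

where ℓ is phenotype length and the intersection counts markers with the
same non-neutral state (identical phenotypes score 0.5). The network is
pruned at `n` increasing thresholds `t_i = i·max(S)/(n+1)`; Louvain
clustering labels each pruned sub-network; one representative per cluster is
chosen by a normalized ranking statistic (|effect size|·|log₂ fold change|
for group comparisons, |τ| or |Cox coefficient| otherwise); and each
phenotype's **confidence score** is the fraction of sub-networks in which it
was selected.

## Worked example

Generate a synthetic two-group cohort in which the phenotype A+B+ is
four-fold enriched in group 2, then run the full pipeline:

```sh
cytocomb synth -m 4 --cells 2000 --samples 12 --effect 4 --seed 3 -o data/
cytocomb run data/s*.csv --thresholds data/gating.csv \
    --annotation data/annotation.csv --p-threshold 0.01 -o out/
```

The run log prints the per-stage tallies:

```
preprocess: 12 samples, 24000 cells retained
combinatorics: 16 full-length phenotypes, 80 phenotypes after expansion and filtering
stats (group mode): 80 phenotypes tested, 76 at p <= 0.01
independence: 76 candidate phenotypes, 1 at confidence 1.0
outputs written to out
```

All 3⁴ − 1 = 80 phenotypes of this panel are materialized; 76 reach p ≤ 0.01
(a multiplicative planted effect shifts every frequency through
renormalization), and the network stage collapses them to a single
confidence-1.0 representative — `A+B+C+D+`, a refinement of the planted
phenotype. `out/stats.tsv` holds the per-phenotype test results,
`out/independent.tsv` the representative report (ranking, confidence,
per-threshold cluster labels) and `out/counts/` the chunked count table,
searchable with `cytocomb find out/counts "A+B+"`.

The same analysis is available as a library:

```python
import cytocomb as cc

tables, panel, ann, truth = cc.generate_planted_cohort(cc.SynthConfig(seed=3))
states = [cc.discretize_events(t, panel) for t in tables]
full = cc.count_full_length(states, panel)
counts = cc.expand_neutral(full, cc.CountingConfig(max_length=8, min_count=100,
                                                   min_sample_fraction=0.5))
stats = cc.evaluate_phenotypes(counts, ann)
```

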