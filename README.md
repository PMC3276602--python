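# aimsel

Selection and evaluation of **ancestry-informative marker (AIM) panels**
for admixed populations.

Admixture mapping and structured-association studies need small panels of
SNPs whose allele frequencies differ strongly between the ancestral
populations of an admixed group (e.g. African-American cohorts with West
African and European ancestors). Many informativeness statistics compete
for that job, and they do not pick the same markers. `aimsel` implements
the five standard measures, the machinery to turn scores into spaced
panels, statistics to quantify how much the measures agree, a
maximum-likelihood estimator of individual admixture proportions, and a
forward-time simulator of admixed populations with tracked truth so every
panel can be evaluated against known ancestry.

## The statistics

For a biallelic marker with reference-allele frequencies `p1`, `p2` in two
ancestral populations, with `δ_j = p_1j − p_2j` per allele and an assumed
contribution `m1` of population 1 (`p_Aj = m1·p_1j + m2·p_2j` the admixed
frequency):

| measure | definition |
|---|---|
| δ (delta) | absolute frequency difference \|p1 − p2\| |
| F_ST | (p1 − p2)² / [(p1 + p2)(2 − p1 − p2)] |
| FIC | Σ_j δ_j² / p_Aj — Fisher information for the admixture fraction; favors fixation in the majority-contribution population |
| SIC | m1 Σ_j p_1j log p_1j + m2 Σ_j p_2j log p_2j − Σ_j p_Aj log p_Aj — entropy gap of the admixed mixture |
| I_n | Σ_j (−p̄_j log p̄_j + Σ_i p_ij log p_ij / K) — informativeness for assignment, defined for K ≥ 2 populations |

Individual ancestry `q` is estimated by maximizing the binomial
log-likelihood `Σ_l [g_l log f_l + (2 − g_l) log(1 − f_l)]` with
`f_l = q·p_1l + (1 − q)·p_2l` over `q ∈ [0, 1]` (concave, unique
maximizer). Panel accuracy is summarized by the bias of the mean,
`|mean(q̂) − mean(q)|`, and the individual-level RMSE
`sqrt(mean((q_i − q̂_i)²))`.

## Worked example

Simulate a two-way admixed population (20,000 markers, founder
differentiation F = 0.15, initial contribution 0.7, 10 generations of
random mating), build a spaced top-20 panel by `I_n`, and recover the
admixture proportions:

```python
from aimsel import (AdmixtureSpec, SimConfig, distance_filter, estimate_ancestry,
                    generate_ancestral_freqs, score_table, select, simulate_admixed)
from aimsel.evaluation import rmse_bias

config = SimConfig(seed=7)
table = generate_ancestral_freqs(config)
genotypes, truth = simulate_admixed(table, config)

scores = score_table(table, AdmixtureSpec(m1=0.8))
panel = select(distance_filter(scores, "i_n", min_bp=100_000), top_n=20)
est = estimate_ancestry(genotypes, table, panel)

report = rmse_bias(est, truth.sample_ids, truth.q_true)
print(f"realized mean ancestry : {truth.mean_q_true:.3f}")
print(f"estimated mean ancestry: {est.mean_q_hat:.3f}")
print(f"bias = {report['bias']:.3f}, RMSE = {report['rmse']:.3f} over {report['n']} individuals")
```

prints

```
realized mean ancestry : 0.750
estimated mean ancestry: 0.756
bias = 0.005, RMSE = 0.088 over 100 individuals
```

i.e. drift during founding and mating moved the realized mean ancestry to
0.750; twenty well-chosen AIMs recover that population mean to half a
percentage point and each individual's proportion to about ±0.09.

The same pipeline is available from the shell:

```sh
aimsel simulate --seed 7 --out-prefix sim
aimsel score --freq sim.freqs.tsv --m1 0.8 --out scores.tsv
aimsel select --scores scores.tsv --measure i_n --min-dist 100000 --top-n 20 --out panel.tsv
aimsel estimate --freq sim.freqs.tsv --genotypes sim.genotypes.tsv --panel panel.tsv --out est.tsv
```

`aimsel concord` reports pairwise Spearman/kappa agreement and top-n
overlap patterns between the five measures; `aimsel sensitivity`
quantifies how strongly FIC and SIC panels depend on the assumed
ancestral contribution; `aimsel subset-experiment` reruns ancestry
estimation on random subsets drawn from top-1/2/5/10% panels.

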