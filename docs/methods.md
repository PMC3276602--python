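# Methods

## Scope and model

`aimsel` treats ancestry-informative-marker selection as a pipeline with
four stages: (1) score biallelic SNPs for ancestry informativeness from
reference-allele frequencies in two (or, for I_n, K ≥ 2) ancestral
populations; (2) turn scores into panels under a physical-spacing
constraint and a selection rule; (3) quantify how much the five scoring
measures agree; (4) evaluate panels by how well they classify ancestral
individuals and recover admixture proportions in an admixed sample with
known truth.

Throughout, a marker is a biallelic SNP described by the frequency of an
arbitrary "reference" allele per population. Every measure is invariant
to which allele is called reference and (δ, F_ST, I_n exactly; FIC and
SIC under the simultaneous swap m1 ↔ 1 − m1) to population order; these
invariances are property-tested.

## The five measures

* **δ** = |p1 − p2|. Bounded [0, 1].
* **F_ST** = (p1 − p2)² / [(p1 + p2)(2 − p1 − p2)], the two-population
  biallelic form. A marker fixed for the *same* allele in both
  populations is a 0/0 case; it is defined to score 0 and flagged
  `monomorphic` (it carries no ancestry information).
* **FIC** = Σ_j δ_j²/p_Aj with p_Aj = p_2j + m1·δ_j, the Fisher
  information that one marker contributes about the admixture fraction
  at an assumed contribution m1 ∈ (0, 1). A term with δ_j = 0
  contributes 0 even when p_Aj = 0; if p_Aj = 0 with δ_j ≠ 0 the score
  is `inf`, which ranks above every finite score (for strictly interior
  m1 this cannot actually occur, but the contract keeps NaNs out).
* **SIC** = H(p_A) − m1·H(p1) − m2·H(p2), the Jensen gap of the binary
  entropy at the mixture; nonnegative by concavity, clipped at 0 against
  rounding.
* **I_n** = Σ_j [−p̄_j log p̄_j + Σ_i p_ij log p_ij / K], bounded
  [0, log K].

Entropy-based measures use the natural logarithm by default with a
`log_base="2"` switch. The base rescales SIC and I_n by 1/ln 2 but can
never change a ranking, so every downstream analysis is base-invariant;
natural log was chosen as the default because it keeps SIC's concavity
argument in its textbook form. The convention 0·log 0 = 0 applies
everywhere. The default assumed contribution for FIC/SIC is m1 = 0.8
(the conventional "majority ancestry fixed at 80%" choice), always
overridable.

**Ranking and ties.** Ranks are descending in score with the
deterministic tie-break (chromosome in natural order, position, marker
id). The tie-break is a total order, so ranks are always a permutation
of 1..M and every derived object (panels, deciles, overlap sets) is
reproducible bit-for-bit.

## Panels

The spacing filter visits markers best-score first and rejects a
candidate when an already selected marker on the same chromosome lies
strictly closer than `min_bp` (default 100 kb; markers exactly 100 kb
apart are both kept — "at least 100 kb"). Greedy-by-score rather than a
left-to-right genomic scan was chosen because the point of the filter is
to keep the *most informative* representative of each local cluster;
the greedy invariant (every rejected marker conflicts with a kept,
better-ranked one) is re-verified in tests by an independent O(M²)
check. Physical distance is a deliberate proxy for LD pruning; no r²
computation is attempted.

Selection rules: `top_n` (error, not truncation, if n exceeds the
panel), `top_fraction` (ceil(q·M), so a positive fraction is never
empty), and `cutoff` with the published defaults δ ≥ 0.3, F_ST ≥ 0.4,
FIC ≥ 2.0, SIC ≥ 0.3, I_n ≥ 0.3. Combined rankings score each marker by
the mean (AVE) or minimum (MIN) of its five per-measure ranks.

## Concordance

Spearman correlation uses tie-averaged ranks (delegated to scipy;
verified against a hand-built averaged-rank oracle). Decile groups are
assigned from the global ranks, sizes equal ±1, group 1 = most
informative. Cohen's κ is computed from the 10×10 contingency table as
(Pr(a) − Pr(e))/(1 − Pr(e)); values below 0 are reported as-is and
flagged rather than clamped, since clamping would hide
worse-than-chance disagreement. Top-n overlap is encoded per marker as
a 5-digit binary membership vector in the fixed order (δ, F_ST, FIC,
SIC, I_n).

## Ancestry estimation

Genotypes g ∈ {0, 1, 2} count reference alleles. Assuming Hardy-Weinberg
proportions within an individual and independence across (spaced)
markers, g_l ~ Binomial(2, f_l(q)) with f_l(q) = q·p_1l + (1 − q)·p_2l.
The log-likelihood is concave in q, so the maximizer over [0, 1] is
unique whenever any panel marker has p1 ≠ p2. It is located on a
1001-point grid followed by bounded scalar minimization in the
bracketing interval (xatol 1e-9); tests require agreement with a
10⁴-point grid oracle within 1e-3. Numerical choices:

* frequencies are clamped to [ε, 1 − ε], ε = 1e-6 (configurable), so a
  genotype conflicting with a fixed allele yields a finite, strongly
  negative term instead of −∞;
* missing genotypes contribute nothing (complete case per marker);
  individuals with no usable genotype are flagged and excluded from the
  population mean;
* a panel with p1 = p2 everywhere makes the likelihood flat; the
  estimator raises a non-identifiability error rather than returning an
  arbitrary interior point;
* population orientation is canonicalized internally (lexicographic
  comparison of the two frequency vectors), which makes the label-swap
  symmetry q̂ ↔ 1 − q̂ exact in floating point, not just approximate.

Only global (genome-average) ancestry is modeled; there is no
hidden-Markov local-ancestry component, and K = 2 with a 1-D bounded
optimizer replaces EM because both find the same unique maximizer.

## Classification

The discriminant model is two-class LDA with pooled within-class
covariance and priors proportional to class sizes. With panels of up to
~150 markers and a few hundred samples the pooled covariance is
near-singular, so a ridge λ = 1e-6 · trace(S)/p is added to the
diagonal. Accuracy is leave-one-out cross-validated by default (k-fold
available); LOOCV is verified against brute-force per-fold refitting,
and predictions match scikit-learn's LDA on well-conditioned problems.
`markers_needed` applies the threshold definition literally: the
smallest n in the grid whose accuracy reaches the threshold, even if
the curve later dips.

## Synthetic data

The generator replaces an external forward simulator seeded by real
phased haplotypes with a self-contained equivalent:

* **Founder frequencies** follow the Balding-Nichols model: ancestral
  frequency p ~ Uniform(0.05, 0.95) per marker (mirroring a MAF > 5%
  "common in both populations" filter), then each population draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) independently. F is the drift of each
  population from the shared ancestor; the realized mean *pairwise*
  F_ST between the two populations is ≈ 0.46·F (Monte-Carlo), so the
  default F = 0.15 yields ≈ 0.07 — the level seen between strongly
  differentiated human populations on common shared SNPs. Marker
  positions are uniform over the configured chromosome lengths
  (default 10 × 20 Mb).
* **Admixed deme:** `n_founders` (default 200) diploid founders, each
  wholly assigned to population 1 with probability m0 (default 0.7) and
  given per-locus haplotypes from its population's frequencies; then G
  (default 10) discrete non-overlapping generations of monoecious
  random mating without selfing, constant deme size, no mutation or
  selection. Meiosis recombines with Poisson crossover counts
  (`recomb_rate` = 1e-8 Morgans/bp, i.e. 1 cM/Mb — Haldane model) and
  uniform crossover positions. Every allele copy carries an ancestry
  label through meiosis.
* **Truth:** q_i is the fraction of the individual's 2L allele copies
  labelled population 1 — marker-weighted rather than
  physical-length-weighted, because that is exactly the quantity the
  genotype-based estimator targets. E[mean q] = m0, with binomial
  founder drift of SD ≈ sqrt(m0(1−m0)/n_founders) ≈ 0.032 around it,
  so realized study means land a few points away from 0.7; evaluations
  always compare against the realized truth.

What the generator does **not** emulate: real LD/haplotype structure
(loci are drawn independently within a founder), a realistic site
frequency spectrum or informativeness decay across ranks (the
Balding-Nichols tail is comparatively fat, so mid-rank markers remain
informative), continued gene flow after founding, and non-random
mating. Consequences: passing end-to-end tests demonstrate correct
estimation and honest panel comparisons *given* frequency divergence,
but panel sizes and the sharpness of quality decay from top-1% to
top-10% panels on real data are not claimed. In particular, the
mean-error growth across subset-panel fractions that appears on real
data is muted here (the dispersion growth is reproduced), because even
top-10% synthetic markers remain strong.

## Reference study conditions

The default `SimConfig` is the package's reference scenario: L = 20,000
markers, F = 0.15, m0 = 0.7, G = 10, 200 founders, 100 sampled
individuals. These sizes keep a full study (simulation, scoring, five
panels, estimation, concordance, sensitivity) at a few seconds, and the
acceptance-style end-to-end tests at a few minutes for three seeds. A
less differentiated scenario in the spirit of East-Asian population
pairs uses m0 = 0.72 with roughly ten-fold smaller F.

## Known limitations

* δ, F_ST, FIC, SIC are implemented only for two ancestral populations
  and biallelic markers; I_n alone generalizes to K > 2.
* Frequencies are taken as known constants; sampling error in the
  ancestral panels is not propagated into scores or the likelihood.
* The HapMap allele-frequency reader merges files by rs id without
  reconciling strand or allele identity across files (measures are
  allele-choice invariant, but a mixed-strand file pair would still be
  inconsistent for downstream genotype analysis).
* Exact panel sizes under the 100 kb rule depend on the tie and order
  convention; only the spacing invariant and determinism are promised.
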