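# Methods

## Model and procedure

The detector treats the disease status *D* (binary) and the SNP genotypes
(3-category, coded as copies of the disease-associated allele) as nodes of
a Bayesian network and estimates the parent set Pa(*D*). Two assumptions
underpin the design: the joint distribution is faithful to some DAG (every
conditional independence in the data reflects one in the graph), and the
disease-relevant structure is local — markers outside the Markov blanket
of *D* are screened off by small conditioning sets.

**Phase I** applies the adjacency criterion: a marker X is kept only if no
conditioning set Z (|Z| ≤ `max_cond`) drawn from the current candidate set
makes X ⟂ D | Z acceptable. Independence is judged by the G-test,
G = 2 Σ O ln(O/E), with expected counts computed per conditioning stratum
and degrees of freedom counted per stratum from non-empty rows and columns
(a stratum with no contrast contributes nothing; a table with zero
corrected df is declared independent, since it carries no evidence either
way). G is additive across strata, which is why it is preferred to the
Pearson χ² here. The surviving markers are ranked by marginal p-value
(ties: larger G, then column index), and the ranked list is pruned
interleavedly: each incoming marker is tested against subsets of the
current set, and after each admission existing members are re-tested
against subsets involving the newcomer. The output order — strongest
association first — is part of the contract, because Phase II consumes it.

**Phase II** maximises the decomposable local score
loglik(D | Pa) − κ·n_params·ln N by greedy hill-climbing over the
candidate list: at each step every single addition (in candidate order)
and every single removal is evaluated and the best strict improvement is
applied, additions preferred on ties. Removals let the search undo a
one-step-suboptimal admission; strict improvement guarantees termination.
The likelihood is the plug-in multinomial — no smoothing, which is what a
BIC-type criterion assumes — and n_params = (Cat(D)−1)·∏ᵢ Cat(parentᵢ)
counts categories actually observed per column, so a monomorphic marker
contributes a factor of one.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha1` | 0.01 | significance level of Phase I G-tests |
| `bonferroni` | on | marginal screen tested at `alpha1 / n_markers` |
| `max_cond` | 3 | largest conditioning set tried in Phase I |
| `kappa` | 0.17 | score penalty coefficient (0.5 = standard BIC) |
| `max_parents` | none | optional cap on the Phase II set size |

κ = 0.17 softens the standard BIC penalty (κ = 0.5) for moderate sample
sizes; it makes the score accept a first parent whenever its G exceeds
4κ·ln N (≈ 5.2 at N = 2000) but grows the penalty threefold per added
3-category parent, which is what keeps selected sets small.

The familywise-corrected screen is a deliberate design choice rather than
a per-test convention. The conditional shrink cannot reject a *lone*
spurious survivor (there is no conditioning partner to screen it off), and
with κ = 0.17 Phase II admits any marker that passes a per-test screen at
conventional levels; an uncorrected sweep of a 100-marker null panel would
therefore end with a non-empty selection in roughly a third of datasets.
Bonferroni correction of the screen (only the screen — conditional tests
use `alpha1` per test) restores the false-positive suppression that is the
method's point, keeps the behaviour sensible on panels of any size, and
costs sensitivity only near the detection boundary. `bonferroni=False`
recovers the per-test behaviour.

## The simulator

Datasets mimic a two-locus retrospective case-control study. Disease odds
follow one of three classic epistasis models (multiplicative
α(1+θ)^(i+j); interaction-only α(1+θ)^(i·j); threshold α(1+θ) for joint
carriers), with penetrance odds/(1+odds). Rather than picking (α, θ)
directly, the user specifies a marginal per-allele odds-ratio parameter λ
— the odds ratio of disease for one vs zero copies at a locus, after
marginalising the other locus under Hardy-Weinberg — and a prevalence *p*;
a two-dimensional root-find in (ln α, ln(1+θ)) recovers the model
parameters, with back-substitution residuals verified below 1e-8.
Genotypes are drawn retrospectively from P(g | case) and P(g | control);
each disease locus gets one LD tag marker generated allele-wise from the
haplotype distribution with π_CD = π_Cπ_D + √(r²·π_Cπ_cπ_Dπ_d)
(positive-coupling sign, since only r² identifies the coupling); null
markers are i.i.d. Hardy-Weinberg draws with MAFs uniform on (0.05, 0.5).

Unstated study constants were fixed once: prevalence 0.1 (conventional for
these odds models), tag-marker MAF equal to its disease locus, the
disease-associated allele identified with the minor allele, and the
four signal columns placed at seed-determined random positions among the
nulls (recorded in metadata). The simulator does not attempt genome-scale
LD structure, population stratification, missingness or quantitative
traits, so passing tests speak to the algorithm's behaviour under clean
two-locus signals, not to performance on real panels.

## Power evaluation

Power is the fraction of simulated datasets whose selected set equals
exactly the true disease loci with zero false positives; the relaxed
variant tolerates up to two false positives. LD tags count as false
positives — they are associated with the loci, not the disease. Replicate
seeds derive deterministically from (master seed, cell index, replicate),
so any cell can be re-run in isolation.

A caveat documented here because it shapes expectations: with λ = 0.3 the
per-allele case-control odds ratio is 1.3, and at 1000 cases + 1000
controls the resulting per-locus G noncentrality (≈ 12 at MAF 0.2) caps
exact-pair recovery for *any* detector well below the levels sometimes
quoted for settings described this way — an exhaustive pair-scoring oracle
told there are exactly two causal loci recovers the pair in only about a
quarter of such datasets. The harness reports what the stated data-
generating process actually supports; at these effect sizes that is
near-zero power below MAF 0.2 and partial power above it, rising steeply
with λ.

## Numerical choices and edge cases

* 0·ln 0 ≡ 0 throughout; a cell with E = 0 necessarily has N = 0 (zero
  margin), asserted rather than special-cased.
* G-test p-values come from the upper χ² tail at the corrected df; no
  continuity correction.
* Rows with a missing genotype are dropped per computation
  (complete-case); the simulator produces no missingness.
* Greedy ties are resolved by candidate rank then column index, making
  every run bit-reproducible for identical inputs.
* The (α, θ) solver refuses infeasible targets (non-convergence or
  residuals above 1e-8 raise); λ = 0 short-circuits to θ = 0,
  α = p/(1−p).
* The baseline greedy search (`run_bneat`) uses first-improvement scans in
  column order deliberately: it is the order-sensitivity foil, not a tuned
  competitor, and its numbers should be read only as a stability contrast.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the study at its native scale
— 50 datasets per setting, 2000 samples × 102 markers — except where a
property is scale-free (solver identities, haplotype algebra, score
invariances), which run on small instances. The order-robustness check
uses 20 datasets × 5 permutations; the greedy-vs-exhaustive comparison
restricts to instances with ≤ 8 candidates so the exhaustive oracle stays
exact.
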