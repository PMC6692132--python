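# mutdfe

Analysis toolkit for the **distribution of fitness effects (DFE)** of
single-nucleotide substitutions in a bacterial gene, built around the kind of
mutagenesis study in which every synonymous, nonsynonymous and nonsense point
mutant of a gene (e.g. *gtsB* of *Pseudomonas fluorescens* SBW25) is competed
head-to-head against a marked ancestor in defined medium.

It is aimed at experimental-evolution and molecular-evolution researchers who
have (or want to simulate) four kinds of data:

1. **competition colony counts** per replicate (initial/final plates of
   mutant vs reference),
2. a **coding sequence** and its list of point mutations,
3. per-mutation **covariates** — relative transcript level from reporter
   fusions, ΔCAI/ΔtAI, ΔMFE of folding windows, promoter-strength scores,
4. a **phylogeny** of related strains with binary presence/absence of each
   mutation at the tips.

## What it computes

**Relative fitness.** Per replicate, `w = (f_final / f_initial)^(1/d)`, where
`f` is the mutant:reference frequency ratio on a plate and `d` the number of
doublings; plates with fewer than 30 colonies of either strain are excluded.
Per mutation: mean, SEM, replicate provenance, plus a marker-control estimate.

**DFE comparison.** Two-sample Kolmogorov–Smirnov D between the synonymous
and nonsynonymous DFEs (s = w − 1), with a permutation p-value from shuffling
pooled class labels (default B = 10,000, add-one convention).

**Beneficial-tail characterisation.** Beneficial selection coefficients are
shifted to the smallest observed value and fitted by maximum likelihood to
the Generalised Pareto Distribution

&nbsp;&nbsp;&nbsp;&nbsp;ℓ(τ, κ) = −n log τ − (1 + 1/κ) Σᵢ log(1 + κxᵢ/τ),

with κ < 0 the Weibull domain (bounded tail — a local fitness optimum),
κ = 0 Gumbel (exponential) and κ > 0 Fréchet. A likelihood-ratio test
against the exponential null (κ = 0, τ̂ = x̄) gets its p-value from a
parametric bootstrap.

**Covariate regressions.** OLS with permutation-of-residuals inference
(reduced-model/Freedman–Lane scheme) for fitness vs ΔCAI, ΔtAI, distance
from the start codon, transcript level, etc.; CAI (Sharp & Li weights from a
reference gene set) and tAI (dos Reis weights from tRNA gene copy numbers)
are computed internally; a translational-ramp test checks rare-codon
enrichment in the first 50 codons.

**Phylogenetic presence.** Polytomies are resolved into an ensemble of 100
random bifurcating trees; two-pass Fitch parsimony counts independent
origins of each mutation; a binomial GLM relates presence (mutant observed
*and* ≥ 1 inferred origin) to log w.

**Synthetic data.** `mutdfe.simulate` generates every input above from one
seeded config — mixture DFE with an exact GPD beneficial tail, binomial
colony sampling, linear expression–fitness link, fitness-linked tip
states — so the whole pipeline is testable without laboratory data.

## Worked example

```bash
mutdfe pipeline run --seed 1 --outdir demo
```

runs simulate → fitness → DFE → covariates → regressions → phylogeny and
writes `demo/report.json`. With the default configuration (39 synonymous,
65 nonsynonymous, 6 nonsense mutations; 6 replicates of 200 colonies;
planted tail τ = 0.05, κ = −0.35):

```python
>>> import json
>>> r = json.load(open("demo/report.json"))
>>> r["dfe"]["n_by_class"]
{'synonymous': 39, 'nonsynonymous': 71}
>>> round(r["dfe"]["tail_test"]["free_fit"]["kappa"], 3)
-0.465
>>> r["dfe"]["evt_domain"]
'Weibull'
>>> round(r["phylo"]["model"]["slope"], 1)
13.6
```

Reading: nonsense mutations are merged into the nonsynonymous DFE (65 + 6 =
71); the fitted tail shape κ̂ = −0.465 is the maximum-likelihood estimate
from the ~56 beneficial mutations of this run (the planted truth is −0.35;
at this sample size the sampling SD of κ̂ is ≈ 0.09), and its negative sign
puts the beneficial DFE in the Weibull domain — evidence of a bounded
adaptive landscape; the positive presence slope means higher-fitness
mutations are more likely to be segregating among related strains.

Equivalent library calls: `mutdfe.run_pipeline(RunConfig(...))`, or the
stage functions (`estimate_fitness_table`, `ks_compare`, `fit_gpd`,
`lrt_exponential`, `permlm`, `PresenceAnalysis`, ...).

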