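# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mutdfe`, in the order the pipeline runs them.

## Fitness from competition counts

Each replicate competition mixes a mutant 1:1 with a neutrally marked
reference, grows the culture for `d` doublings, and plates initial and final
aliquots. With `f` the mutant:reference frequency ratio on a plate,

    w = (f_final / f_initial) ** (1 / d).

`w` is a per-doubling relative growth rate: `w = 1` is neutral,
`s = w − 1` the selection coefficient. Assumptions: the marker is neutral
(a marker-control competition is estimated with the same code path; an
opt-in flag divides mutant fitness by the control mean, off by default
because the control is conventionally reported rather than corrected for),
frequencies change deterministically between plates, and plate counts are
the only sampling noise. Replicates are technical; the per-mutation
estimate is the arithmetic mean with SEM = sd/√n (n = 1 leaves SEM as NaN,
and fewer than 4 surviving replicates warns). Inclusion filter: ≥ 30
colonies of *each* strain on *each* plate (`min_colonies`, default 30);
zero counts always exclude a replicate. Exclusions are logged per mutation,
and a mutation whose replicates are all excluded is reported with NaN
fitness, never silently dropped. `d` is a per-replicate input column; 6.7
and 13.2 (the two usual dilution regimes) are provided as named presets.

Exact inversion: for noiseless counts generated from any `(w*, d)` the
formula returns `w*` to machine precision (property-tested), so estimator
bias comes only from plate sampling.

## DFE construction and comparison

Classes come from codon translation (table 11): synonymous, nonsynonymous,
nonsense. For DFE comparison, nonsense rows are by default merged into the
nonsynonymous sample — they are an extreme amino-acid-level change and the
published class sizes pool them that way (65 + 6 = 71 vs 39) — while the
beneficial-tail and covariate analyses always exclude them (no complete
protein). `include_nonsense=False` drops them everywhere.

The two-sample Kolmogorov–Smirnov D is given a resampling p-value by
shuffling the pooled class labels (B = 10,000 by default), the standard
exchangeability construction; `method="bootstrap"` resamples pooled values
with replacement instead, since "bootstrapping the K-S statistic" is used
loosely in the literature. p-values use the add-one convention
`(1 + #exceed)/(B + 1)` and are never 0. The null permutations are drawn
against a canonical label vector marking the smaller sample, which makes
the result exactly invariant under swapping the two samples at fixed seed.

## Beneficial tail: GPD likelihood and LRT

Beneficial mutations default to `w_mean > 1` (no significance filter; the
published count of 55 beneficial mutations implies the same rule). The
threshold is shifted to the smallest beneficial `s`; the minimal (now zero)
observation is dropped from the likelihood by default — at the threshold it
carries no tail information — and `drop_minimum=False` keeps it.

The Generalised Pareto log-likelihood (scale τ > 0, shape κ; κ < 0 =
Weibull/bounded, κ = 0 = Gumbel/exponential, κ > 0 = Fréchet) is maximised
by the profile in η = κ/τ: for fixed η the inner maximiser is
κ̂(η) = mean(log(1 + ηxᵢ)), leaving a one-dimensional profile that is
scanned on a sorted 120-point log-spaced grid on both sides of 0 (the
negative side runs from near 0 down to the feasibility bound −1/max x) and
polished by bounded Brent search between the best grid point's neighbours.
Grid coverage near η → 0 matters: a sparse grid there biases small-|κ|
fits toward exactly κ = 0 and makes the LRT conservative. Explicit
candidates κ = 0 (τ̂ = x̄, closed form) and the κ = −1 boundary (uniform
density, τ̂ = max x) are always compared. The search is restricted to
κ ≥ −1 because the likelihood is unbounded for κ < −1 (the usual MLE
regime); fits at the −1 boundary are reported as such. For κ̂ < 0 the
fitted support bound max x ≤ −τ̂/κ̂ holds by construction and is
property-tested, as is dominance of the returned likelihood over a dense
(τ, κ) grid.

The likelihood-ratio statistic LR = 2(ℓ_free − ℓ_exp) is referred to a
parametric bootstrap: simulate `n_tail` draws from Exponential(τ̂_exp),
refit both models, add-one p-value (LR is scale-invariant, so the null
does not depend on τ̂). A χ²₁ p-value is reported alongside for reference
only. The EVT domain call is the sign of κ̂ with a configurable zero band
(default |κ̂| < 10⁻³ reported as Gumbel-indistinguishable). Calibration:
under an exponential truth at n = 54 the bootstrap test rejects at the
nominal 5% (verified by simulation in the acceptance suite).

## Codon covariates

- **CAI** (Sharp & Li): relative-adaptiveness weights
  `w_c = count_c / max(family count)` from a user-supplied highly expressed
  reference gene set (ribosomal protein genes in the motivating study);
  zero counts are smoothed to 0.5 (seqinr's convention) so no weight is 0;
  single-codon families (Met, Trp) and stops are excluded; CAI is the
  geometric mean of the remaining per-codon weights.
- **tAI** (dos Reis): per-codon absolute adaptiveness
  `W_c = Σ (1 − s) × copies` over decoding anticodons under Watson–Crick
  plus wobble rules with the standard published penalties (sG:U = 0.41,
  sI:C = 0.28, sI:A = 0.9999, sU:G = 0.68, lysidine C:A = 0.89 for
  bacterial AUA); relative weights are `W_c/max W`, zero-weight codons get
  the geometric mean of the nonzero weights, and tAI is the geometric mean
  over the gene. Per-species re-optimisation of the penalties (the stAI
  approach) is out of scope; the defaults are a documented limitation.
- **Δ metrics**: mutant-CDS metric minus reference-CDS metric, so a
  synonymous swap's ΔCAI depends only on the two codons and the number of
  included codons (closed form, tested). Distance from the start codon is
  `cds_position − 1` nt.
- **mRNA windows**: `width` nt (default 42) centred on the mutated base;
  for even widths the mutated base sits immediately right of centre
  (positions p − 21 … p + 20), a convention choice the window metadata
  records along with any truncation at sequence ends. Folding energies
  themselves are *not* computed — ΔMFE from an external folding tool is
  consumed as an input column.
- **Ramp test**: both a regression of per-codon weight on codon index
  (permutation p) and a first-50-codons vs remainder pooled-variance
  t-test are reported, since "rare-codon enrichment near the start" can be
  formalised either way.

## Permutation-of-residuals regression

The reduced-model (Freedman–Lane) scheme: to test a term, fit the model
without it, permute those residuals, add them back to the reduced fitted
values, refit the full model, and compare |t| of the term (add-one p).
Permuting the raw response is available (`scheme="raw"`). The permutation
refits are vectorised (one pseudo-inverse application for all B
pseudo-responses). Zero residual variance is detected against a
scale-relative tolerance and resolved to t = 0 (null coefficient) or ±∞
(perfect fit). p-values are invariant to affine rescaling of response and
predictors at fixed seed, and converge to the classical t/F p for Gaussian
models (both property-tested). Missing covariate rows are dropped listwise
with a logged count. Reported R² is the adjusted R².

Plate-reader expression: the reporter signal is background-strain-
subtracted fluorescence, maximised over the series (the peak is found, not
fixed at a nominal time), divided by blank-corrected OD at the peak time,
then standardised by the wild-type value. Non-positive corrected OD at the
peak rejects the record with a reason.

## Phylogenetic presence

Branch lengths are ignored (parsimony). Polytomies are resolved by
sequential random pairing of children, independently per polytomy, into an
ensemble of `n_resolutions` (default 100) strictly bifurcating trees;
all sites are scored on the same ensemble. Two-pass Fitch: bottom-up
intersection/union gives the parsimony score (verified against exhaustive
enumeration of internal labelings on ≤ 8-tip instances); the top-down pass
resolves one most-parsimonious reconstruction by inheriting the parent
state wherever it lies in a node's state set — the delayed-transformation
choice, which guarantees the branch-transition total equals the Fitch
score on every instance (tested). An ambiguous root resolves to the
ancestral state. Among equally parsimonious reconstructions only the
branch *attribution* differs, never the total; an accelerated-
transformation attribution was considered and not implemented because,
for ambiguous binary state sets, resolving against the parent can exceed
the minimum change count — the delayed rule is the one with the
correctness guarantee.

Per site, the summary records mutant tip count, mean/min/max transition
count over the ensemble, ancestral-state frequency for each internal node
of the *input* tree (tracked across resolutions by descendant-leaf set),
and two presence indicators: raw tip occurrence, and the
relatedness-aware rule (occurrence *and* mean inferred origins ≥ 1). Both
are emitted because "presence while accounting for common ancestry" has no
unique formalisation; the origin rule is the model default.

The presence–fitness model is a binomial GLM of presence on log w (a
linear-w variant is a flag; the logarithmic link matches a "logarithmic
relationship" between presence probability and fitness), with a
likelihood-ratio p against the intercept-only model and an optional
label-permutation p. Complete separation is detected (diverging
coefficients or non-finite standard errors) and reported, with an
L2-penalised logit as the flagged fallback.

## Synthetic-data generator

One master seed feeds named substreams (gene, mutations, DFE,
competitions, expression, tree, states, reference, tRNA), so identical
configs give byte-identical files.

What it emulates, and the defaults chosen as study conditions:

- **Mutation set**: a random valid CDS (default 303 sense codons; start
  codon ATG/GTG/TTG, no internal stops) and 39/65/6
  synonymous/nonsynonymous/nonsense substitutions sampled from the
  exhaustively enumerated, classified possibilities.
- **True DFE**: beneficial with probability 0.53 (≈ the 55/104 observed
  beneficial fraction), beneficial s drawn *exactly* from
  GPD(τ = 0.05, κ = −0.35) — the Weibull-domain tail the analysis is meant
  to recover; non-beneficial s is a Gaussian mixture truncated to (−1, 0]
  (a near-neutral half-normal, sd 0.02, and with weight 0.35 a deleterious
  normal at −0.05 ± 0.03), giving the observed mode near w = 1; the paper
  gives no parametric family for the non-beneficial DFE, so any family
  with that shape serves. Nonsense effects are the deleterious component
  shifted by −0.10 (mean s = −0.15): strongly deleterious yet still above
  the 30-colony inclusion filter at the default plate size, as in the
  study, where every mutant received an estimate.
- **Competitions**: 6 replicates; plated initial mutant counts are
  Binomial(200, 0.5) (the 1:1 mix), final counts Binomial(200, f₁) with
  f₁ = f₀wᵈ/(f₀wᵈ + 1 − f₀) the deterministic growth outcome of the
  plated initial frequency; d = 6.7. Binomial plate sampling is a modelling
  choice — counts are reported without a noise model in this kind of
  study — and per-plate colony totals are config knobs, not claims (200 is
  a plausible plate). A neutral marker-control competition is appended.
- **Expression**: relative transcript level = −9 + 10·w + N(0, 0.286²);
  the noise is set by closed form so the expected expression–fitness
  adjusted R² over synonymous mutants matches the published ≈ 0.69.
- **Tree and tip states**: a 77-tip random topology with ~30% of internal
  nodes collapsed into polytomies (disjoint edges, so the polytomy count
  is the rounded fraction); presence on ≥ 1 tip with probability
  logistic(−0.6 + 15·log w) (≈ 10% at w = 0.9, ≈ 70% at w = 1.1); carriers
  are scattered uniformly (1 + Binomial(n − 1, 0.05) tips), at the pattern
  level rather than by sequence evolution, because the analysis consumes
  only binary states.
- **Reference set / tRNA table**: 20 codon-biased genes (preferred codon
  odds 8:1 per family) and a Poisson-ish anticodon copy table repaired to
  decode every sense codon — enough structure for informative CAI/tAI
  weights.

What it does **not** emulate: batch effects and day-to-day variation in
competitions, non-neutral marker costs, reporter maturation kinetics
(only endpoint expression), linkage between mutations and real codon
usage of any particular genome, and tree non-independence of sites.
Passing tests therefore demonstrate estimator correctness and calibration
under the stated noise models, not robustness to those real-data
features.

## Problem sizes and runtime choices

Defaults reproduce the published analysis settings (B = 10,000
permutations, 10,000 LRT null simulations, 100 resolutions). The test
suite scales Monte-Carlo studies to what its statistical tolerances need:
calibration checks use 99–199 inner resamples with 400–1,500 outer
repeats, parameter-recovery checks use n = 10,000 draws, and the
end-to-end test runs the pipeline at reduced resampling depths. The
acceptance script runs everything at the full defaults.

## Known limitations

- GPD inference assumes an i.i.d. tail; measurement error in w (SEM per
  mutation) is not propagated into the tail likelihood.
- The MLE regime excludes κ < −1; tails even shorter-bounded than the
  uniform are reported at the boundary.
- tAI penalties are the universal constants, not species-optimised.
- The parsimony presence rule treats sites independently; shared branches
  induce correlation the binomial GLM ignores (the permutation p is the
  more defensible of the two).
- `process_expression` expects one averaged series per strain; replicate
  wells are averaged upstream.
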