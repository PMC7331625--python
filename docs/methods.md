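# Methods

## Estimators

All entropies are in nats. For an observed allele-count vector
`x₁ … x_k` with `n = Σ xᵢ` gene copies, `f₁`/`f₂` singleton/doubleton
alleles and `p̂ᵢ = xᵢ/n`:

* **Plug-in (`H_MLE`)** `−Σ p̂ᵢ ln p̂ᵢ`. Negatively biased at small `n`
  (expected shortfall ≈ `(k−1)/2n` plus higher-order terms).
* **Zahl jackknife (`H_Z`)** `n·Ĥ − (n−1)·H̄₍·₎`, where `H̄₍·₎` is the
  average plug-in entropy over the `n` leave-one-copy-out samples. The
  implementation groups leave-outs by allele (removing any copy of allele
  `i` yields the same configuration), giving an `O(k)` closed form that
  tests verify against the literal `n`-fold recomputation for every count
  configuration with `n ≤ 12`. The jackknife can exceed `ln k`.
* **Chao–Shen (`H_CS`)** Horvitz–Thompson with Good–Turing shrinkage:
  coverage `Ĉ = 1 − f₁/n`, adjusted frequencies `p̃ᵢ = Ĉ p̂ᵢ`, estimate
  `Σ −p̃ᵢ ln p̃ᵢ / (1 − (1−p̃ᵢ)ⁿ)`. When every allele is a singleton
  (`f₁ = n`) the coverage is zero and the estimator is undefined; the
  package raises a dedicated `ChaoShenFailure` signal that batch code
  records as a missing value rather than aborting. This is the
  mathematically forced failure set; other implementations fail on a
  superset of it (via nested richness estimation), so failure *counts*
  are comparable only qualitatively.
* **Chao–Wang–Jost 2013 (`H_Chao`)**
  `Σ (xᵢ/n)(H_{n−1} − H_{xᵢ−1}) + (f₁/n)(1−A)^{1−n}[−ln A − Σ_{r=1}^{n−1}(1−A)^r/r]`
  with harmonic numbers `H_m` and
  `A = 2f₂/((n−1)f₁ + 2f₂)` when `f₂ > 0`,
  `A = 2/((n−1)(f₁−1) + 2)` when `f₂ = 0 < f₁`, and a vanishing tail when
  `f₁ = 0`. Harmonic numbers are accumulated once (`O(n + k)`); plain
  double precision throughout; `0·ln 0 = 0` wherever a probability
  vanishes.
* **Gene diversity (`Hs`)** `1 − Σ p̂ᵢ²` (Nei), the reference measure.

A vectorised re-implementation of the same formulas evaluates whole
stacks of resampled count vectors at once; unit tests pin it to the
scalar functions at `1e-12`.

## Coalescent simulator

Each locus is an unlinked microsatellite evolved on a Kingman coalescent
with per-generation pairwise rate `1/(2N)` inside each epoch of a
backward-in-time piecewise-constant diploid size history (exponential
waiting times truncated at epoch boundaries, which is exact by
memorylessness). Mutations are a Poisson process at rate `μ` per gene
copy per generation on every branch; each mutation steps the allele
state ±1 with equal probability within `[0, k_max−1]`. Tips are paired
consecutively into diploid genotypes — coalescent tip labels are
exchangeable, so this is a random union of gametes.

Parameters and defaults (the study design):

| parameter | default | meaning |
|---|---|---|
| `μ` | 1e-4 … 1e-3 /copy/generation | single-step mutation rate (4 design values) |
| `k_max` | 3 … 20 | number of allelic states allowed (6 design values) |
| `N` | 10,000 diploids | population size at sampling, and ancestrally |
| bottleneck | 500 / 50 / 20 for 20 generations | 20 generations before sampling, preceded backward by a return to 10,000 |
| sample | whole population (20,000 gene copies) | parametric reference basis |

Design choices made where the design was genuinely open:

* **Boundary rule.** A step leaving the allowed range is *discarded*
  (state unchanged). The alternative — reflecting off the range wall —
  is implemented behind `SimulationConfig(boundary="reflect")`; at the
  design's rates the two differ by under 0.01 in mean whole-population
  entropy, so the choice is immaterial in practice.
* **Root state** is `k_max // 2`, centring the bounded walk so the cap
  binds symmetrically. For slow loci the walk does not mix over the full
  range within a genealogy's depth, so the allele cloud stays near the
  root state; centring maximises the usable range on both sides.
* **Pure single-step mutation** — no geometric multi-step component.
* **Independent scenarios.** The four populations are simulated
  independently with the same ancestral size; shared ancestry above the
  bottleneck would not change within-population statistics, the only
  quantities analysed.
* **Continuous time.** The discrete Wright–Fisher generations are
  approximated by the continuous-time coalescent even when the number of
  lineages approaches `2N` (whole-population sampling). The error this
  induces in total recent branch length contributes ≲ 0.002 nats to
  whole-population entropy at the fastest design rate.

Validation: the simulator reproduces (i) the Ohta–Kimura identity
probability `1/√(1+2θ)` for unbounded stepwise mutation, (ii) closed-form
mean pair-coalescence times through bottleneck demographies, and
(iii) msprime's independent bounded stepwise (microsatellite) mutation
model for matched parameters — all as tests.

## The experiment

Per replicate and scenario the whole population is simulated once and the
parametric value of every metric is computed per locus and as the
arithmetic mean over loci. For each sample size `Ns ∈ {5, 20, 80, 200}`,
500 independent without-replacement samples of whole genotypes are drawn
(Floyd's algorithm; draws are shared across loci, as sampling
individuals implies). Then:

* `rB = (Ĥ − H)/H` is computed once per metric/scenario/size/replicate
  from the **first** resample — deterministic and independent of later
  draws; the design does not say which of the 500 draws to use.
* `MRSE = mean((Ĥᵢ − H)²/H)` over the non-missing resamples — note the
  denominator is `H`, not `H²`, matching the definition as printed; the
  count of contributing resamples is recorded alongside.
* `SD` is the standard deviation (ddof = 1) of the mean-over-loci
  estimate across the non-missing resamples.
* A mean-over-loci `H_CS` is missing whenever any locus failed; missing
  values are excluded, counted, and reported.

SD distributions are compared pairwise by drawing 100,000 independent
value pairs: the reported `p` is the fraction of pairs ordered against
the observed difference of means (one-sided; ties count against
rejection; floored at 1/100,000). These tie/sidedness rules are this
package's own — the procedure is otherwise underdetermined.

Summary tables aggregate mean-over-loci values across replicates:
whole-population min/median/max per scenario (with cells at the smallest
sample size excluded from the SD summary wherever resampling failures
occurred), and pooled min/median/max `rB` per sample size. The per-locus
MRSE export carries (metric, scenario, sample size, replicate, locus,
whole-population `He` of the locus, MRSE), which is sufficient to refit
the study's downstream regression models externally; those fits are out
of scope here.

Seeds derive from a single master seed through counter-based
`SeedSequence` keys `(replicate, scenario, stage, …)`, so replicates are
bit-reproducible independently and in any execution order.

## Problem sizes

The full design is 24 loci × 4 scenarios × (4 sizes × 500 resamples + 1
parametric) × 1000 replicates = 192,096,000 estimation events per metric;
the dry-run counter reports exactly this. The package's scaled preset
runs the identical design at 100 replicates (~2–4 minutes on one CPU),
which is what the acceptance script and the end-to-end tests use; medians
and means of `rB` and `SD` are stable at that scale (their Monte-Carlo
standard errors are an order of magnitude below the tolerances checked).

## What the generator does and does not emulate

The synthetic populations carry realistic microsatellite features —
bounded allelic ranges, mutation-rate heterogeneity across loci,
bottleneck-shaped allele-frequency spectra — but no genotyping error, no
missing data, no null alleles, no linkage, and no departures from
random mating. Conclusions about estimator rankings transfer to real
data only to the extent that those complications act similarly on all
estimators.

## Known limitations

* Under the stated conditions (pure bounded single-step mutation,
  N = 10,000) the whole-population diversity level sits ~5–7% below the
  original study's reported medians (e.g. control-scenario mean-over-loci
  plug-in entropy ≈ 1.55 vs 1.67), while agreeing closely with an
  independent simulator (msprime) under identical assumptions. The
  original fastsimcoal2 configuration evidently contained an additional
  diversity-raising detail (for example a non-zero multi-step mutation
  component) that is not recoverable from its description; the rates and
  caps here are kept exactly as stated rather than adjusted to match.
  Relative quantities — bias medians, SD levels, failure patterns,
  error orderings — are insensitive to this level shift and reproduce
  the original values closely.
* The Chao–Shen failure condition here is exactly `f₁ = n`; failure
  *counts* in other implementations are larger for incidental reasons,
  so only the failure *pattern* (smallest samples, most diverse
  populations) is comparable.
* The coalescent is pairwise-merger only; for whole-population samples
  the first few generations of the true discrete-generation process are
  slightly mis-timed (quantified above and negligible here).
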