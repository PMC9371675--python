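# Methods

## Model structure

The simulator is a discrete-generation, separate-sex Wright–Fisher model of a
single drive locus containing m gRNA target sites, with no recombination
between sites and no positional effects. A chromosome is either the drive
construct D (copied as a unit, never mosaic) or a multiset of m site alleles
from {W, R, N}; there are C(m+2,2)+1 haplotypes and H(H+1)/2 diploid
genotypes. Haplotypes are indexed lexicographically on the sorted allele
string (W < R < N) with D last; genotypes use the flattened upper-triangle
index. These orderings fix all output columns.

Each generation:

1. **Gamete pools.** Per-genotype gamete distributions are precomputed once
   per parameter set. In genotypes pairing a non-drive haplotype (r resistant
   sites) with D, each of the m−r W sites independently resolves to homing
   (ε(1−ν)), NHEJ→R (ενβ), NHEJ→N (εν(1−β)) or intact (1−ε); any homing event
   converts the chromosome to D, so the non-drive gamete fraction is
   ½[1−ε(1−ν)]^(m−r). Conversion operates in the germlines of both sexes.
   After conversion, every W site of every non-drive gamete class mutates to
   R with probability ξμ and to N with (1−ξ)μ; multi-site mutation terms are
   kept exactly (they are cheap and matter for m-fold classes), and D neither
   cleaves itself nor mutates. Back-mutation is absent: resistant alleles are
   assumed to abolish cleavage completely and no reverse rates are modelled.
   Sex-specific mean pools weight each parent equally within its sex
   (viability selection has already acted).
2. **Offspring.** Genotype probabilities follow from random union of one
   male and one female gamete. The offspring total is Poisson around the
   Beverton–Holt mean M = 2R_m F/(1+(R_m−1)N_t/K), whose all-wild-type fixed
   point is K and whose low-density per-capita growth is R_m (default 6,
   typical of strongly fecund insect vectors; config-overridable). A
   deterministic-total mode exists for pure Wright–Fisher calibration tests.
3. **Survival selection.** Offspring are assigned (sex, genotype) and female
   survival simultaneously in one categorical draw with categories
   {male genotype: ½p_g} ∪ {female genotype: ½p_g w_g} ∪ {non-surviving
   remainder}, so counts are conserved exactly. Males have fitness 1; female
   fitness is the product over sites of per-pair factors anchored at
   (W,W)=1, (W,R)=1−σ, (W,N)=1−h_N s, (W,D)=1−hs, (N,N)=(D,D)=1−s. Pairs not
   fixed by those anchors are set to (R,D)=1−σ (an R copy cannot be cut, so
   it escapes the somatic-cleavage cost that h represents), (R,R)=max(0,1−2σ)
   (additive copies), (R,N)=(1−σ)(1−h_N s); all four are overridable through
   `fitness_overrides`. When two mosaic haplotypes meet, their canonical
   (sorted) allele vectors are aligned position-wise; the model tracks
   multisets, so some pairing convention is unavoidable, and the sorted
   alignment is deterministic and symmetric. It only affects rare
   double-heterozygous mosaic genotypes.
4. **Endpoint.** Resistance when the summed frequency of fully resistant
   haplotypes (R/N at all m sites) over all adult chromosomes of both sexes
   reaches 0.95; elimination when either sex has zero adults; censoring at
   `max_generations` (default 1000 — resistance and elimination both resolve
   well under 100 generations in the regimes studied, so censoring is rare
   and always reported, never dropped).

Drive release replaces uniformly chosen males by D/D homozygotes so the D
allele frequency among male chromosomes equals `release_freq` (default 0.1);
females are untouched. Releasing homozygotes is the natural reading of "an
allele frequency of 0.1 in males"; heterozygote release can be emulated via a
custom initial state.

## Hybrid Poisson–Gaussian sampling

The categorical draw above is the only O(N) operation in a naive
implementation. For totals above `exact_sampler_cutoff` (default 10⁶; below
it numpy's exact multinomial is used) the sampler splits categories at
expected count `threshold` (default 10): rare categories are independent
Poisson(Nx_k) — their drift is effectively independent — while common
categories are drawn from the multivariate Gaussian with mean N′x′ and
covariance N′x′_i(δ_ij−x′_j), conditioned on N′ = N − Σ(rare draws). The
Gaussian block drops the largest-frequency category (restoring full rank),
samples by Cholesky, rounds to integers, clamps negatives, and assigns the
dropped category the remainder; a negative remainder is repaired by
decrementing the currently largest counts. If rare Poisson draws ever exceed
N in total, the rare block is redrawn (up to 100 times) and then fails
loudly — silent truncation would bias frequencies. Means are stored as
doubles, so totals are reliable to ~10¹⁵. Validation: exact total
conservation at N = 10¹², marginal means within 0.1%, variances at the
sampling-noise floor, and two-sample KS agreement with the exact sampler for
categories straddling the threshold.

## Standing variation and burn-in

With `standing_variation` enabled, each replicate first runs
⌈burn_in_multiplier/σ⌉ generations (default multiplier 1) from an
all-wild-type population with mutation and selection but no drive, so the
R-frequency distribution at release is drawn implicitly from
mutation–selection–drift balance.

Because fitness costs act on female survival only, the sex-averaged selection
against an R copy is σ/2. The equilibrium of this model is therefore a mean R
frequency of 2ξμ/σ and, for strong selection, a frequency distribution close
to Gamma(shape 4Nξμ, rate 2Nσ) — not the Gamma(4Nξμ, 4Nσ) law that applies
when the cost is expressed in both sexes. The test suite verifies the
female-limited law directly (KS test over replicate endpoint frequencies at
N = 10⁷, σ = 0.01, burn-in multiplier 8, i.e. four relaxation times of the
distribution; the default 1/σ burn-in reaches ≈63% of the equilibrium mean
and is kept as the standard pre-release condition).

## Theory layer

Closed forms implemented exactly as stated in the module docstring of
`theory.py`, with calibration defaults γₙ = 0.2, γₘ = {0.76, 6, 55} for
m = 1..3 (extrapolated as s_b τ^m with s_b = 0.09, τ = 8.5 beyond), γ = 2 and
s_b = 0.5. Minimal-m calculators invert the critical sizes by brute-force
integer search (authoritative) and by the closed forms — the NHEJ power-law
inversion and, for standing variation, the Lambert W₋₁ expression obtained
after replacing ln(1+s_b/(mσ)) by its m = 1 value; the W₋₁ branch is
evaluated by scipy. When γξμ/σ ≥ 1 additional gRNAs no longer raise the
standing-variation critical size and the brute search raises an explicit
error; when the W argument leaves [−1/e, 0) the closed form falls back to
brute force with a warning. The sigmoid fit maximises the binomial likelihood
of per-N resistant counts over log N* (replicate outcomes are Bernoulli, so
least squares would mis-weight the tails) with a profile-likelihood CI;
all-zero/all-one tables are flagged as boundary cases.

## Reproducibility and problem sizes

Every stochastic path takes an explicit numpy Generator. Replicate streams
derive from `SeedSequence(base_seed, spawn_key=(grid_index, replicate))`, so
a (config, base_seed) pair fixes every draw and batches parallelise without
stream overlap. The test suite and acceptance script use reduced designs
chosen to keep statistical power while running quickly on one CPU: 100–200
replicates per N over 5–7 grid points for sigmoid fits (the fitted γₙ then
carries ≈10% binomial noise), 100 replicates for conditional
time-to-resistance, 40–50 burn-in replicates for distributional tests, and
8000 draws for sampler moment checks.

## Known limitations

No spatial structure, migration or inbreeding feedback; no recombination
between target sites or off-target cleavage; no error-prone homing or gRNA
loss; no age structure, seasonality or historical bottlenecks; cleavage
probability per site is independent of m. The synthetic populations are
ideal Wright–Fisher demes — real vector populations add overdispersed
reproduction and spatial substructure that rescale effective N, so passing
tests validate the model's internal calibration, not field predictions.
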