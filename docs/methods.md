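# Methods

## The inference problem

`sigmanet` estimates the mean per-generation dispersal distance σ — the
root-mean-square displacement along one axis between a child's birth
location and that of a randomly chosen parent — from a single spatial
sample of SNP genotypes.  The estimator is simulation-based: a
convolutional network is trained on data simulated from a spatially
explicit population model in which σ is known, then applied to held-out
simulated data or to empirical genotype matrices.  Only two inputs reach
the network: the genotype matrix itself and the sampling width (the
largest pairwise distance among sampled individuals); individual
coordinates are never used.

## The spatial population model

Hermaphroditic diploid individuals live on the square `[0, W]²`.  One time
step (a generation; generations overlap) has three stages:

1. **Reproduction.**  Every individual acts as mother once per step.  A
   mate is drawn among neighbours within `3σm`, with weight given by the
   Gaussian density `g(d/σm)`; an individual can therefore mother its own
   brood and father others' in the same step.  Selfing is excluded, and a
   mother with no neighbour in range skips the step.  The brood size is
   Poisson with mean `1/L` (default `L = 4`, the mean-lifetime parameter).
   Each offspring lands at the mother's location plus independent
   `N(0, σf)` displacements per axis; offspring proposed outside the
   habitat are not born and are not replaced.
2. **Mortality.**  Individual *i* survives with probability
   `min(0.95, 1/(1 + n_i/(K(1+L))))`, where `n_i` is the local density
   around *i* measured with a Gaussian kernel of scale `σc` truncated at
   `3σc`.  Fitness declines near the habitat boundary: survival is further
   multiplied by `min(1, sqrt(d_edge/σc))`, which reduces, but does not
   remove, edge effects.
3. **Recording.**  Census size, a per-step inbreeding effective size, and
   the effective-dispersal accumulators are updated.  Newborns join the
   population at the end of the step; they do not mate, compete, or die in
   the step of their birth.

Reproduction and mortality both use start-of-step positions, mate pools
and densities, so within-step event order cannot create density
artefacts.  Extinction is a reportable outcome (`extinct_at`), not an
exception, matching how failed replicates are excluded from training sets
rather than treated as errors.

### Density normalisation

The literal per-neighbour kernel weight is the standard normal density of
`d/σc` (this is what `local_density` returns, and what its unit tests pin
down).  Feeding that raw sum to the survival rule would make the
equilibrium density scale like `1/σc²`: halving the interaction scale
would quadruple the population.  The observed behaviour of this model
family is different — the equilibrium census tracks `K·W²` regardless of
the kernel scale, which is only possible if the competition kernel is
normalised to unit area.  The step function therefore divides the summed
weight by `sqrt(2π)·σc²` (equivalently, uses the 2-D Gaussian density
`exp(-d²/2σc²)/(2πσc²)`) before applying the survival rule.  With `L = 4`
the equilibrium census settles near `1.3–1.5 × K·W²` for interior-dominated
habitats, and the σc-insensitivity experiment (below) is well defined
because both members of a pair are demographically stable.

### Effective dispersal and the √(3/2) correction

σf alone understates gene movement because the father is displaced from
the mother by the mating kernel.  The mean squared per-axis displacement
between a child and a random parent is `σf²` (mother) averaged with
`σf² + σm²` (father), i.e. `(3/2)σf²` when `σf = σm`.  The simulator also
tracks realised *effective* dispersal: each individual records
`d_i²`, its natal squared displacement averaged over both parents and both
axes, and the tracked effective σ is `sqrt(Σ d_i² f_i / Σ f_i)` with `f_i`
the lifetime offspring count — dispersal weighted by reproductive success.
Founders have no parents and are excluded from both sums; note that every
birth increments two parents' counts, so `Σ f_i` equals twice the number
of recorded births.  Training targets are `log σf`; predictions are
exponentiated and multiplied by `sqrt(3/2)`.  Two small systematic
deviations from the closed form are expected and visible in the tests: the
mating kernel is truncated at `3σm` (≈ −1.7% on the tracked σ) and
boundary rejection truncates dispersal near edges, so the tracked
effective σ sits a few percent below `sqrt(3/2)·σf`, well within the 5%
band we test; at small σ/W, spatial clumping pushes it a few percent the
other way.

The competition scale σc has no direct role in displacement, and the
paired-simulation experiment (`sigma_c_sensitivity_experiment`) confirms
that a tenfold change in σc moves the tracked effective σ by less than 1%
beyond Monte-Carlo error.

### Inbreeding effective size

For the density input of the isolation-by-distance baseline the simulator
evaluates, each cycle, `NeI = (N·k̄ − 2)/(k̄ − 1 + Vk/k̄)` using the current
census `N` and the lifetime offspring counts `k` of the individuals dying
that cycle (the natural way to handle overlapping generations), and
reports the per-step mean at the end.

## Genetic ancestry

The forward simulation records a pedigree but no genomes.  For a set of
sampled individuals:

1. The ancestor closure of the sample is extracted and handed to
   `msprime` as a fixed pedigree; meiosis (fair starting haplotype,
   Poisson crossovers at the model recombination rate) is simulated
   through it.  `inherit_recombinant_haplotype` documents and tests the
   identical meiosis model as an explicit primitive.
2. Lineages that reach the founders uncoalesced are completed by a
   panmictic coalescent whose present-day size is the census at sampling —
   a deliberately observable quantity — optionally with one instantaneous
   size change (`DemographicHistory`) anchored in generations before
   sampling.  Trees that fail to coalesce raise.
3. Neutral mutations are overlaid starting at 1e-15 per bp per generation,
   escalating tenfold (keeping earlier mutations) until at least `m`
   biallelic sites segregate in the sample; exactly `m` are then drawn
   uniformly.  By Poisson thinning the result is distributed as if one had
   simulated at a high rate and subsampled `m` variable sites, making the
   output mutation-rate invariant — which the tests verify directly.

`unlinked` mode (default) additionally spaces the subsampled SNPs at least
`genome_length/(2m)` apart, emulating reduced-representation (RADseq-like)
data; `linked` mode subsamples without the spacing constraint.

## Genotype encoding

Sites are oriented to the minor allele in the sample (ties at frequency
0.5 break to the lexicographically smaller allele string).  Phased
matrices carry two 0/1 columns per individual with the within-individual
column order randomised; unphased matrices carry 0/1/2 minor-allele
counts.  In both conventions 1 counts the minor allele — for heterozygotes
the two conventions coincide, and a single orientation rule keeps VCF
round-trips exact.  Columns are zero-padded on the right to `pad_to`; the
network is always trained and applied with the same padding convention.
Sampling widths are Euclidean in habitat units for simulated data and
WGS84 geodesic kilometres (Vincenty's inverse method, implemented in
`geodesic.py`) for latitude/longitude data.

## Network and training

The architecture is derived from the input dimensions: `floor(log10 m) − 1`
convolution blocks (1-D, kernel spanning two SNPs and all columns, stride
one, ReLU, then average pooling of width 10), with filter counts
`64 + 44k`; then flatten, three 128-unit ReLU dense layers, concatenation
with the sampling-width scalar, one further 128-unit ReLU layer and a
linear output.  Fewer than 100 SNPs would derive an empty convolution
stack and is rejected.  Training uses mean squared error on `log σ`
targets, Adam at initial learning rate 1e-3, batch size 40, and a 20%
validation holdout; after `patience/10` epochs without validation
improvement the learning rate halves, training stops after `patience`
epochs without improvement, and the best-validation weights are restored.
The engine is a small, fully seeded numpy implementation
(`nnet.py`) — forward and backward passes for exactly the layer types this
architecture needs — so training and prediction are bit-reproducible for a
given seed.

Two conventions in the published description conflict: the results prose
suggests the first convolution strides two SNPs at a time, while the
methods give kernel height two with stride one.  We follow the methods
(kernel 2, stride 1).  Pooling uses width-10 average pooling with no
padding, and each convolution block is followed by one pooling layer.

## Uncertainty and diagnostics

`bootstrap_predict` draws `m` SNPs without replacement from the available
pool (replicates independent, overlap allowed), re-encodes and predicts,
giving a distribution of estimates whose spread reflects genealogical
noise among subsets of loci.  The reported interval is the middle 95% of
the bootstrap distribution inflated about its mean by a factor of 3.8,
clamped at zero on the left; 3.8 is an empirically calibrated value for
the reference training regime and is exposed as a parameter because it is
not guaranteed to transfer to other networks.  Quantiles use linear
interpolation between order statistics.  The Mahalanobis distance
`sqrt((x−μ)ᵀC⁻¹(x−μ))` between a dataset's summary statistics (π,
Tajima's D, F_IS, observed and expected heterozygosity) and the training
distribution flags out-of-distribution inputs.  Accuracy is scored as
relative absolute error `|σ̂ − σ|/σ` per replicate, averaged into the MRAE;
undefined estimates are counted separately and excluded from the mean.

## Isolation-by-distance baseline

The per-pair differentiation statistic is an ANOVA-style ratio computed
from genotype mismatches: `SSb` sums over sites the squared allele
difference averaged over the four between-individual gamete pairs, `SSW`
sums the two pair members' heterozygous-site counts, and
`â = (2SSb − SSW)/((2/P)·Σk SSW(k))`, i.e. in identity probabilities
`E[â] = (Qw − Qb)/(2(1 − Qw))`.  The published rendering of the
denominator is typographically ambiguous, so the normalisation was fixed
by the recovery property rather than by typography: simulated
isolation-by-distance data with known density must return σ̂ close to the
tracked effective σ through `b = 1/(4πDσ²)` (the reciprocal of Wright's
neighbourhood size `Nloc = 4πDσ²`).  The `(2/P)` form recovers σ within
~25% across the tested settings, and it keeps per-pair â well below 1, so
the `â/(1−â)` transform remains well-conditioned under per-pair sampling
noise (the alternative `(1/P)` form pushes noisy pairs past the
transform's pole and can flip the fitted slope).
The regression uses `â/(1−â)` on log distance with zero-distance pairs
excluded and equal weights; `σ̂ = sqrt(1/(4πDb))` for positive slope `b`,
and a non-positive slope is reported as an undefined status rather than an
error.  Density comes from `D = NeI/(W − 2σ)²`, excluding the
reduced-density edge band.

## Desk-scale study conditions

Full-scale training (10⁸ bp genomes, 10⁵ spatial generations, 1,000
simulations, 50,000-example training sets) is cluster work.  The package's
fixture scales are chosen once as desk-scale analogues:

- **small** — `W = 15`, `K = 5`, `σf = σm = σc = σ ~ U(0.15, 1.0)` (the
  σ/W ratios track the full-scale baseline regime; the lower end is
  bounded by the neighbourhood size needed for demographic stability),
  150 spatial steps, `n = 20` individuals per sample, `m = 1000` unphased
  SNPs, 300 simulations with 4 samples each (1,200 training examples), genome
  2.5e7 bp at 1e-8 crossovers/bp, constant demography, edge crop fixed at
  the maximum simulated σ so the crop cannot leak the per-simulation σ.
  Spatial mixing over the sampling window equilibrates on the order of
  a few hundred generations here, and the published full-scale experiments
  include training sets built from only 100 spatial generations, so 150
  steps retain the dispersal signal that the recent pedigree carries.
- **tiny** — `W = 10`, 100 steps, `m = 500`, `n = 10`, 30 simulations — a
  smoke-test scale used to exercise the full pipeline quickly.

What these fixtures emulate — and what they do not: uniform square
habitat, uniform random sampling, constant demography, a single selfless
hermaphroditic species with Gaussian kernels.  Passing the desk-scale
recovery test shows the implementation learns σ from genotype matrices
under these conditions; it does not establish accuracy for empirical data
with irregular habitats, non-uniform sampling, selfing, or demographic
histories outside the simulated range.

## Numerical choices and degenerate inputs

- Neighbour queries use a uniform-grid cell list (compiled with numba)
  whose results are identical to brute-force all-pairs search; the tests
  assert exact agreement.  Mate choice consumes one uniform draw per
  mother via a cumulative-weight threshold walk in a fixed neighbour
  order, making the weighted draw exact and reproducible.
- The simulator uses independent named random streams (placement, mating,
  offspring counts, dispersal, survival), so toggling one process does not
  shift another's draws.
- Seeds derived for msprime stay below 2³¹; all derived seeds come from
  `numpy.random.SeedSequence` spawning.
- `survival_probability` rejects negative densities; `inbreeding_Ne`
  raises on `k̄ ≤ 0` or a non-positive denominator; `effective_sigma`
  raises when no weighted births exist; monomorphic sites raise a
  dedicated error so callers resample; the Mahalanobis distance raises on
  non-positive-definite covariances with a regularisation hint; Vincenty's
  iteration raises for near-antipodal points instead of returning a wrong
  distance.
- Minor-allele ties (frequency exactly 0.5) break deterministically to the
  lexicographically smaller allele string.

## Known limitations

- The ancestral phase is panmictic; spatial structure older than the
  recorded pedigree is absent, so very long-range isolation-by-distance
  signal is understated relative to a fully spatial history.
- The desk-scale network is trained on narrow nuisance-parameter ranges
  (fixed K, W, n); it is not a general-purpose pretrained model.
- The bootstrap interval's 3.8 inflation is a property of the reference
  regime, not a universal constant.
- Habitat masks hook into founder placement and offspring rejection, but
  edge-distance penalties still use the bounding square's edges.
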