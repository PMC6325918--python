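# Methods

## Model

`reactnorm` fits reaction norms — phenotypes expressed as functions of an
environmental covariate — by random regression on Legendre polynomials
with pedigree-structured random effects.  A record of individual *k*
(genotype *j*) in site *i* at covariate value *x* is modelled as

    y_ijkl(x) = Σ_m s_im L_m(x′) + Σ_m a_jm L_m(x′) + Σ_m p_km L_m(x′) + r_ijkl

where x′ = 2(x − min x)/(max x − min x) − 1 standardizes the covariate to
[−1, 1] and L_m is the (raw, unnormalised) Legendre polynomial of degree
m.  One order M applies to the whole model: site curves (fixed), additive
curves and permanent-environment curves all use coefficients 0…M.

* **Additive term.** Coefficient vectors a_j are jointly Gaussian with
  covariance Σ_A ⊗ A, A the numerator relationship matrix from the
  pedigree (tabular method; unknown parents are unrelated, non-inbred
  founders).
* **Hybrid decomposition.** For interspecific hybrids the additive value
  decomposes as a_H = g_E + g_J, the general-combining-ability
  contributions of the two parental species.  With outbred, unrelated
  parents, g_E ~ N(0, Σ_HE ⊗ ½I) indexed per parent (and likewise g_J);
  the ½ lives in the covariance structure, not in Σ.
* **Permanent environment.** p_k ~ N(0, Σ_P ⊗ I) captures the similarity
  among repeated records of one individual; it is required whenever an
  individual has more than one record and unidentifiable (and refused by
  default) with single records.
* **Residual.** Unstructured, one variance per trait; in bivariate fits
  the two traits of one ring record have independent residuals.

Bivariate fits stack per-trait coefficients into one vector of length
2(M+1); Σ then contains every variance and covariance among trait×order
coefficients.  Missing trait values contribute nothing to that trait's
residual.

Raw rather than √((2m+1)/2)-normalised Legendre polynomials are used; the
choice only rescales coefficients and every derived parameter function is
invariant because all basis evaluations go through one module.

## Sampler

The model is fitted by a blocked Gibbs sampler with fully conjugate
updates:

1. **Parent tier.**  Fixed coefficients plus the coefficient vectors of
   every individual that appears as a parent are drawn jointly from their
   dense multivariate-normal full conditional.  The prior precision of the
   parent block is A_PP⁻¹ ⊗ Σ⁻¹ plus the Mendelian couplings contributed
   by terminal offspring.
2. **Terminal tier.**  Individuals without offspring are conditionally
   independent given the parent tier: u_t | parents ~ N(½(u_s + u_d),
   d_t Σ) with d_t the Mendelian-sampling variance coefficient computed
   from the relationship matrix (½ for two known non-inbred parents).  All
   terminal vectors are therefore drawn in one vectorised batch of small
   (k×k) solves.  This makes two-generation designs — diallels, half-sib
   trials — fast regardless of progeny count, while remaining exact for
   arbitrary pedigrees (any multi-generation parent simply joins the dense
   tier).
3. **Covariances.**  Genetic blocks use the zero-belief, zero-scale limit
   of the inverse-Wishart (density ∝ |Σ|^−(k+1)/2), giving the conditional
   IW(q, S) with S = Ũᵀ A⁻¹ Ũ computed via the Mendelian decomposition
   S = Σ_i m_i m_iᵀ / d_i (no matrix inversion).  Permanent-environment
   blocks take a flat improper prior (conditional IW(q_P − k − 1, S_P)),
   residual variances a flat prior on the variance scale (scaled
   inverse-χ² with n − 2 degrees of freedom).
4. **Parameter expansion.**  Each genetic block carries a persistent
   scalar working parameter λ with standard-normal prior: the sampler
   states are working effects ũ with covariance Σ̃, the likelihood sees
   λũ, and the reported draws are u = λũ, Σ = λ²Σ̃.  Keeping λ as state
   (rather than folding it into Σ every iteration) prevents the chain
   from being absorbed near zero variance when the genetic signal is
   weak: the working effects keep their own scale even while λ ≈ 0.
   A standard-normal working prior is the common default; the expansion
   can be switched off (``PriorSpec(genetic="jeffreys")``).

Point estimates are maximum a posteriori: the mode of a Gaussian KDE
(Silverman bandwidth) over the retained draws, evaluated at the draw
points.  Credible intervals are central posterior quantiles.  Derived
parameter curves are computed on every retained draw and summarised
pointwise (MAP and 95% band); pointwise bands are per grid point, not
simultaneous.

### Chain presets

| preset     | iterations | burn-in | thinning | use |
|------------|-----------:|--------:|---------:|-----|
| desk       | 6 000      | 1 000   | 10       | interactive work |
| full-sim   | 150 000    | 50 000  | 1 000    | full-length simulation-study chains |
| full-real  | 5 500 000  | 500 000 | 5 000    | full-length chains for large repeated-records datasets |

The desk preset is deliberately short: the blocked sampler draws all
location effects in two exact Gaussian steps per iteration, so MAP
summaries stabilise within a few thousand iterations on the simulated
designs.  The acceptance battery uses 4 000/1 000/6 for the large
(5 400-progeny) scenario and 12 000/3 000/18 for the small (900-progeny)
one — wall-time-balanced, with more iterations where the weaker signal
mixes more slowly.

### Numerical guards

Covariance inversions floor eigenvalues at 10⁻¹²·var(y); residual
variances are floored likewise; the dense-tier Cholesky symmetrises and
retries with escalating diagonal jitter (starting at 10⁻¹² of the largest
diagonal entry) when rounding makes a near-degenerate precision
indefinite.  Inverse-Wishart scale matrices are jittered and retried on
Cholesky failure.  Datasets of unrelated single-record founders leave the
additive and residual variances confounded; `assemble` warns.

## Derived genetic parameters

With L(x′) the basis row at x′ and V, C trait blocks of Σ:

    σ²_T(x) = L(x′) V_T L(x′)ᵗ            c(x) = L(x′) C L(x′)ᵗ
    h²_T(x) = σ²_A:T(x) / (σ²_A:T(x) + σ²_P:T(x) + σ²_R:T)
    h²_HE:T(x) = σ²_HE:T(x) / (½σ²_HE:T(x) + ½σ²_HJ:T(x) + σ²_P:T(x) + σ²_R:T)
    r(x) = c(x) / √(σ²_T1(x) σ²_T2(x))

The hybrid heritability keeps the full per-side variance in the numerator: it measures the share of hybrid phenotypic
variance attributable to additive inheritance from that parental side, and
reaches 1 when both sides have equal variance and no other variance
exists.  The pure-species h² carries no ½ factors.  Correlations are
clipped only for floating-point excursions (<10⁻⁸) and flagged NaN where a
variance vanishes.  Default grid: 101 equally spaced points over the
covariate range stored with the fit.

## Water indices

`d1rew` is the 10th percentile (linear interpolation between order
statistics, numpy type-7; configurable) of one year's daily relative
extractable water — the REW below which lie roughly the 36 driest days of
a year.  The decile is taken over the whole year's series.  `mjja_index`
is Σ rain − Σ PET over May 1–August 31 (123 days); the PET sum uses the
same window as the rain sum, the natural reading of a seasonal
rain-minus-demand budget.  The daily water-balance model that produces
REW is out of scope; the module starts from its output.

## Synthetic diallel generator

The generator emulates a purely additive, forward genetic model:

* 100 diallelic loci (configurable); each allele's effect is a parabola
  α(x) = α0 + α1(x+δ) + α2(x+δ)², with parameters drawn uniformly from
  α0 ∈ [−1,1], α1 ∈ [−0.5,0.5], α2 ∈ [−0.25,0.25], δ ∈ [−1,1] on a
  gradient of [−1,1].  These defaults make the norms strongly interactive:
  parental rankings at the two gradient ends differ for ≥95 of 100 random
  genomes.
* Full diallel between 10 monoecious founders excluding selfs: 90 ordered
  crosses, 45 full-sib families (reciprocals pooled), n/2 sibs per ordered
  cross.  Free recombination (no linkage), one generation, no mutation or
  selection.
* The gradient is divided into n uniform random positions; each
  environment hosts exactly one sib per family, so each family spans the
  whole tested range and each environment holds 45 individuals.  Each
  progeny yields a single phenotypic record at its position (a
  repeated-records option adds further records at fresh positions plus an
  individual-level permanent deviation, for the subsampling experiment).
* Because allelic effects are quadratics, a genotype's value is a
  quadratic; genomes are reduced to three aggregated polynomial
  coefficients, making true breeding values evaluable at any x.
* The residual sd is calibrated as √(V_g(1−h²)/h²) where V_g is the
  variance of the progeny's additive deviations at their assigned
  environments — heritability is controlled environment-averaged, since
  no single control point is canonical.  Realized heritability is defined
  net of the population mean curve (fixed effects do not enter the
  phenotypic variance of a heritability).

What the generator does **not** emulate: realistic allele-frequency
spectra, linkage, dominance or epistasis, multi-generation structure, or
environment distributions other than uniform.  Passing tests therefore
show that the estimator recovers what this idealised additive world
defines, not that real tree-ring data meet the model's assumptions.

## Evaluation battery

*Accuracy* is the Pearson correlation, across the 10 founders, between
MAP-predicted additive performances (per-coefficient MAP, then the linear
combination) and true simulated performances, at 50 grid points spanning
the progeny-tested range.  *Variance recovery* compares the estimated
additive-variance function with the variance across founders of their
true performance functions — the founders are the base population of the
fitted model, and with single records per progeny the data inform exactly
that realized spread (the expected Mendelian variance adds no separable
information).  The recovery summary defaults to the pointwise posterior
mean; the MAP is also reported, and sits systematically below the mass of
the strongly right-skewed variance posterior at low heritability.  The
low-heritability scenarios therefore show posterior-mean overestimation
of the additive variance, most visibly at h² = 0.1.

The *single-record experiment* simulates repeated-records data (4 records
per progeny, permanent-environment sd at 30% of the genetic sd), fits the
full model with the permanent term, then keeps one random record per
individual and refits without it, comparing the fixed slope (sign and
position within the full fit's 95% CI) and the founder ranking (Spearman
correlation of predicted parental values at the gradient ends).

## Known limitations

* No residual covariance function: residuals are white within trait,
  which can bias variance partitioning when records of one individual are
  serially correlated beyond what the permanent-environment term absorbs.
* With single records and a handful of founders, the additive variance is
  estimated against ~10 realized founder values; replicate-to-replicate
  variability of any variance-recovery ratio is intrinsically large
  (χ²₉-scale, roughly ±45%).
* Two traits maximum; one environmental covariate; founders must be
  non-inbred and (for the hybrid decomposition) unrelated within species.
* The MAP of a weakly identified variance component is sensitive to the
  KDE bandwidth; the posterior mean and full draws are always available.
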