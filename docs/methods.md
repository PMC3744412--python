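# Methods

## The experimental design being modelled

Two haploid yeast parents — one phenotypically superior, one inferior and
essentially identical to the reference genome — are crossed; haploid F1
segregants are phenotyped; a pool of extreme segregants and an unselected
control pool (both typically 58 members) are sequenced. Each pool yields,
at every parent-distinguishing SNP, a variant read count (superior-parent
allele) out of a total. Under random segregation every marker sits at 50%
variant frequency; selection drags markers linked to causative alleles away
from 50%, upward for superior-parent linkage and downward for
inferior-parent linkage. A second mapping round with "downgraded" parents —
each parent's superior allele at an already-mapped QTL replaced by the
other parent's inferior allele — removes the dominant signals and lets
minor or epistatically masked QTLs surface.

## Marker filter

A site enters the marker catalogue iff the superior parent's own sequencing
shows total coverage ≥ 20 reads and a variant ratio ≥ 80%, both bounds
inclusive. The filter applies to the parent only: the pools' frequencies
are the quantity under study and must be free to vary. Sites missing from a
pool are kept with (0, 0) counts and zero likelihood weight, preserving one
marker frame across pools.

## Frequency smoothing

Per pool and chromosome, variant counts follow a binomial GAM on the logit
scale. Numerical choices:

- cubic B-spline basis; 20 interior knots by default (30 in the bundled
  mapping analyses, where ~300 markers per chromosome support the extra
  resolution), placed at marker-position quantiles; boundary knots at the
  chromosome ends;
- second-order difference penalty on the coefficients plus a weak (10⁻³)
  first-order ridge. The ridge removes the linear trend from the penalty
  null space, so infinite smoothing collapses the fit to the constant
  overall pooled frequency instead of an arbitrary line;
- penalised IRLS, λ selected by AIC (deviance + 2·edf) over a log-spaced
  grid 10⁻⁴…10⁸; the working predictor is clipped at |η| = 15 so saturated
  cells (0% or 100% markers) keep finite weights, and fitted frequencies
  are reported with the same cap. No pseudo-counts are added;
- coefficient covariance is the inverse penalised information
  (BᵀWB + λP)⁻¹; markers with zero total are dropped from the likelihood
  but kept on the evaluation grid (markers plus a regular 1 kb grid by
  default).

Plain binomial likelihood is used within the fit; overdispersion enters the
inference stage explicitly (below) rather than through a quasi-likelihood,
because its dominant source in this design is correlated along the
chromosome and cannot be expressed as a per-marker variance inflation.

## Simultaneous inference on the contrast

The contrast of selected pool q against unselected pool 0,
c(x) = η_q(x) − η_0(x), is a log odds ratio. Its uncertainty around the
cross-level truth has two components:

1. **Read sampling.** Propagated from the two fits' coefficient
   covariances.
2. **Segregant sampling.** A pool of M segregants has a realised frequency
   profile that wanders around the cross expectation. At a marker the
   variance of the pool frequency is 1/(4M), i.e. ≈ 4/M on the logit scale
   near 50%; between positions at genetic distance d Morgans the parental
   origin of a segregant co-segregates with probability following
   Haldane's map function, giving correlation e^(−2d). For pools of 58 at
   ~100× coverage this term is roughly an order of magnitude larger than
   read noise and is the dominant uncertainty of the design. It is added
   as a closed-form covariance (unshrunk by the smoother, which is mildly
   conservative), with the genetic map scale configurable per chromosome
   (default 0.4 cM/kb, the canonical yeast average). Setting
   `pool_size=None` disables the term and leaves the read-noise-only
   construction.

Monte-Carlo draws from the joint Gaussian of both components give, per
draw, the supremum over the evaluation grid of |deviation|/SE. The
(1−α) quantile z* of the sup distribution yields the simultaneous band
c ± z*·SE; on a single-point grid z* reduces to the pointwise normal
critical value (≈1.96 at α = 0.05). With several chromosomes, per-
chromosome sup draws are combined by their per-draw maximum, so the band
and the p-values are simultaneous genome-wide. One seeded Monte-Carlo pass
per chromosome serves both the band and the p-values. The default is 10⁴
draws for desk-scale work and 10⁵–10⁶ for production profiles.

Testing is threshold-aware: the statistic t(x) = max(0, |c(x)| − δ)/SE(x)
measures distance beyond a biological-relevance threshold δ, and the
adjusted two-sided p-value is the null probability that the genome-wide sup
exceeds t(x); p ≡ 1 wherever |c| ≤ δ. The default δ = 0.4088 is the
conventional printed value for an odds ratio outside [2/3, 3/2]; note
ln(3/2) = 0.4055, a 4th-decimal inconsistency between the printed constant
and its stated interval semantics that the package exposes but does not
resolve — both the constant and α are config keys. Because δ > 0, the
familywise error of calls at the 0.05 cut-off is conservative (measured
0.00, 200 null genomes).

QTL calls are maximal runs of grid points with p < α and constant contrast
sign; runs separated by a single non-significant grid point merge;
intervals listed in an optional mask BED (e.g. subtelomeric repeat regions,
which show frequency artefacts even in unselected pools) are excluded
before calling. Direction follows the contrast sign at the peak: positive →
superior parent, negative → inferior parent.

## Segregant scoring

Association of a scored SNP is the percent of non-missing individual
segregant calls carrying the superior allele (missing calls excluded
per SNP). Departure from 1:1 is tested with the two-sided exact binomial
p = min(1, 2·min(P(X≤k), P(X≥k))) — the symmetric 2·min-tail convention —
and adjusted across the scored SNP set with Benjamini–Yekutieli FDR
(statsmodels implementation), whose validity under arbitrary dependency
suits tightly linked SNPs. Adjustment is per scored set; pooling across
regions is the caller's choice of SNP list.

## Synthetic cross generator

The generator emulates the study design so every downstream stage is
testable:

- **Meiosis.** Crossovers per chromosome are Poisson with mean equal to
  the genetic length in Morgans, placed uniformly in bp (no interference —
  the simplest model with correct marginal segregation); the leftmost
  block's parental origin is a fair coin. Chromosome sizes follow the
  16 yeast chromosomes (~12 Mb, 0.4 cM/kb).
- **Phenotype.** Continuous latent trait: baseline + Σ active QTL effects
  + Gaussian noise (unit SD by default). A positive effect means the
  superior-parent allele raises the trait; a negative effect models
  inferior-parent linkage (the recessive-variation case expected in a
  heterozygous natural isolate). An effect with an epistatic mask
  contributes nothing when the masking locus carries its phenotypically
  beneficial allele — complete masking, the qualitative pattern reported
  for such interactions.
- **Selection and pooling.** Selected pool = top 58 by phenotype (seeded
  tie-break), or everything above a threshold; unselected pool = a seeded
  random sample of 58 (how the original control pool was composed is not
  documented; random sampling is assumed). Defaults: 950 segregants in the
  original cross, 2,464 in the downgraded cross, pools of 58.
- **Sequencing.** Per marker, Poisson(100) coverage; each read's parental
  identity is drawn from the pool's true allele frequency and flipped with
  probability 0.002.
- **Downgrading.** Fixes the named QTL's phenotypic allele to the
  inferior variant in every segregant, neutralising the effect (and
  releasing anything it masks) while leaving marker segregation untouched —
  the marker catalogue is shared across crosses, as in the two-round
  design.
- **Effect sizes.** The default scenario uses majors of 2.0 and 1.5 and
  minors of 0.8 phenotype SDs; 0.8 reproduces the 70–80% association
  levels reported for minor QTLs in 58-segregant selected pools. The
  recovery scenario used for end-to-end detection tests uses 3 SD majors
  and a 1.5 SD masked minor, the effect ≫ noise regime in which pooled
  mapping should succeed in every replicate.

What the generator does not emulate: read alignment artefacts, subtelomeric
repeat mis-mapping (handled only via the mask BED), base-quality structure,
crossover interference, and copy-number-style wave patterns. Passing tests
therefore demonstrate the statistical chain's correctness under its own
assumptions, not robustness to alignment pathology in real data.

## Calibration and problem sizes

The bundled calibration studies (also run by `scripts/acceptance.py`) use
null genomes with two unselected pools of 58 at 100× coverage: one 1 Mb
chromosome with 300 markers for band coverage, four 750 kb chromosomes with
150 markers each for familywise error, and 2,000 markers over four
chromosomes for the unselected-pool mean frequency; 200 replicates and 10⁴
Monte-Carlo draws per chromosome. Measured: simultaneous coverage 99.0%
(nominal 95%; the excess is the deliberate conservatism of the unshrunk
segregant-sampling covariance), familywise error 0.00 (≤ 0.05 by
construction, further tightened by δ), unselected mean frequency 47.8%
(the deviation from 50% is genuine finite-pool composition variance: 58
segregants over ~30 effectively independent linkage blocks leave ~1.3%
standard error on the genome mean).

## Known limitations

- The segregant-sampling covariance assumes unselected-pool correlation
  structure for the null; selected pools under strong QTLs have locally
  distorted covariance, which affects power near peaks, not validity.
- Minor QTLs at the association levels reported for 58-segregant pools
  (~75%) sit at the detection boundary of the pooled contrast once
  segregant sampling is honoured; individual-segregant scoring is the
  appropriate confirmation route, and the analysis drivers follow it.
- Binomial read model without per-read error structure; sequencing error
  enters only as the generator's strand-agnostic flip probability.
- p-values are Monte-Carlo estimates with resolution 1/n_sims; reported
  zeros mean "below resolution".
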