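# Methods

## The neutral occurrence-abundance model

The core model treats each host individual as a local community of `N`
individuals (operationally: sequencing reads per sample) receiving
immigrants from a shared metacommunity — here, the bacterioplankton of the
surrounding water plus whatever the host itself maintains. Under neutral
immigration-drift dynamics, the stationary local relative abundance of a
taxon with metacommunity mean abundance `p` is approximately

    x ~ Beta(N m p, N m (1 - p))

where `m` is the probability that a death in the local community is
replaced by an immigrant rather than local reproduction. The observable the
model predicts is *occurrence*: the fraction of hosts in which the taxon is
detected.

**Detection models.** Detection of a taxon in count data means "at least
one read". Integrating the binomial read-sampling over the beta gives the
beta-binomial non-zero probability

    f_hat = 1 - B(a, b + N) / B(a, b),   a = N m p,  b = N m (1 - p)

which is exact for the generative process the package simulates and is the
default (`detection="betabinomial"`). The classical closed form
`f_hat = 1 - I(d; a, b)` — the probability that `x` exceeds a detection
limit `d = 1/N` — is kept as `detection="threshold"`. The two curves are
close, but fitting the threshold form to sequencing data biases `m` upward
by roughly 20% (the threshold event `x >= 1/N` is not the same event as
"at least one of N reads"); the parameter-recovery study below quantifies
this. `N` defaults to the mean post-filter reads per sample and `d` to
`1/N`.

**Fitting.** `fit_sloan_beta` minimizes the occurrence sum of squares over
`m` in (0, 1] (bounded scalar optimization, tolerance 1e-8; a boundary
solution raises a warning). `fit_sloan_glm` fits detections `k_i` out of
`S` samples as a binomial GLM with logit link on `log10 p_i`, falling back
to a small ridge penalty under separation. Its response residuals
`f_i - fitted_i` are the default "departure from neutrality" carried into
source attribution; Pearson and deviance residuals are available. Taxa
never detected (or with `p = 0`) are excluded from fitting but retained in
reports with NaN residuals.

**Classification.** Taxa with residuals strictly above the empirical 97.5th
(below the 2.5th) percentile of the fitted residuals are labelled over-
(under-)represented. Strict inequalities make ties at a cutoff neutral and
the rule deterministic. Note the structural consequence: the empirical rule
flags ~2.5% per tail *by construction*, so it ranks departures rather than
testing them — with 200 taxa exactly 5 can sit above the upper cutoff,
which caps the detectable number of enriched taxa regardless of effect
size. The quantiles are exposed (`lower_q`, `upper_q`).

## Distances, ordination, permutation tests

Bray-Curtis is computed on raw counts and Jaccard on presence (count >= 1);
UniFrac (unweighted, and weighted in its normalized [0, 1] variant) is
delegated to scikit-bio with a tip-coverage check. Beta diversity is not
rarefied by default; rarefaction (without replacement, seeded, depth
defaulting to the minimum sample sum) is applied for alpha diversity only.
Both choices are configurable.

PCoA double-centers `-D^2/2` and eigendecomposes; axes with eigenvalue
below 1e-9 are dropped, negative eigenvalues are reported but uncorrected
(no Lingoes/Cailliez), since ordination is used for display and PC-1
summaries only.

One-way PERMANOVA uses the standard pseudo-F from squared distances with
label permutation and the +1/+1 p-value convention; for small designs
`method="exact"` enumerates all distinct assignments of samples to the
observed group sizes (the minimum exact p for two groups is 2/n_assignments
because the mirrored assignment reproduces the observed F). The crossed
two-factor test partitions the Gower-centered inner-product matrix by
sequential sums of squares of nested hat-matrix projections
(intercept ⊂ A ⊂ A+B ⊂ A+B+A:B), with pseudo-F against the full-model
residual and permutation of raw observations. Sequential SS is a choice;
the original adonis-style analysis does not state its scheme. A constant
second factor degenerates cleanly to the one-way test; an aliased factor is
an error.

The Mantel statistic is the Pearson correlation of lower-triangle entries
(primary, scale-free) with the raw cross-product sum `z` also reported;
the null permutes one matrix's row/column order jointly, one-tailed
"greater" by default because the scientific hypothesis (host differences
track water differences) is directional. BH-FDR is applied within an
analysis block — e.g. the 8 weekly tests of one population's table — via
statsmodels.

Site-level pairing for the Mantel test: multiple water samples per site are
summed into one site profile before distances; host distances are averaged
over all between-site polyp pairs, diagonal zero.

## Synthetic data: what it emulates, what it does not

`generate_source_pool` draws log-normal relative abundances (default
sigma = 2.0, the few-dominants/long-tail shape of lake bacterioplankton).
`assemble_neutral_samples` applies the same beta + multinomial process the
fit assumes — deliberately, so parameter recovery is a sharp test of the
estimator rather than of model misspecification. Defaults mirror the field
design: 15 sites, 12 polyps and 3 water samples per site, 10,000 reads per
sample, m = 0.1.

`inject_nonneutral_taxa` pushes chosen taxa's occurrence at least `effect`
above (below) the neutral prediction, iterating because added detections
shift `p_i` and hence the prediction itself. Over-injection adds single-read
detections (minimal abundance impact); under-injection removes detections
but reallocates the removed reads to samples keeping the taxon, conserving
its mean abundance — present on fewer hosts, more abundant where present,
the signature of a host-restricted taxon. Candidate selection can target
the water-enriched abundance tail (over) and the host-core set absent from
water (under), mirroring environmentally sustained vs host-restricted taxa.

`generate_paired_sites` perturbs the global pool along a site-specific
log-scale direction (scale = `gradient_strength`) and assembles polyps from
a 50/50 mixture of a shared host core (absent from water) and the site's
water pool; `gradient_strength = 0` makes polyps site-independent — the
exact null of the Mantel analysis.

`generate_exchange_timeseries` produces, per population, shared week-0
start samples and weekly native/foreign samples (default 5 jars per
treatment, one polyp per jar per week, 4 weeks, 1000 taxa — ASV-scale
richness, since the experiment's distances operate on ASV tables). A fixed
lab-shift displaces every week >= 1 pool identically in both treatments; in
the foreign group a fraction `turnover_rate` of rare-taxon *identities* is
replaced by novel taxa each week, cumulatively, with the replacement
inheriting the replaced taxon's abundance so the sorted abundance spectrum
is conserved exactly. "Rare" means below the per-sample median observed
relative abundance, operationalized as the detection-probability-weighted
median of pool abundances (weights `1 - exp(-N a)`): that cutoff sits a few
reads above the detection limit, so turnover is visible to
presence/absence metrics while moving a negligible share of read mass. One
designated taxon ramps up in all groups, reaching 2% by the final week.

Not emulated: sequencing error and chimeras, taxonomy misassignment,
compositional coupling to water chemistry, jar-level ecological drift, and
any within-host spatial structure. Passing tests therefore demonstrate
that the estimators and tests behave correctly under the stated model, not
that real data satisfy that model.

## Calibration studies and the sizes they run at

All studies live in `reservoirlink.calibration`, derive every replicate
seed from one master seed, and are rerun from scratch by
`scripts/acceptance.py`:

* m-recovery: 20 replicates of 200 genera x 60 samples at N = 5000,
  m = 0.1; the median fitted m is reported (lands within a few percent).
* classification: 10 replicates with 10 over- + 10 under-injected taxa at
  effect 0.3 among 200; sensitivity, precision, and the neutral-only flag
  rate (~5%) are reported. Because the percentile rule flags only ~5 taxa
  per tail of 200, sensitivity saturates near 0.5 while precision is ~1 —
  the flagged sets consist almost entirely of injected taxa.
* residual-source correlation: 50 survey replicates with water-tail
  over-injection and host-core under-injection; Spearman rho against water
  occurrence and abundance (median ~0.5) and the fraction of replicates
  with rho > 0.3 at p < 0.01.
* Mantel: 500 null replicates (gradient 0; rejection at alpha = 0.05 stays
  within 0.05 ± 0.02) and 100 power replicates at gradient 1.0.
* exchange dissociation: 25 single-population replicates at turnover 0.3,
  1000 permutations; success = Jaccard q < 0.05 and Bray-Curtis q > 0.05
  at weeks 2-4 after the dataset-wide <50-count filter.

Studies that mirror end-to-end analyses apply the standard preprocessing
(the dataset-wide total-count < 50 filter) before distances; the
m-recovery and classification studies run on the generator output directly
because their conditions fix the genus count.

## Numerical and degenerate-input conventions

Count tables must be non-negative integers with unique ids and positive
sample sums; zero-sum samples are construction errors. Rarefaction uses
multivariate hypergeometric draws (sub-multisets of the input).
Genus aggregation conserves the grand total; unassigned-genus ASVs pool
into `unclassified_<family>` pseudo-genera by default (droppable). The
low-count filter applies before genus aggregation. Permutation p-values
are never 0 (+1/+1 convention). Percentile classification with
`lower_q=0, upper_q=1` labels everything neutral. All generators and tests
are deterministic under fixed seeds; reports embed config hash, seed and
package version.

## Known limitations

* The empirical-percentile classification cannot flag more than the
  nominal tail fraction of taxa, whatever the true number of non-neutral
  taxa; null-calibrated or envelope-based thresholds would decouple the
  flag count from the quantile but are deliberately out of scope.
* The crossed PERMANOVA permutes raw observations; restricted/stratified
  permutation schemes are not implemented.
* The beta-binomial detection default assumes detection = count >= 1; data
  filtered with per-sample abundance floors would need the threshold form
  with a matching `d`.
* Site gradients and the lab-shift are linear displacements in log-pool
  space; real site differences include richness and chemistry effects the
  generator does not model.
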