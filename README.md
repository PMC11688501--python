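# reservoirlink

Statistical machinery for asking where a host-associated microbiome comes
from: do environmental (water) bacteria seed the communities living on an
aquatic host, and can they restructure them?

The package targets the study design used for freshwater cnidarians such as
*Hydra* — paired host (polyp) and water samples across many field sites,
plus a longitudinal experiment in which animals are cultured in water from
their own ("native") or a different ("foreign") site — but every component
works on any sample × taxon count table with matching metadata.

## What it computes

**Neutral community model.** For each taxon with metacommunity mean relative
abundance `p_i`, the Sloan model predicts its occurrence across hosts from a
community size `N` (reads per sample), migration rate `m` and detection
limit: local relative abundance is approximately `Beta(Nm p_i, Nm (1-p_i))`
distributed, so expected occurrence is the probability that a sample of `N`
reads detects the taxon. `fit_sloan_beta` estimates `m` by bounded least
squares (beta-binomial detection by default; the classical beta-CDF
threshold form is available); `fit_sloan_glm` fits the binomial GLM of
detections on `log10 p_i`. Taxa with residuals beyond the empirical
2.5/97.5 residual percentiles are classified under-/over-represented.

**Source attribution.** Spearman correlation between departures from
neutrality and each taxon's occurrence/abundance in water (taxa absent from
water enter at 0), and a one-tailed Mantel test between the site-level
water distance matrix and the site-averaged host distance matrix.

**Diversity machinery.** Bray-Curtis, presence-absence Jaccard, unweighted
and (normalized) weighted UniFrac; Shannon entropy; classical PCoA;
one-way PERMANOVA with an exact-enumeration mode; crossed two-factor
PERMANOVA (McArdle-Anderson sequential partition of the Gower-centered
matrix); Benjamini-Hochberg FDR.

**Longitudinal analytics.** Per-week native-vs-foreign PERMANOVA tables
with per-table FDR, Shannon trajectories with rank-sum tests, PC-1
volatility, and presence-based gain/loss tallies against the shared start.

**Synthetic data with recorded truth.** Generators for heavy-tailed source
pools, neutral host communities, injected non-neutral taxa, multi-site
surveys with shared water-host gradients, and native/foreign exchange
time-series with rare-taxon identity turnover — every analysis above is
testable against known ground truth without any sequencing data.

## Worked example

```sh
python examples/01_neutral_model_fit.py
```

```
true m                : 0.1
fitted m (beta model) : 0.0943   R^2 = 0.975
binomial GLM          : R^2 = 0.964
classification at 2.5/97.5 percentiles: {'neutral': 190, 'over': 5, 'under': 5}
```

The fitted migration rate recovers the generating value within a few
percent, and on purely neutral data the percentile rule flags ~5% of taxa
by construction — the baseline against which real enrichment is judged.
`examples/02_source_attribution.py` adds injected water-tail taxa and
prints the residual-water correlation (Spearman rho ≈ 0.5, p < 1e-12) and
the site-averaged Mantel test; `examples/03_water_exchange.py` prints the
weekly PERMANOVA table in which Jaccard separates native from foreign water
(q ≈ 0.02 every week) while Bray-Curtis does not (q > 0.2) — identity
turnover without abundance restructuring.

Library-first: `import reservoirlink as rl` exposes everything. A thin CLI
mirrors the pipelines:

```sh
reservoirlink simulate exchange --seed 3 --outdir data/
reservoirlink neutral-fit --counts data/counts.tsv --out-prefix results/fit
reservoirlink survey --config survey.yaml --outdir results/
```

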