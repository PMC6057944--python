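# Methods

## The gradient model

Cohorts compare four ordered habitat classes — captive < semi-captive <
semi-wild < wild — which the analysis treats as a coarse discretisation of
a latent, continuous "wildness" variable.  Rather than running six pairwise
tests per feature, the central statistic is the **polyserial correlation**
between each feature's CLR abundance x and the ordinal class y: the ML
estimate of corr(x, η) under the assumption that y arises by thresholding
a standard-normal latent η, with (x, η) bivariate normal.  CLR-transformed
abundances are close enough to Gaussian for this model to be serviceable,
which is the reason for the compositional preprocessing.

Estimation is the standard two-step scheme: thresholds
τ_j = Φ⁻¹(Σ_{k≤j} p̂_k) from the ordinal marginals, then a bounded 1-D
maximisation of the conditional log-likelihood over ρ ∈ (−0.999, 0.999)
(Brent, xatol 1e-8).  Two p-values are attached:

- **LRT χ²**: 2(ℓ(ρ̂) − ℓ(0)) on 1 df.  This is the p-value used for
  family-wise adjustment and selection.
- **Wald** ("rho confidence p"): 2Φ(−|ρ̂|/se), with se from the numerical
  observed information (central second difference, h = 1e-4).

The two are asymptotically equivalent but not identical in finite samples;
both are reported, and both enter the selection rule (LRT adjusted, Wald
raw), so a feature must survive the stricter of the two.

### Selection rule

A feature is called a gradient biomarker only if all four hold:

| criterion | threshold |
|---|---|
| effect size | abs(rho) ≥ 0.3 |
| Holm-adjusted LRT p (family = all features scanned) | ≤ 0.05 |
| raw Wald p | ≤ 0.05 |
| Holm-adjusted extrema Wilcoxon p (family = all features) | ≤ 0.05 |

The extrema test pools captive + semi-captive into one "(Semi-)captive"
group (accumulating enough samples to power a two-sample test) and compares
it against wild by Wilcoxon rank-sum, excluding semi-wild.  It is a
nonparametric corroboration: the polyserial fit characterises the gradient,
the rank test certifies that its endpoints genuinely differ.  Heatmap
display uses stricter tiers on the selected set: |ρ| > 0.6 for taxa,
|ρ| > 0.75 for pathway (KEGG-module) scans, with rows CLR-valued (taxa) or
per-row min-max normalised (pathway).

Holm families are per statistic battery (all LRT p's together, all Wilcoxon
p's together), and taxa and pathway scans are separate families.  The
replicate-collapse validation pass uses Benjamini-Hochberg instead of Holm.

## Compositional preprocessing

Counts are compositions: only relative information is meaningful, so all
per-feature testing happens on centred log-ratios.  Order of operations is
fixed: **bin → filter → CLR** (and rarefaction only for diversity metrics,
never before CLR).  Filtering requires presence (count > 0) in ≥ 3 samples
AND mean per-sample relative abundance ≥ 1e-4; presence is assessed on the
unrarefied table.

**Zero replacement.**  The default is multiplicative detection-limit
replacement: per sample, δ = 0.65 × (smallest non-zero fraction), zeros set
to δ and non-zeros shrunk by (1 − δ·n_zeros) so the composition still sums
to one.  The factor 0.65 is the conventional fraction of the detection
limit used in compositional practice; it is a config knob, recorded in the
output, and an additive-pseudocount variant (`method="additive"`) is
selectable.  The imputed δ per sample is kept in the `CLRMatrix` so
downstream consumers can see exactly what was filled in.

**Replicate collapse.**  Unequal replication of individuals (12 samples
from 2 captive animals vs 18 singletons from semi-wild animals)
pseudoreplicates any test that treats samples as independent.  The
validation pass averages each individual's *relative-abundance vectors*
(not counts — replicates have unequal depth; not CLR values — averaging is
done on the simplex before transformation) into one profile per
(lifestyle, individual), with all unidentifiable wild samples pooling into
a single "unknown" wild profile.  On the reference skeleton this reduces
111 samples to 36 profiles (2 / 7 / 18 / 9 per lifestyle).  The collapsed
scan is a robustness check, expected to agree in sign with the full scan
while losing power.

## Diversity conventions

Shannon uses log base 2 (bits) and Simpson is 1 − Σp²; Chao1 uses the
classic S + F1²/(2F2) form, switching to the bias-corrected form
automatically when no doubletons exist.  Alpha variation is tested by
one-way ANOVA plus all pairwise Welch t-tests (unequal variances,
Welch-Satterthwaite df).  Weighted UniFrac is unnormalised by default;
PCoA reports negative eigenvalues but excludes them from coordinates (no
Cailliez/Lingoes correction).  PERMANOVA uses Anderson's pseudo-F with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) and seeded label permutations;
groups of size 1 are rejected.  The alpha metrics, UniFrac, PCoA and the
PERMANOVA statistic are computed by scikit-bio behind this module's
surface; the test suite cross-checks UniFrac against an exhaustive
branch-enumeration oracle and the rank tests against full enumeration.

## Derived markers

**F:B ratio.**  ln(ΣFirmicutes / ΣBacteroidetes) per sample.  Natural log,
recorded in the output (the base is a convention; group differences are
rank-tested so the choice only scales the reported means).  When either
phylum sum is zero, one count is added to both sums and the sample is
flagged (`when_zero` policy; `always`/`never` selectable).

**Chloroplast diet proxy.**  Plant chloroplast 16S reads in faeces measure
plant intake.  The per-sample chloroplast fraction is
chloroplast/(chloroplast + bacterial) reads; for gradient testing the
(chloroplast, rest) two-part composition is CLR-transformed — equivalently
½·ln(f/(1−f)) — rather than embedding chloroplast features in the full
bacterial composition, so the proxy is insensitive to bacterial
composition shifts.  The alternative (full-composition CLR) is available
by passing the chloroplast features through the ordinary scan.  Sign
convention: all ρ are computed against wildness-ascending coding
(captive = 1 … wild = 4) and the captive-ascending negation is reported
alongside, since both conventions circulate.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
sequence-level reality.  For sample i of individual j at level s:

    w_k = α_k + β_k·s + u_j          (log-weights, bacterial features)
    p   = softmax(w), rescaled so chloroplast features jointly occupy
          chloroplast_fraction_by_level[s]
    counts ~ DirichletMultinomial(depth_i, p/θ),  depth_i ~ logNormal

Defaults: 100 bacterial features + 5 chloroplast features; baseline
α_k ~ N(0, 1); 10 planted features at a slope giving latent |ρ| ≈ 0.8
(derived analytically from the variance decomposition, see
`slope_for_latent_rho`), half positive (labelled Firmicutes — wild-
enriched) and half negative (Bacteroidetes — captive-enriched); depth
logN(ln 20000, 0.25); θ = 0 (pure multinomial); chloroplast fractions
(0.001, 0.005, 0.05, 0.10) rising with wildness; sampling skeleton =
the reference design of 111 samples (12/2, 15/7, 18/18 samples/individuals,
and 66 wild samples of which 26 come from 8 identified individuals and 40
from an unidentifiable pool whose true individuals are drawn internally
from the identified animals plus never-identified extras).

Planted features receive a deterministic baseline −β_k·center so their
abundance crosses the typical feature's at the chosen gradient point:
at the default midpoint (2.5) they swing symmetrically; the
`directional_preset` centres them at 4.5 (mirrored for negative slopes)
so each planted taxon falls below detection at its opposing gradient end —
the "crashes in captivity" regime that produces richness, F:B and
chloroplast orderings in the wild-over-captive direction.

The individual effect u_j is by default a scalar per individual: it models
load/recovery differences and cancels exactly in the softmax, so the
default cohorts satisfy the independence assumptions of the downstream
tests (this is what makes null-calibration results interpretable as test
calibration).  `individual_effect_mode="per_feature"` instead draws
u_jk per (individual, feature), giving replicates correlated compositional
deviations; under that regime the per-sample tests are anti-conservative
by design — it exists to demonstrate the pseudoreplication problem the
collapse pass addresses, and calibration claims do not apply to it.

What the generator does **not** emulate: sequencing error, chimeras and
contamination, phylogenetic correlation of abundances (the random tree is
independent of the planted slopes), copy-number variation, nonlinear or
non-monotone gradient responses, and realistic rank-abundance tails.
Passing recovery/calibration tests therefore demonstrates correctness of
the statistical machinery under the stated model, not performance on real
sequencing data.

## Numerical choices and degenerate inputs

- Polyserial: likelihood probabilities clipped at 1e-300; constant x or
  single-level y raise; non-negative curvature at the optimum yields
  se = ∞ and Wald p = 1.
- Wilcoxon: exact enumeration when both n ≤ 10 and no ties, otherwise
  normal approximation with midrank tie correction and continuity
  correction.
- Kruskal-Wallis on all-identical data returns p = 1 with an explicit
  flag instead of raising.
- CLR on a sample with fewer than two non-zero features raises; columns
  re-sum to zero within 1e-9.
- Rarefaction is exact multivariate-hypergeometric subsampling; samples
  below depth are dropped and reported, and a sample exactly at depth is
  returned unchanged.
- All stochastic steps take explicit integer seeds; two runs with the same
  seed are byte-identical.

## Problem sizes used in the shipped checks

The automated checks run cohorts at the reference design size
(111 samples, 100–105 features), 10–20 seeds per calibration claim,
100 replicates per polyserial recovery setting (n = 2000), 200 runs for
PERMANOVA type-I error (n = 24, 199 permutations), and 100 random trees
(≤ 6 leaves) for the UniFrac oracle. These sizes give stable Monte-Carlo
estimates for the claims tested while keeping a full run in the
low minutes on one core.

## Known limitations

- The polyserial model assumes a linear latent relationship on the CLR
  scale; strong non-monotone responses (e.g. taxa peaking at intermediate
  wildness) are attenuated and may be missed — by design, the statistic
  characterises gradients.
- Holm across hundreds of features is conservative; the BH-adjusted
  collapsed pass is the anti-conservative counterweight, and disagreement
  between the two passes is informative rather than an error.
- The two-step polyserial estimator is consistent but not fully efficient
  relative to joint ML; at cohort sizes of ~100+ samples the difference is
  far below the selection thresholds.
- The unknown-pool collapse treats all unidentifiable wild samples as one
  pseudo-individual, which over-collapses if the pool actually spans many
  animals — the conservative direction for a robustness check.
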