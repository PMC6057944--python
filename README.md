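# gradientscope

Compositional analysis of gut-microbiome count data along an ordered
"lifestyle" gradient — the study design used to compare wild, semi-wild,
semi-captive and captive populations of the same host species (e.g.
red-shanked doucs sampled across zoos, rescue centres and native forest).

The question such studies ask is not "do two groups differ?" but "which
taxa and functions track the *gradient* from captivity to the wild?".
gradientscope treats the four ordered habitat classes as a discretisation
of a latent wildness continuum and tests every feature against it.

## What it computes

Given a feature-by-sample count table (OTUs, genera or predicted KEGG
modules), a GreenGenes-style taxonomy, per-sample metadata (individual id
and lifestyle level) and optionally a rooted phylogeny:

1. **Compositional preprocessing** — genus-level binning (features whose
   genus is uncharacterised bin at their lowest characterised rank),
   prevalence/abundance filtering (present in ≥ 3 samples, mean relative
   abundance ≥ 0.01%), and the centred log-ratio transform
   clr(x)ᵢ = ln xᵢ − (1/D)Σⱼ ln xⱼ with multiplicative detection-limit
   zero replacement.
2. **The gradient statistic** — for each CLR feature the polyserial
   correlation ρ with the ordinal lifestyle y ∈ {captive=1 < semi-captive=2
   < semi-wild=3 < wild=4}: thresholds τⱼ = Φ⁻¹ (cumulative category
   proportions), then ρ̂ maximising
   Σᵢ log[Φ((τ_{yᵢ} − ρzᵢ)/√(1−ρ²)) − Φ((τ_{yᵢ−1} − ρzᵢ)/√(1−ρ²))],
   with a likelihood-ratio χ² p-value (df = 1) and a Wald "confidence"
   p-value from the observed information.
3. **Dual-criterion selection** — a feature is a gradient biomarker only if
   |ρ̂| ≥ 0.3, Holm-adjusted χ² p ≤ 0.05, Wald p ≤ 0.05, **and** a
   Holm-adjusted Wilcoxon rank-sum test comparing the gradient extrema
   (captive + semi-captive pooled vs wild) has p ≤ 0.05.
4. **Diversity** — observed richness, Chao1, Shannon (bits), Simpson with
   ANOVA + pairwise Welch tests; Bray-Curtis and weighted/unweighted
   UniFrac with PCoA and PERMANOVA (Adonis).
5. **Derived markers** — the natural-log Firmicutes:Bacteroidetes ratio
   (Kruskal-Wallis + pairwise Wilcoxon) and a chloroplast dietary proxy
   (plant chloroplast reads as a quantitative signal of plant intake).
6. **Pseudoreplication guard** — replicates of each individual are
   collapsed to averaged profiles (unidentifiable wild samples into a
   single pool) and the scan re-run with Benjamini-Hochberg adjustment.
7. **Synthetic cohorts** — a Dirichlet-multinomial generator that plants
   known gradient slopes, phylum labels, a chloroplast fraction rising with
   wildness, and the exact 111-sample / 36-individual replication skeleton
   of the motivating study, for power and calibration analysis.

## Worked example

```python
from gradientscope import CohortConfig, FeatureTable, generate_cohort
from gradientscope.compositional import clr_transform
from gradientscope.gradient import gradient_scan
from gradientscope.markers import fb_ratio

cfg = CohortConfig(seed=42)          # 100 taxa, 10 planted, 111 samples
table, meta, tax, truth = generate_cohort(cfg)
bact = FeatureTable(table.data.loc[~truth.is_chloroplast])
scan = gradient_scan(clr_transform(bact), meta)
print(scan[scan.selected][["rho", "rho_p_adj", "wilcoxon_p_adj"]]
      .sort_values("rho", ascending=False).round(4).head(4))
fb = fb_ratio(bact, tax, meta)
print(fb.group_summary["mean"].round(2))
```

prints

```
               rho  rho_p_adj  wilcoxon_p_adj
feature_id
OTU0097     0.8175        0.0             0.0
OTU0072     0.8072        0.0             0.0
OTU0061     0.8051        0.0             0.0
OTU0042     0.6925        0.0             0.0
captive         0.52
semi-captive    0.54
semi-wild       0.55
wild            0.57
```

The scan recovers all 10 planted gradient taxa (the cohort plants them at a
latent |ρ| ≈ 0.8; positive-slope rows like `OTU0097` are wild-enriched)
with no false selections among the 90 null taxa, and the log F:B group
means rise monotonically from captive to wild, the direction expected of a
wildness gradient.  Every reported ρ uses the wildness-ascending coding
(captive = 1 … wild = 4); flip the sign for the captive-ascending
convention.

A command-line layer exposes the same steps
(`gradientscope simulate|bin|filter|clr|rarefy|collapse|alpha|beta|pcoa|permanova|gradient|fb|diet|run`),
each writing TSV output plus a JSON provenance sidecar.

## Layout

- `gradientscope.core_data` — domain types + TSV/Newick I/O
- `gradientscope.synthetic` — cohort generator and random phylogeny
- `gradientscope.compositional` — binning, filtering, CLR, rarefaction, collapse
- `gradientscope.diversity` — alpha/beta diversity, PCoA, PERMANOVA, rank tests
- `gradientscope.gradient` — polyserial fit, Holm/BH, selection rule
- `gradientscope.markers` — F:B ratio, diet proxy, heatmaps, pipeline driver

See `docs/methods.md` for the statistical model, parameter choices and
limitations.
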