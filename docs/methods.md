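# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the open design choices made in `hifmeth`.

## Differential calling

Both platforms are tested with the same two-group machinery on a
features × samples matrix with ≥ 2 replicates per group.

**Effect sizes.** Expression effects are reported as
log2FC = log2((μ_B + ε)/(μ_A + ε)) on raw group means with pseudocount
ε = 1, so low-abundance genes cannot produce unbounded fold changes.
Methylation effects are Δβ = mean β(B) − mean β(A), on the β scale (not
M-values) because the downstream gates are defined in β units.

**Test.** The default is a variance-moderated t-test in the style of
empirical-Bayes expression analysis: per-feature pooled variances s²_g
(df d_g = n_A + n_B − 2) are shrunk toward a prior (d₀, s₀²) fitted by
moments on log s²_g (trigamma inversion by Newton iteration), and the
moderated statistic is referred to a t distribution with d₀ + d_g df
(normal when d₀ → ∞). The rationale is power at triplicate sample sizes:
with n = 3 per group, a purely per-feature test of a log2 effect of 2 at
noise sd 0.5 yields p ≈ 0.008 (df 4), which cannot survive a BH correction
across thousands of features, so planted-effect recovery would sit near
zero rather than the intended ≥ 0.9. Variance pooling is the standard
remedy in this field for exactly this design. A per-feature Welch t-test
remains available (`method="welch"`) for heterogeneous-variance data.

**Degenerate rows.** Rows with zero variance in both groups get p = 1 when
the group means agree and p = 0 when they differ; effects are still
computed from the means. This avoids NaN propagation on toy inputs.

**Gates.** Expression: |log2FC| strictly > 0.5 and BH q < 0.05.
Methylation: |Δβ| strictly > 0.2 and q < 0.05. The strict inequalities are
deliberate — a feature at exactly the threshold is excluded. By contrast,
the enhancer target-linking gate is inclusive (|log2FC| ≥ 0.2), matching
the looser screening role it plays there.

**Sign convention.** Effects are second-named group minus first-named
reference, so a "HYP vs NX" contrast reads as hypoxia relative to
normoxia; a probe gaining methylation in hypoxia has positive Δβ.

## Set crossing and concordance

Crossing two filtered directional gene sets partitions A ∪ B into
exclusive-A, exclusive-B and common; set identities
(|A| = |exclusive-A| + |common|, etc.) are enforced by construction and
property-tested against direct set enumeration. Common genes are
classified concordant/discordant by the sign of the two fold changes, not
by the direction labels, so the classification stays meaningful when the
two contrasts used different magnitude gates. Genes with a fold change of
exactly zero in either contrast (possible only on unfiltered inputs) are
reported separately rather than forced into either class.

## Probe annotation and enrichment

CGI-centric annotation is purely positional: inside an island → island;
distance d to the nearest island edge: d ≤ 2 kb → shore, 2–4 kb → shelf,
> 4 kb → open sea. Exact 2000/4000 bp boundaries fall in the band nearer
the island (inclusive-lower, the common array-manifest convention). A
chromosome without islands is all open sea. Strand is ignored throughout.

Feature distributions of a probe selection are compared to the full
manifest background with one-sided hypergeometric tails in both
directions; the reported p is twice the smaller tail (capped at 1), BH is
applied across the features of one annotation system, and over/under
calls are made at q < 0.05. Gene-set over-representation intersects each
category with the background first, drops categories below the minimum
size (default 10), computes P(overlap ≥ observed), and applies BH across
tested categories (enriched at q ≤ 0.05).

## Inverse expression–methylation pairing

A pair is retained when the probe passes |Δβ| > 0.2, both the probe and
its *manifest-annotated* gene pass the p gate, and the signs of Δβ and
log2FC are opposite. The p gate defaults to the nominal p-value on both
sides (switchable to BH q): the reference pair tables include genes whose
fold changes sit below the full DE filter, so the pairing step is
demonstrably looser than the DE filter and the nominal default reproduces
their membership. Probes without a gene link (intergenic) are skipped and
counted, not errors; a gene annotated by several probes yields one row
per probe. Probe-to-gene linkage here is manifest-based by design —
distance-based search is the enhancer module's job.

## Enhancer filtering, linking and dependency

A probe is *active* if any marker interval covers its position in any
cell line and *stringent* if ≥ 4 distinct markers cover it in **every**
cell line; the stringent reading was chosen over "≥ 4 pooled across cell
lines" because requiring support in all assayed lines is the conservative
interpretation, and the per-cell-line counts are reported either way.
Stringent probes are linked to every gene whose TSS (the conventional
regulatory anchor) lies within ±1 Mb and whose hypoxia-contrast
|log2FC| ≥ 0.2; probes with no in-window responsive gene are reported
with an empty link rather than dropped.

Dependency labels per link:

* **hif1a_independent** — probe not significant in the HIF1A-silencing
  contrast (|Δβ| ≤ 0.2 or q ≥ 0.05) *and* target not significantly
  responsive there (|log2FC| < 0.2 or q ≥ 0.05). Significance, not
  magnitude alone, defines "not responsive": at triplicate sample sizes
  the fold-change noise routinely exceeds 0.2, so a magnitude-only rule
  would misclassify genuinely unresponsive targets.
* **hif1a_dependent** — probe Δβ inverts (opposite sign, past the gate)
  and target log2FC inverts significantly.
* anything else — **ambiguous**, reported, never silently dropped.

Per-probe summaries take dependent > independent > ambiguous over the
probe's links; the ordering is unambiguous because a non-significant
probe cannot produce a dependent link and an inverted probe cannot
produce an independent one.

Percentages (active fraction, risk percentages) are formatted as
100·k/n rounded half-up to one decimal.

## Cohort signature clustering

Signature rows are z-scored with the sample (n − 1) standard deviation
(the dominant convention in expression-heatmap tooling); zero-variance
genes are dropped with a warning. Patients are clustered agglomeratively
on Euclidean distances with complete linkage by default (deterministic
and a common heatmap default; average and Ward are exposed) and the
dendrogram is cut into exactly two clusters. The high-majority cluster is
the one holding most high-risk patients, ties going to the smaller
cluster (deterministic); the low-risk percentage is scored on the other
cluster. Association is tested by permutation: shuffling risk labels with
cluster sizes fixed makes the high-risk count in one cluster
hypergeometric, so the null is sampled directly from that distribution
(10 000 draws by default, seeded) and compared on the 2×2 chi-square
statistic with an add-one correction, so the p-value is never exactly 0.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with one
master seed driving deterministic per-stage substreams.

* **Expression**: per-gene baselines log-uniform in [1, 1000] FPKM-like
  units; replicate noise normal on the log2 scale (default sd 0.5, a
  calibration choice — replicate-level variance is not something the
  emulated design pins down). Planted classes realise their defining
  contrasts through per-condition log2 offsets of magnitude 2 by default:
  exclusive-normoxia/hypoxia genes shift in one silencing contrast only,
  concordant/discordant HIF1A targets shift in both with equal/opposite
  signs, and HIF1A-independent hypoxia responders shift under hypoxia
  with the same direction of change in the silenced-hypoxia contrast.
* **Methylation**: β values are Beta-distributed around planted
  per-condition means (concentration 100 ⇒ sd ≈ 0.05 at β = 0.5),
  respecting the [0, 1] support; baselines are re-centred so a planted
  ±0.3 shift stays inside (0.05, 0.95), with clamping and a warning
  otherwise. Oxygen-driven probes shift in both hypoxic conditions,
  HIF1A-contrast probes only in the silenced-hypoxia condition, and
  common-inverted probes shift in hypoxia and revert when HIF1A is lost.
* **Coordinates**: a single reference genome of n_chromosomes × 20 Mb with
  genes, probes and CpG islands placed uniformly; the manifest assigns
  CGI features positionally and links probes to the nearest gene within
  100 kb (IGR beyond). Probes planted as inverse-pair partners are moved
  next to their gene's TSS.
* **Marker tracks**: every enhancer probe is covered by all four markers
  in all three cell lines; a handful of decoy probes get ≤ 3 markers so
  the stringent filter has true negatives, and background intervals never
  contain a probe position. Independent-pattern enhancer probes are
  recruited from the oxygen-driven methylation classes with a planted
  in-window target that responds to hypoxia but not to silencing;
  dependent-pattern probes come from the common-inverted class with a
  target whose response reverts. Defaults plant 9 independent and 5
  dependent enhancer probes.
* **Cohort**: 40 low-risk and 56 high-risk patients; 30 signature genes
  shifted by 3 units (sd 1) between classes with random per-gene sign,
  non-signature genes exchangeable between classes.

What the generator does **not** emulate: realistic 450K probe density or
chemistry, read-level data, count-based expression noise, correlated
genes or probes, batch structure, copy-number/NMYC amplification, or
survival times. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration under the stated noise models, not
performance on real array or sequencing data.

## Problem sizes and tolerances

The test suite and the acceptance script run the generator at 800 genes ×
1500 probes × 3 replicates (cohort 96 patients), sizes chosen so every
planted class has tens of members while a full run stays in seconds.
Planted-contrast fidelity is asserted within 3 standard errors of the
configured effect; null calibration is asserted over 20 seeds against
nominal FDR + 2 binomial SE; hypergeometric p-values are checked against
brute-force enumeration to 1e-12 on universes ≤ 30; interval overlap is
checked against an all-pairs membership oracle.

## Known limitations

* The moderated test assumes roughly exchangeable per-feature variances;
  data with strong mean–variance trends would warrant a trend-fitted
  prior, which is not implemented.
* Two-sided feature-representation p-values double the smaller
  hypergeometric tail, which is conservative for very skewed margins.
* The permutation test conditions on the observed cluster sizes; it does
  not account for the clustering step having seen the same data, so the
  p-value is descriptive of the association, not a selective-inference
  guarantee.
* Linkage distance is probe-to-TSS only; no strand, promoter width or
  contact-map information is used.
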