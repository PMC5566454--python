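# Methods

triomix analyses paired cartilage samples — one intact and one degraded
sample from the same patient's joint — across three molecular layers,
and integrates the results. This note records the models, the defaults
and why, the numerical choices, and what the synthetic cohorts do and
do not establish.

## Study design and data model

Every statistical contrast in the package is within-patient: the sample
sheet pairs each patient's intact and degraded sample, and all tests
condition on patient identity. Inputs are post-QC matrices — normalised
CpG beta values (probes × samples, complete), gene-level read counts
(genes × samples, complete, integer) and protein abundances (proteins ×
samples, positive, missing allowed) — plus a probe manifest with 450k
style feature annotations (TSS200, TSS1500, 5'UTR, 1stExon, Body,
3'UTR, intergenic), BED-like gene models with summed exonic length, and
GMT gene-set collections. All intervals are 0-based half-open (BED
convention). Upstream steps (alignment, counting, array QC and
quantile normalisation, spectral processing) are out of scope; the
package starts where the statistics start.

## Differential methylation

Per probe, the model is a linear model for tissue status with patient
identity as covariate. On a complete paired design the status
coefficient's t-test is algebraically identical to the paired t-test on
per-patient beta differences (degraded − intact), which is how it is
computed — vectorised over all probes; the equivalence to an explicit
blocked OLS fit is verified numerically in the tests. Probes with zero
within-pair variance get p = 1 (keeping the BH input complete) rather
than an undefined statistic. Betas are tested directly on the beta
scale; an M-value transform is deliberately not applied, matching the
convention of the array toolchain being emulated.

Differentially methylated probes (DMPs) are probes with BH q ≤ 0.05.
A differentially methylated region (DMR) is a run of consecutive
manifest probes with at least 3 significant probes, at most 3
non-significant probes in total, every adjacent-probe gap ≤ 1,000 bp,
and both endpoints significant. Two points in this definition are
under-determined and were fixed as package design choices:

- *"at most 3 non-significant"* is counted over the whole region, not
  as a consecutive run; both readings are implemented
  (`nonsig_mode={"total","consecutive"}`), total is the default.
- Maximal valid windows can overlap, so the caller uses a deterministic
  greedy rule: among all valid windows, repeatedly keep the
  leftmost-starting (longest on ties) window and discard windows
  overlapping it. This makes the output unique, disjoint per
  chromosome, and equal to an exhaustive window-enumeration oracle,
  which the test-suite checks on thousands of random manifests.

DMR-to-gene assignment intersects each region with gene spans extended
1,500 bp upstream of the TSS (strand-aware; the distance matches the
array's TSS1500 annotation convention and is configurable). The
promoter-level analysis averages each gene's promoter-probe
(TSS200 ∪ TSS1500) betas per sample and applies the paired t-test per
gene with BH correction; genes without promoter probes are excluded
with a logged count.

## Differential expression

The per-gene model is the paired NB2 GLM

log μ = log(effective library size) + β₀ + patientᵢ + β·status,  Var(Y) = μ + φμ²

fitted by iteratively reweighted least squares, batched across genes
(the design matrix is shared; per-gene weights enter through
batched normal equations). The status effect is tested by a
likelihood-ratio chi-square test on 1 df; the reported effect is
β/ln 2, a log2 fold-change (degraded over intact). The LRT was chosen
over a quasi-likelihood F-test as the simpler construction with one
fewer estimated quantity; its adequacy is established empirically by
the null-calibration suite rather than assumed.

Library composition is normalised by trimmed-mean-of-M (TMM) factors:
reference sample by upper-quartile proximity to the mean upper
quartile, 30% two-sided trim on M-values, 5% on A-values, genes with a
zero in either sample excluded, precision weights from the binomial
delta-method variance, factors rescaled to geometric mean 1.

Dispersions are estimated in two stages from Poisson-fitted
patient+status means: a common φ₀ solving the pooled Pearson chi-square
moment equation (which accounts for the residual degrees of freedom,
df = samples − patients − 1), and gene-wise estimates solving the same
equation per gene, floored at 0. Gene-wise values are shrunk toward φ₀
with weight prior_df/(prior_df + df), prior_df = 10 — the documented
default of the framework this module re-implements. Genes with all-zero
counts are dropped (logged) to mirror a post-QC expressed universe.
Non-converged fits (typically genes with a zero group, where the MLE
diverges) are flagged, reported with missing p, and excluded from BH.

FPKM is counts / ((length/10³) · (total/10⁶)) per sample, provided for
reporting; it plays no role in testing.

## Differential protein abundance

Per patient, the log2 abundance ratio degraded/intact is defined only
when both pair members are detected. A protein is called differential
when all three hold: |median ratio| ≥ 0.75, |median ratio| > sample
standard deviation (n−1 denominator) of the ratios, and at least 5
patients contribute a paired detection. The 0.75 threshold is read on
the log2 scale: a linear-ratio bound of 0.75 cannot express
up-regulation, and label-based quantitation conventionally reports log
ratios; the scale is configurable and the reading is recorded as an
assumption. This layer has no sampling model, hence no p-values; its
output carries per-criterion flags so failed calls can be audited.

## Integration, replication, enrichment

Overlap between two differential feature lists is tested with the
one-sided upper-tail hypergeometric distribution against the universe
of features quantified in both layers (the universe is always explicit,
never implied). Direction concordance among overlapping features uses
the two-sided exact binomial test at p₀ = 0.5, computed as twice the
smaller tail capped at 1 — the convention that reproduces the worked
concordance p-value of 0.0002 for 26 of 31. Zero-effect features have
no sign and are excluded with a logged count. Effect-size correlations
use Pearson or Spearman as requested. The evidence table counts, per
gene, the distinct omics levels with differential evidence; DMR overlap
and promoter-level significance jointly count as the single
methylation level.

Replication concordance restricts to features passing QC in both
cohorts, then reports, over discovery-significant features: the
proportion with the same direction of change in replication (zero
replication effects count as discordant, logged) and — among the
same-direction features, i.e. as a conditional proportion — the
proportion reaching nominal significance (replication p ≤ 0.05), plus
effect correlations over all common and over significant features.

Gene-set enrichment per omics layer is the one-sided hypergeometric
test with BH across sets and fold enrichment
(share of significant genes in set) / (share of universe in set).
Empirical p-values redraw the significant-gene list uniformly from the
universe (preserving its size) and use the add-one convention
(1 + #{null ≥ observed})/(n_rand + 1), never zero, deterministic under
the seed. The integrative statistic per set is the geometric mean of
its three per-omics p-values; its null redraws the three significant
lists independently from their own universes, ignoring gene-level
correlation between layers (a documented limitation — the alternative
of permuting set labels is also implemented). Sets are intersected with
each omics' universe and kept when at least 5 in-universe genes remain
in at least 2 layers.

**Tie handling in empirical p-values.** Overlap counts are discrete, so
the conservative convention (ties count as extreme) yields
super-uniform nulls — valid for inference but not uniform, and a
uniformity check would rightly reject it. The package therefore also
provides `tie_break="randomized"`, a Lehmann-style randomized p-value
that breaks ties with independent seeded uniforms and is exactly
uniform under the null. The conservative form is the default for
analysis; the randomized form is what the calibration tests exercise.

## Synthetic cohorts

The generator produces the study conditions at desk scale: 12 discovery
patients with one intact and one degraded sample each; 20,000 probes,
2,000 genes and 500 proteins standing in for the 425,694 probes, 15,418
genes and post-QC proteome of a full experiment; replication cohorts of
17 (knee) and 9 (hip) patients with planted effects attenuated by 0.5
while keeping their signs.

Genes are tiled on synthetic chromosomes (lengths 2–10 kb, gaps
5–15 kb); half the probes are placed in promoters within 1 kb upstream
of the TSS (so a gene's promoter probes always satisfy the DMR
adjacency rule), 35% in gene bodies, the rest in intergenic space kept
clear of gene territories. Betas are logit-additive: a bimodal baseline
(mixture at logit(0.1)/logit(0.9), sd 0.5), per-(probe, patient)
effects (sd 0.3), residual noise (sd 0.2 on the logit scale — the
range observed for within-pair array variability), and a status shift
on planted DMR probes. Planted probes get mid-range baselines and a
logit shift calibrated so the realised beta-scale difference equals the
configured delta-beta (0.15 by default). Counts are gamma-Poisson with
Var = μ + 0.1μ², per-patient library factors (log-sd 0.3), lognormal
gene rates and planted |log2FC| = 1.5 shifts. Protein log2 abundances
carry patient effects, planted |log2| = 1.0 shifts, residual sd 0.35
(typical isobaric-label ratio noise) and 20% independent per-(protein,
sample) missingness. A configurable subset of DE genes is planted
concordantly on all three layers: promoter DMR with sign-opposed
delta-beta, protein shift with the expression sign.

The truth set records every injection exactly, enabling recall,
precision and empirical-FDR measurement downstream. None of the noise
magnitudes are reported values from any experiment; they are
calibration choices. Consequently, passing recovery tests shows the
pipeline detects effects of the stated sizes under this noise model —
not that a real cohort of 12 patients would achieve the same power.
Features of real data deliberately not emulated: probe-level technical
artefacts (cross-reactive probes, SNPs under probes), count outliers
and sample-quality gradients, protein missingness that depends on
abundance (the generator's missingness is completely at random), and
correlation between methylation and expression noise within a patient.

## Problem sizes and numerics

Default test and acceptance runs use the scaled universes above; the
calibration suites run 10 seeds of 2,000-gene null cohorts, recovery
suites 5–10 seeds at the default scale, and the permutation calibration
999 randomisations over 500 sets (the integrative CLI default remains
100,000 randomisations). IRLS iterates to a 1e-8 relative coefficient
tolerance with a 100-iteration cap, a 1e-10 ridge on the normal
equations and linear predictors clipped at ±30; dispersion equations
are solved by 60-step bisection on [0, 100]. BH uses the step-up
running minimum; missing p-values reduce the number of tests and
propagate as missing q.

## Known limitations

- The NB LRT is mildly liberal at n = 12 pairs (null rejection ≈ 6% at
  the 5% level in the calibration suite); a quasi-likelihood F-test
  would tighten this at the cost of an extra estimated quantity.
- The DMR caller's greedy window selection is one deterministic
  resolution of an under-specified rule; alternative resolutions can
  differ on manifests with overlapping valid windows.
- The integrative randomisation null ignores cross-layer correlation of
  gene-level evidence, so its empirical p-values are calibrated against
  an independence null only.
- The proteomics rule has no error model; its operating
  characteristics are purely empirical (measured on synthetic data).
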