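# Methods

`tadscape` re-implements, as a reusable and testable pipeline, an
integrative analysis of what happens to the epigenome and the 3D genome
of mouse embryonic stem cells when linker histone H1 is depleted to
~50% of its normal stoichiometry (the H1c/H1d/H1e triple knock-out,
"TKO", versus wild type, "WT"). The analysis has four statistical
layers, each available as a library module, plus a synthetic-data
generator that plants every effect the pipeline is supposed to detect
so that all estimators can be validated against known truth.

## 1. Differential DNA methylation (`tadscape.methylation`)

The methylation assay contrasts two restriction digests at CCGG sites:
HpaII cuts only unmethylated sites, MspI cuts regardless. Relative
HpaII signal therefore reports the *unmethylated* fraction.

**Score.** Per site we compute a 0–100 methylation score

    score = 100 · (1 − (2/π) · atan2(hpaii/d_h, mspi/d_m))

with `d_h`, `d_m` the HpaII/MspI library depths. This is a stated,
monotone stand-in for the published HELP-angle: it maps (no HpaII
signal) → 100, (no MspI signal) → 0, equal normalized counts → 50, and
is strictly decreasing in HpaII signal. The original angle's
MspI-depth confidence weighting is not reproduced; any monotone
transform gives identical site rankings, which is all downstream
analyses use.

**Test.** Differential methylation per site is an exact two-sided
binomial test conditional on the total HpaII count: under no change,
`x = hpaii_TKO` out of `n = hpaii_WT + hpaii_TKO` is Binomial(n, p0)
with `p0 = d_TKO/(d_WT + d_TKO)`. Two-sided p is `min(1, 2·min(lower
tail, upper tail))` — simple and verifiable against direct tail
summation (the suite checks agreement to 1e-12 up to n = 1000). Sites
with TKO HpaII excess at p < 1e-6 are *hypo*methylated in TKO, deficit
sites *hyper*. The "stringent" class additionally requires a score
delta of ≥ 25 units (of 100); the delta is configurable since only
"more stringent criteria" is specified upstream.

**Clustering.** The window permutation test tiles each chromosome with
fixed windows (20 kb default, last partial window kept, anchored at
coordinate 0), counts windows holding ≥ 5 differential sites, and
compares against draws of the same number of sites sampled uniformly
without replacement from all assayable sites; empirical
p = (1 + #{null ≥ observed})/(draws + 1).

**States.** Chromatin-state composition assigns each site to the state
at its midpoint and reports a size-matched random-site baseline.

## 2. Differential DNase/ChIP signal (`tadscape.sites`)

Regions with replicated counts per condition are normalized with
library size factors (total / geometric mean of totals) and tested with
a pooled exact conditional binomial test, the same construction as the
methylation test but on pooled replicate sums with p0 from the summed
size factors. This deliberately replaces the two external tools the
original analysis used (a Poisson-sequencing FDR tool for DNase, a
sliding-window ChIP caller) with one oracle-checkable test; their
thresholds survive as the two calling modes: DNase mode controls the
Benjamini–Hochberg FDR at 5%, ChIP mode thresholds raw p at 0.001.
log2 fold changes use a 0.5 pseudocount so zero counts stay finite.

**De novo sites.** A de novo DHS is called in TKO only, overlaps no WT
DHS call, and has WT H3K4me1 *and* H3K4me3 signal below the 25th
percentile of WT called-peak signal (the "not bookmarked" condition);
de novo H3K4me1 sites are defined symmetrically against WT H3K4me3 and
DHS. The quantile is exposed (`--wt-quantile`) because the upstream
description gives only "threshold levels".

**Overlap and concordance.** Set overlap is an upper-tail
hypergeometric test over a shared region universe (membership = ≥1 bp
overlap); cross-mark concordance is a gain/loss 2×2 table plus Spearman
correlation of the paired fold changes over jointly significant
regions.

## 3. TAD-level enrichment (`tadscape.tads`)

TADs are ranked by any per-TAD key (gene content, change counts,
domain-score delta), split into five bins of equal TAD count
(ascending; remainder TADs go to the lowest bins; ties broken by
genomic order), and each feature's per-bin percentage, enrichment ratio
against a reference distribution, and a 4-df Pearson chi-squared
against the reference proportions are computed. Sites map to the TAD
containing their midpoint; genes to the TAD containing their TSS (an
any-overlap mode exists behind a flag — the TSS is the regulatory
anchor, and a gene body may straddle a boundary). Sites in inter-TAD
gaps are reported in an `unassigned` bucket and excluded from
percentages so totals stay auditable. TSS-proximal change rates count a
gene when a changed site's midpoint lies within ±2500 bp of its TSS.

## 4. Hi-C topology (`tadscape.hic`)

Contacts are binned at 100 kb per chromosome (cis only; trans pairs
feed the cis/trans QC ratio). Matrices are balanced by Sinkhorn-style
iterative correction (`m ← m / √(s sᵀ)` on row sums s) after masking
bins with row sum below 10% of the median; the published analysis's
normalization is not specified beyond a citation, so the modern
convergence-testable standard is used, and equivalence is claimed only
at the level of qualitative invariants.

* **Distance decay** — mean contact per bin distance, log–log slope as
  the decay exponent, and the contact-fraction-per-distance-band curve.
* **Compartments** — observed/expected, Pearson correlation matrix,
  first principal component per chromosome (no genome-wide stitching),
  sign oriented so PC1 correlates positively with gene density
  (A = positive).
* **PE-SCAN** — average observed/expected window ((2·flank+1)², flank 5)
  over all anchor pairs 2–50 Mb apart; center enrichment = center cell /
  mean border cell.
* **Domain score** — per TAD, intra-domain contacts (upper triangle,
  diagonal included) over cis contacts crossing the boundary, with a
  pseudocount of 1 so zero-inter TADs stay finite; computed on balanced
  matrices by default (a raw-matrix flag exists; the upstream choice is
  unstated). WT and TKO scores are compared with a two-sided Wilcoxon
  rank-sum test, and the per-TAD delta drives the quintile coupling
  analysis, with negative-control rankings by gene count, TAD size and
  DE-gene count.

## The synthetic genome (`tadscape.simulate`)

The generator emulates the study's signal structure, not its genome:
2 chromosomes × 30 Mb, 100-kb Hi-C bins, 200 TADs tiling the
chromosomes on bin boundaries, 2000 genes, 50,000 methylation sites,
5000 signal regions. Defaults are the study conditions:

| parameter | default | emulates |
|---|---|---|
| `gene_density_gradient` | 12 | top gene-content quintile holds >50% of genes, bottom 3–4% |
| `hypo_to_hyper_ratio` | 14 | 93% vs 7% stringent hypo/hyper asymmetry |
| `dmr_fraction` | 0.015 | ~1.5% of assayable sites differential |
| `dmr_gene_density_skew` | 4 | DMR concentration in gene-dense TADs |
| `dmr_cluster_size` | 5 | local clumping that the 20-kb window test detects |
| `gain_fraction`, `loss_fraction` | 0.02 | ~2% of regions gain/lose signal |
| `concordance_prob` | 0.3 | ~⅓ of new DHSs also gain H3K4me1 |
| `repressive_change_fraction` | 0 | near-negligible H3K9me3/H3K27me3 change |
| `de_fraction`, `down_fraction` | 0.03, 0.8 | small, >75%-down DE gene set |
| `decay_exponent` | 1.0 | power-law contact decay |
| `compartment_strength` | 0.3 | A/B checkerboard |
| `tad_block_strength` | 1.0 | TAD insulation |
| `domain_score_shift` | 0.6 | TKO-specific insulation loss |
| `altered_tad_fraction` | 0.2 | subset of (preferentially gene-dense) TADs carrying that loss |

Mechanics worth knowing:

* **One root seed, fixed sub-streams.** Each simulator derives its RNG
  as `default_rng([seed, stream_id])`, so adding a simulator never
  perturbs the others and identical parameters give bit-identical
  output.
* **Compartments first, genes second.** Alternating A/B blocks of
  ~15–25 bins are laid down, then TAD gene rates follow the A-fraction
  of the TAD (rate = g^(1.25·u) over density rank u, which makes the
  expected top/bottom quintile gene ratio equal g). Gene-dense TADs
  therefore sit in A compartments, which is what lets the compartment
  eigenvector be sign-oriented by gene density.
* **Change placement.** Planted epigenetic changes (DMRs, signal
  gains/losses) fall on TADs with weight `skew^(u + boost·altered)`:
  at skew = 1 placement is exactly uniform; at the default skew the
  changes concentrate in gene-dense and, additionally, in altered TADs,
  which is what makes the domain-score-delta coupling plantable.
* **Count models.** Methylation counts are negative binomial
  (dispersion 50 — mild overdispersion; the binomial test is exactly
  valid only for Poisson-like counts, and strong overdispersion would
  make the planted truth unrecoverable by *any* binomial test); signal
  regions and Hi-C are Poisson around stated expectations, the simplest
  models consistent with the downstream conditional tests. No
  generative distributions are specified upstream; all are implementer
  choices.
* **Planted methylation effects are near-saturating** (latent
  methylation moves between ~0.93 and ~0.07), giving score deltas of
  ~60 units at 30× depth — comfortably past both the p < 1e-6 and the
  Δ ≥ 25 stringency gates, so sensitivity is power-limited only by
  count noise.
* **Signal regions** sit on a 1-kb slot grid (never overlapping each
  other), carry heterogeneous peak strengths (0.8–3× nominal depth),
  and per-library depth factors of 0.7–1.4× exercise the size-factor
  normalization. Bookmarked DHS gains are planted at strong WT H3K4me1
  peaks so the "not bookmarked" quantile filter has a real margin to
  detect them.
* **Hi-C matrices** are Poisson samples of an expected matrix
  d^(−α) × compartment × TAD-block (× altered-TAD inflation of
  cross-boundary contacts in TKO), symmetrized, ~1M reads split across
  chromosomes by length.

### What the generator does *not* emulate

Sequence content, read-level data, CpG density covariation,
replication timing, chromosome-specific effects (the sex-chromosome
protection seen in the study), inter-chromosomal contact structure, and
the genome-wide scale of real data. Passing tests therefore demonstrate
that the estimators recover the planted signal structure under the
stated count models — not that the pipeline reproduces the study's
genome-wide counts, which depend on the deposited raw data.

## Numerical choices and degenerate inputs

* Two-sided exact p-values are `min(1, 2·min(tails))` throughout.
* Zero-total sites/regions return NaN p and a "none" label rather than
  failing.
* Balancing raises after 200 iterations without convergence (tol 1e-5
  relative row-sum deviation); degenerate (constant-bin) correlation
  matrices raise in the compartment step.
* TADs spanning < 2 Hi-C bins are skipped with a warning in the domain
  score; the mean TAD here spans 3 bins, which is why the default
  genome is 2 × 30 Mb rather than 2 × 20 Mb — 200 TADs need ≥ 2 bins
  each with headroom for the random TAD-size composition.
* Quintile ties break by genomic order; remainder TADs go to the
  lowest bins.
* The chi-squared test refuses totals < 25 or zero expected bins and
  recommends an exact test.

## Validation experiment sizes

The test suite validates calibration and power at sizes chosen for
statistical resolution: the count test's type-I error is pooled over
10 × 5000 null regions (Monte Carlo SE ~1.4e-4 at nominal 1e-3); the
window permutation test's null p uniformity uses 80k sites over 1600
windows so the statistic has enough support for a KS check (coarser
scenarios fail KS purely through tie inflation of the add-one
estimator); the domain-score Wilcoxon power and size use 100 seeds
each; the DMR quintile enrichment curve is averaged over 12 replicate
simulations because a single draw carries ~150 independent site
clusters and is monotone in only ~⅔ of seeds.

## Known limitations

* The pooled conditional test ignores replicate-level dispersion; a
  negative-binomial GLM would be more robust on real data (explicit
  non-goal here).
* The HELP-angle stand-in is rank-equivalent but not numerically equal
  to the published score.
* PC1 sign orientation needs a non-constant gene-density track; on a
  gene-free chromosome labels are arbitrary.
* Balancing and PC1 are per chromosome; no genome-wide eigenvector
  phasing.
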