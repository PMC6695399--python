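# Methods

## Signal model and normalization

Array signals are modelled as linear-scale fluorescence. Normalization is
the GeneSpring-style sequence: (optional) per-sample mass correction on the
linear scale — each exosomal chip multiplied by 1 ng / loaded RNA mass, so
chips represent a common input quantity — then a detection floor (default:
values < 1 set to 1), then a *percentile shift*: log2-transform and subtract
each chip's Pth percentile of log2 signal. "Normalised to the Pth
percentile" is read as this subtraction (the standard GeneSpring
percentile-shift); a multiplicative linear-scale variant sits behind a flag
and agrees with the default exactly whenever the percentile falls on an
integer rank. P defaults to 75 for mRNA chips and 99 for miRNA chips.
Percentiles interpolate linearly between closest ranks (the numpy default);
the convention is echoed into run metadata. No per-feature baseline
(median) centering exists anywhere in the pipeline, and matrices carry a
`normalized` flag so a second shift raises an error instead of silently
double-normalizing. Mass correction defaults to before flooring/shifting
(a correction of the raw signal); a flag applies it after, as a log2 offset.

Missing values are rejected, never imputed: single-channel exports are
dense, and a hole indicates a malformed file.

## Differential expression

**mRNA (Z-score).** With one pooled fold-change estimate per gene,
significance is assessed against the across-gene distribution:
z = (FC − mean(FC)) / sd(FC), sample sd (n−1), calls at |z| ≥ 2 by default.
The mean-centering makes the up/down cutoffs symmetric even when the bulk
of fold changes is shifted; an uncentered variant is a config switch, and
the cutoff itself is a mandatory config value because 2.0 is a convention,
not a law.

**miRNA (fold + paired t + BH).** Features pass a |log2 FC| ≥ log2(2)
filter, then a two-sided paired t-test on log2 signals (pairing by
replicate index; substate 2 − substate 1). Benjamini–Hochberg q-values are
computed *within the fold-passing subset* — the filter precedes
significance analysis in this workflow's order of operations — with a flag
for genome-wide correction and one for Bonferroni. Calls require
q < 0.05 with the fold-change sign. Degenerate features are explicit:
all-zero differences give p = 1; zero-variance nonzero-mean differences
(possible in tiny fixtures) give a p = 0 sentinel plus a warning rather
than an exception.

## Target integration

Down-regulated miRNAs predict up-regulated mRNAs and vice versa (direction
inversion). A gene qualifies as predicted only when targeted by **strictly
more than** `min_fraction` (default 0.5) of the source miRNA set. The
coverage denominator counts *every* source miRNA — one absent from the
target table targets nothing — which keeps the strict boundary meaningful;
an observed-in-table denominator and a no-filter union mode are flags.
miRNA identifiers are matched after case normalization (`miR`/`let`
conventions preserved); an optional fallback strips the `-5p`/`-3p` arm
suffix when an exact match fails (off by default).

Two integration graphs are provided because both are defensible readings
of the workflow: `common_mirna_first` (default) intersects cell and
exosome miRNA calls per direction before predicting targets;
`per_compartment` predicts from each compartment separately and takes the
three-way intersection with the observed mRNA calls. All gene-level
intersections run in Entrez ID space after applying the symbol → ID map;
symbols without IDs drop out beforehand and are reported. Every
intermediate cardinality (per-compartment calls, common sets, predicted
and mapped set sizes, final candidates) is recorded in the report.

## qPCR confirmation

ddCt with amplification efficiency fixed at 2 (no efficiency correction):
ΔCt = Ct(gene) − Ct(reference) per replicate; fold(substate2 / substate1)
= 2^(mean ΔCt₁ − mean ΔCt₂). The confirmation t-test runs on per-replicate
relative expression 2^−ΔCt (the scale on which such experiments report
mean ± SD), unpaired, two-tailed, equal-variance; a ΔCt-scale test is a
flag. Significance tiers p < 0.1 / 0.05 / 0.01 are reported; *confirmed*
requires a direction-consistent fold ≥ 1.5 **and** p < 0.05. Candidates
absent from the Ct panel are flagged `untested`, not failed.

## The synthetic-study generator

`generate_study` emulates the structure the analysis assumes, with
defaults chosen as a realistic small two-substate design:

| parameter | default | meaning |
|---|---|---|
| n_genes / n_mirnas | 2000 / 300 | features per assay |
| replicates_per_group | 3 | paired chips per substate |
| baseline_log2_mean / sd | 8 / 2 | chip-level log2 signal distribution |
| noise_sd | 0.25 | per-replicate log2 noise (and per-pair batch offset sd) |
| effect_log2fc | 2.0 | planted shift in substate 2 (4-fold) |
| n_de_genes up/down | 100 / 100 | planted DE genes |
| n_de_mirnas up/down | 30 / 30 | planted DE miRNAs |
| compartment_share_fraction | 0.5 | DE miRNAs shared by cell and exosome |
| targets_per_mirna | 25 | target-table row budget per miRNA |
| biomarker_coverage | 0.6 | fraction of planted miRNAs targeting each biomarker |
| n_biomarkers up/down | 14 / 1 | genes planted to survive the full integration |
| qpcr_ct_sd | 0.15 | Ct replicate noise (cycles) |

Signals are log-normal: linear signal = 2^(baseline + pair offset +
group effect + noise). Replicate i of substate 1 shares a per-pair,
per-feature batch offset with replicate i of substate 2, so the paired
t-test is strictly more powerful than an unpaired one — the pairing has a
testable consequence. The estimator for a planted effect has sd
noise_sd·√(2/replicates) (both group means are noisy; pair offsets cancel).

Planted-DE baselines are drawn from the central bulk of the chip
distribution (truncated at mean + 1 sd). Percentile-shift normalization is
only valid when the anchor percentile is carried by invariant features; on
real chips the top percentile belongs to stably high-expressed species
while differential miRNAs are mid-abundance. Without this constraint a
planted 4-fold shift can itself become a chip's 99th-percentile anchor and
bias every feature on that chip — a failure of the normalization's
assumption, not of the analysis under study.

The target table links each planted biomarker-up gene to at least
`biomarker_coverage` of *each stratum* of the planted down-miRNAs (shared,
cell-private, exosome-private), so the biomarkers clear the >50% filter
under either integration strategy; symmetrically for down biomarkers and
up-miRNAs. Decoy miRNAs (and the padding targets of DE miRNAs) point only
at non-DE genes, giving the coverage filter something to reject. The qPCR
panel covers the planted biomarkers: a gene with effect e has its
substate-2 Ct lowered by e cycles around a per-gene baseline Ct drawn from
22–28, reference fixed at 18 cycles. All randomness flows from one integer
seed through a single PCG64 generator; identical seeds give bit-identical
studies across platforms.

What the generator does **not** emulate: probe-level effects and
cross-hybridization, background and spatial artifacts, signal-dependent
(heteroscedastic) noise, miRNA families with shared seed sites, partial
gene-ID coverage (the synthetic ID map is complete), and real TargetScan
context scores. Passing recovery tests therefore demonstrates the
pipeline's correctness and statistical behaviour under its own
assumptions, not performance on any particular real dataset.

## Numerical and design choices

- Percentile: `numpy.percentile`, linear interpolation; cross-checked in
  tests against a sort-based closest-rank oracle.
- BH correction: statsmodels `multipletests`; cross-checked against the
  explicit min-over-tails formula.
- Paired t: vectorized mean/sd computation with explicit degenerate
  handling; cross-checked against `scipy.stats.ttest_rel`.
- Identifier hygiene: gene symbols upper-cased, miRNA IDs lower-cased with
  `miR` restored, before any set operation — case is the dominant mismatch
  source when joining lists from different tools.
- Strict ">" at the coverage boundary: a gene hit by exactly half the
  miRNA set does not qualify.
- Report sizes: analyses at the default scale (2000 genes, 300 miRNAs,
  3 + 3 chips) run in well under a second; the acceptance script's
  Monte-Carlo summaries use 20 effect studies and 50 null studies.

## Known limitations

- The Z-score branch assumes most genes are null; with a large DE
  fraction the across-gene sd inflates and calls become conservative.
- With 3 replicate pairs the paired t has 2 degrees of freedom; power
  near the q < 0.05 boundary is modest, and recovery of planted shared
  miRNAs (hence coverage denominators near the strict 0.5 boundary) is
  the main loss channel for integrated biomarker recovery (~90% at the
  default conditions).
- The 99th-percentile anchor of miRNA chips is estimated from few
  features (3rd-largest of 300 by interpolation) and contributes chip-level
  noise that the paired test absorbs as extra variance.
- No moderated/shrinkage variance estimation (limma-style), permutation
  tests, probe collapsing, or GO enrichment; these are out of scope.
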