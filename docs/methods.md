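# Methods

This note records the models, parameter choices and numerical decisions
behind each module, and what the synthetic-data tests do and do not
establish about real data.

## SNP-to-gene mapping

Clumping is greedy in ascending p (ties broken lexicographically by
rsID): a SNP is retained iff its r² with every previously retained SNP
is strictly below 0.6. This is the standard clumping semantics; the
retained set is pairwise independent and every dropped SNP is tagged by
a retained SNP at least as significant. Block expansion is a single hop
— a known SNP joins if r² ≥ 0.6 with *some* independent SNP; no
transitive closure, so LD chains do not leak distant SNPs into a locus.
Boundary conventions follow the quoted operators literally: independence
is r² < 0.6 (strict), block membership r² ≥ 0.6 and eQTL FDR ≤ 0.05
(inclusive), chromatin FDR ≤ 10⁻⁶ (inclusive).

Coordinates are 0-based half-open internally and in BED output; SNP and
TSS positions are 1-based (VCF/GWAS convention); conversions are
centralized in the type constructors and `io`. Positional mapping
applies the 10 kb window symmetrically up- and downstream of the span
(distance to the nearer edge, inclusive at exactly 10 000 bp); SNPs
inside a span always map to it. The promoter window −250/+500 bp is
strand-aware by default — mirrored about the TSS on the − strand, since
"upstream" follows transcription — with a `strand_aware_promoter=False`
switch for the unmirrored reading, because source descriptions of such
windows frequently leave orientation implicit. A chromatin contact
qualifies a gene only when the SNP and the promoter overlap *opposite*
ends of the interaction. Any eQTL tissue qualifies a gene; tissue labels
are provenance only.

## Variant weighting and burden

The weight ladder is a total function from (consequence class, LOFTEE,
SpliceAI, REVEL, CADD) to {0, 0.2, 0.4, 0.6, 0.8, 1.0}; the tier table
is in the `weighting` module docstring. Decisions where the tier wording
needed interpretation:

* The 0.8 missense tier is REVEL > 0.8. The 0.6 tier is explicitly
  "REVEL > 0.6 and ≤ 0.8", so > 0.8 is the only reading that partitions
  the score range; REVEL = 0.8 exactly therefore falls in the 0.6 tier.
* In-frame indels with CADD ≤ 10 or no CADD score take weight 0.2 as
  "remaining in-frame indels". This is implemented as the single, fixed
  reading rather than a configuration switch: a total, unambiguous
  ladder is worth more than a knob for a corner case.
* Missing scores are conservative: missense without REVEL → 0,
  noncanonical splice without SpliceAI → 0.
* Carrier means allele count ≥ 1 (dominant model, matching the
  heterozygous framing of the underlying genetics). Weight-0 variants
  are carried but contribute burden 0, indistinguishable from
  non-carriage in association.

The ultra-rare filter (popmax AF ≤ 10⁻⁴ and cohort AC ≤ 3) commutes
with weighting, since weights never depend on frequency. A missing
popmax AF is treated as 0 (absent from gnomAD) and logged. Multi-allelic
records must be pre-split; `io.read_vcf` rejects them.

## Association engines

*Fisher collapsing.* Carrier iff burden > τ (default τ = 0, so any
positively weighted variant counts). Two-sided exact p via the
hypergeometric (scipy); OR is the cross-product ratio, with the
Haldane–Anscombe +0.5 applied to all cells and flagged whenever a cell
is zero; an empty margin yields p = 1 and an undefined OR. Fisher's p is
discrete and conservative on sparse tables — its null rejection rate at
α = 0.05 measured over 1000 simulated null genes is ~0.03–0.05, which
the calibration test accepts within 3 binomial SE.

*Logistic score test.* The 1-df score test of the burden coefficient
against the covariate-only null (closed-form null fit when there are no
covariates). The score test needs no full-model fit, so separation
cannot break the p-value; reported β/SE come from the ordinary MLE, with
Firth penalized likelihood (Jeffreys-prior adjusted Newton iterations,
implemented here) when the MLE separates. Below 10 carriers the χ²
asymptotics are unreliable and the p-value falls back to permutation.

*Permutation.* Statistic: case-mean minus control-mean burden;
p = (1 + #{perm ≥ obs}) / (n_perm + 1), minimum attainable p
1/(n_perm+1). Because the statistic depends only on how many samples at
each distinct burden value land in the case group, the shuffle
distribution is drawn exactly and cheaply as multivariate hypergeometric
counts — identical in law to permuting labels, verified against full
enumeration at n = 8. Ties are compared with a 10⁻¹² guard so that
identical floating-point statistics count as ≥.

The panel scan runs Fisher always, the other engines on request, sorts
by Fisher p, and derives one child seed per gene from the scan seed so
results are reproducible and order-independent. Benjamini–Hochberg q is
an optional flag; the default report is nominal p, matching the
candidate-panel (hypothesis-driven) framing of the analysis.

## Coordination statistics

F_t/F_min normalization divides each channel by its own minimum, so the
normalized minimum is exactly 1, the operation is idempotent, and any
per-channel gain cancels. The event detector — upward crossing of a
fold-change threshold (default 1.5) with a refractory period (default
0.5 s) — is this package's operationalization; the original
quantification was interactive ROI analysis, so defaults are documented
and exposed rather than claimed as canonical. The left/right asymmetry
index is log(f_left/f_right), natural log by default and configurable;
sign and zero, the properties of scientific interest, are base-invariant.
A silent channel makes the index undefined and is flagged, not computed.

Turning statistics use centroid headings from consecutive displacement
vectors; body-axis orientation is not modeled. The signed turn is the
heading change wrapped to (−180°, 180°], leftward (counter-clockwise)
positive; the relative angle is the sum of signed turns; angular
velocity averages |turn|/Δt. Zero-length steps carry no heading and are
skipped with a log note. All statistics are invariant under rotation and
translation; reflection negates signed quantities only.

## Synthetic data: what it emulates and what it does not

Defaults mirror the motivating study design: 41 significant SNPs, a
156-gene panel, 411 cases vs 3800 controls. The control carrier rate of
the causal gene is not published; the default 0.002 is chosen to be
consistent with a handful of case carriers among 411 at an odds ratio
near 4, and the planted OR is configurable (default 4.0). Heavier
simulation checks use 2000+2000 cohorts with a 2% control carrier rate
so counts are large enough for tight Monte-Carlo bounds.

The generator plants: LD blocks with within-block r² ~ Uniform(0.5,
0.95) (so both prune-away and retain pairs exist) and zero r² across
blocks; one genome-wide-significant lead SNP per block; eQTL and
chromatin records linking the causal block to the causal gene below the
FDR thresholds plus decoys above them; and per-gene Bernoulli carrier
status with odds(p₁)/odds(p₀) equal to the target OR at the causal gene
in cases. Each carrier receives one private heterozygous variant whose
scores are drawn from the qualifying side of its tier threshold, so
carrier status survives filtering and weighting and the planted OR is
exact at the burden level. Decoy variants per gene (AF above the gate,
AC above the gate, weight-zero) exercise the filters without touching
the planted effect. Calcium traces are baseline plus half-sine bursts
(width 0.5 s — the real waveform is unspecified, so the detector is
parameterized) with Poisson event counts, an enforced minimum event gap
of 1.2 s so noiseless detection is exact, an antiphase offset between
channels, and Gaussian noise. Trajectories are correlated random walks
with a configurable per-step turn bias.

Deliberately not modeled: sequencing reads, imputation, population
structure and relatedness, per-variant allele-frequency spectra (the
carrier model collapses to per-gene Bernoulli — the effective unit of
the max-weight burden), real GTEx/Hi-C file formats, and mixed-model
association machinery. Consequently, passing tests show that the
pipeline's decision rules and statistics behave as specified under their
own assumptions; they do not show robustness to confounding, relatedness
or annotation error in real cohorts, and the published cohort-level
numbers (a single significant gene at p = 0.045, OR = 4.09) are not
reproduced here because the underlying data are access-restricted.

One root seed drives everything; each generator component draws from its
own fixed child stream, so adding a component never perturbs the others.

## Problem sizes in the test suite

Simulation tests use 1000 null genes for engine calibration (3-binomial-SE
band at α = 0.05, plus a Kolmogorov–Smirnov uniformity check on the
score-test p over 500 null genes), 200 replicates for planted log-OR
recovery (2 Monte-Carlo SE around log 4), 100 replicate 156-gene scans
for causal-gene ranking (≥ 90% rank-first), 60 randomized instances of
up to 12 SNPs for the clumping-vs-enumeration oracle, and 20 000
resamples against exhaustive enumeration for the permutation engine; the
whole suite runs in a few minutes on one core.
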