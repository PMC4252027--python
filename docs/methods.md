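# Methods

## The two-pool ribosome-loading model

A gene's mRNA population is modelled as two pools.  A copy is
*sequestered* with probability `s` — withdrawn from the translatable
pool, zero ribosomes — and otherwise active, carrying
`X = min(Poisson(λ), C)` ribosomes, with capacity
`C = floor(cds_len_codons / footprint_codons)` (footprint default 10
codons, so a 300-codon CDS holds at most 30 ribosomes).  λ is a lumped
loading intensity: the net outcome of initiation frequency and
elongation/termination speed, in units of ribosomes per active copy.

Closed forms used throughout (capacity truncation leaves lower-tail
probabilities unchanged for thresholds ≤ C):

* engaged fraction: `P(X ≥ k) = (1 − s)·P(Poisson(λ) ≥ k)`; the
  polysomal pool uses k = 2 because the default fraction scheme places
  monosomes in the non-polysomal pool;
* mean loading per copy: `(1 − s)·Σ_{j<C} P(Poisson(λ) > j)`;
* density on engaged copies: mean loading / engaged fraction, in which
  `(1 − s)` cancels — sequestration moves occupancy without moving
  density.  That separation is the point of the model: a single-Poisson
  model makes both observables increasing functions of λ and cannot
  produce occupancy↑ with density↓.

Truncation at C is by clamping rather than resampling: simpler, monotone
in λ, and the truncation mass is negligible for the default parameter
ranges (< 1e−6 at λ = 1.2, C = 10).

### Scenarios

Treatment effects are parameter shifts `(Δlog2 abundance, Δλ, Δs)`:

| scenario | Δlog2A | Δλ | Δs | signature |
|---|---|---|---|---|
| null | 0 | 0 | 0 | nothing |
| transcriptional | +1.5 | 0 | 0 | SL and PL move together |
| concordant | +2.0 | 0 | 0 | as above, stronger |
| initiation_up | 0 | +1.5 | 0 | occupancy↑ and density↑ |
| sequestration_release | 0 | −1.0 | −0.4 | occupancy↑, density↓ |
| elongation_stall | 0 | +1.0 | 0 | loading-level proxy: ribosomes accumulate |
| runoff | 0 | −1.5 | 0 | occupancy↓ and density↓ |

The release class has a pinned control regime (λ = 3, s = 0.6 → treated
λ = 2, s = 0.2): its engaged fraction `(1−s)(1−e^{−λ})` rises 0.380 →
0.692 while per-engaged-copy loading `λ/(1−e^{−λ})` falls 3.157 → 2.313.
Other classes draw control λ ~ U[1.5, 4] with s = 0.25, which puts the
population average near 70% of copies ribosome-associated — a typical
figure for unstressed tissue.  No kinetic rates are measured quantities;
all magnitudes are generator defaults chosen once and documented here.

The pipeline's "paper-like" configuration additionally overrides the
release class to a strong-responder regime (control s = 0.8, i.e. deeply
sequestered, released to 0.2): a ≈3-fold occupancy change, the middle of
the 1.3–3.4-fold range such expression-level screens report as
significant.  The milder default class is kept for the
distribution-level analyses, where a 1.5-fold occupancy shift is already
plainly visible in the fraction profiles.

### What the generator emulates, and what it does not

Emulated: the treated-vs-control × (steady-state, polysomal) × replicate
design with multiplicative log-normal measurement noise (default sd 0.2
log2, 3 biological replicates); per-sample RNA-recovery factors captured
by a luciferase-style spike value; 12-fraction profiles with counting
noise from a finite copy number (default 1000 copies/gene); A254 traces
rendered as Gaussian peaks whose area is proportional to ribosome mass,
plus a free-subunit peak carrying 1.2× the polysome-bound mass
(calibrated so a typical control population shows ~40% polysomal area,
as real plant gradients do); synthetic UTR/CDS sequences in which the
release class is shorter-CDS and GC-richer in the 5′UTR, optionally with
a planted motif instance.

Not emulated: probe-level array artifacts and background correction,
gene-length- or GC-dependent measurement bias, heteroscedastic
(intensity-dependent) noise, correlated replicates, partial gradient
recovery, RNA degradation, and codon-resolved ribosome traffic (no
TASEP; elongation stall is represented only at the loading level).
Passing tests therefore demonstrate correctness of the statistics and
the mechanistic decoupling of occupancy and density — not robustness to
array-specific artifacts.

Seeding: one global seed expands to counter-based substreams
(`SeedSequence([seed, stream, index])`, streams 0 = expression, 1 =
loading, 2 = sample factors, 3 = sequences), so a gene's draws do not
depend on how many genes are simulated or in what order.

## Gradient quantification

Baseline subtraction interpolates the blank onto the trace grid and
clips negative residuals to zero (A254 is nonnegative; clipping keeps
area percentages in [0, 100]).  Areas use the trapezoid rule with
interpolated interval endpoints — exact for piecewise-linear traces and
exactly additive over adjacent intervals.  The polysomal-area percentage
divides by total area to correct uneven gradient loading; a zero total
area raises an explicit error rather than returning 0.

The default scheme cuts the trace domain into 12 equal fractions pooled
as NP = 1–4, SP = 5–8, LP = 9–12 (polysomes start at fraction 5); real
fractionators vary, so boundaries, pools and the ribosome-count →
fraction map are all configurable and echoed into run manifests.  The
count map places free mRNPs in fraction 1, monosomes in fraction 3, and
counts 2..≥9 monotonically into fractions 5–12.  Synthetic trace peaks
are centered on the mapped fraction's midpoint so that the rendered
trace, the count map and the polysomal-area statistic stay mutually
consistent.

Replicate summaries report the difference of arm means with the
propagated sample SD `sqrt(sd_t² + sd_c²)` and a pooled two-sample t
p-value.

## Differential analysis

Intensities are tested on the log2 scale.  The per-gene test is a
two-sample t with **pooled variance by default**: at 2–4 replicates the
pooled t is exact under the homoscedastic noise model, whereas Welch's
approximation is measurably conservative (empirical size ≈ 0.035 at
nominal 0.05 with n = 3) — Welch remains available via
`var_mode="welch"` for data with suspect variance equality.  Degenerate
rows are handled explicitly: zero variance with equal means gives p = 1,
with unequal means p = 0 (exact separation).

Occupancy is tested two ways. The default `ratio` mode forms
per-replicate log-ratios `o = log2(PL) − log2(SL)` on replicate-matched
samples and applies the two-sample t (df = 2(n−1)); the `interaction`
mode tests the 2×2 condition × level contrast with a variance pooled
over all four groups (df = 4(n−1)) and needs no replicate pairing.  Both
are exact under the noise model; the pipeline uses the interaction mode
because the doubled degrees of freedom roughly double BH-limited
detection power at n = 3, recovering some of what a moderated
(empirical-Bayes) statistic would provide — moderated statistics
themselves are deliberately out of scope, and this divergence from
LIMMA-style analysis is the package's main statistical simplification.
Either way the reported `log2FC_RO` is computed from the level-wise
group means so that `log2FC_RO = log2FC_PL − log2FC_SL` holds bit-exactly
on balanced designs.

BH adjustment is applied per contrast (not jointly).  Calls use
significant(X) ⇔ padj_X ≤ 0.05 and |log2FC_X| ≥ 1 by default, with an
independent fold gate for RO since reported occupancy changes are often
below two-fold; precedence is RO_changed > concordant > SL_only/PL_only
> unchanged.

Spike normalization divides each sample by its spike signal and rescales
by the geometric mean of spikes.  The GC–MS internal-standard
normalization projects each sample's standards profile onto the first
principal component of the mean-centered standards submatrix
(sign-fixed, rescaled to geometric mean 1), then divides by sample
weight; pure size effects are removed exactly and degenerate standards
fall back to mean-of-standards with a warning.

## Fraction-resolved metrics

Profiles are normalized by spike and by the gradient's polysomal A254
area; the NP/PL split is scale-invariant and sums to 100 by
construction.  The density proxy is the abundance-weighted mean fraction
index over polysomal fractions — chosen over the modal fraction because
it is continuous and monotone in λ — with the peak fraction reported
alongside (ties break to the lowest index).  Scenario classification
uses tolerances of 1 percentage point (occupancy) and 0.25 index units
(density); deltas inside both tolerances are `no_change`, single-axis or
discordant-but-unnamed patterns fall into `other`.  With finite copy
numbers a fair share of null genes lands in `other` through sampling
noise on one axis; the class labels are meant for genes already flagged
by the expression-level analysis, not as a standalone detector.

## Sequence features and motifs

GC is computed over unambiguous bases only.  Nc uses Wright's estimator
with per-amino-acid homozygosity `F̂ = (nΣp̂² − 1)/(n − 1)` (n ≥ 2
codons), class means over the 2/3/4/6-fold degeneracy classes and
`Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, clamped to [20, 61].  An
unobserved class borrows the mean F̂ of observed classes; F̂ ≤ 0
(uninvertible) counts as unobserved; a CDS with no usable family returns
NaN rather than a fake 61.

uORFs: every 5′UTR ATG with an in-frame stop entirely within the UTR (or
extending into the CDS when `allow_overlap=True`) counts, with peptide
length ≥ `min_codons` (the start codon counts, so the default 1 accepts
ATG-stop).  Nested same-frame candidates sharing a stop are reported
once at the outermost start.  Start context is the 13-nt −5..+8 window
(+1 = A of the main ATG, no position 0), N-padded on shortfall.

Continuous features use the two-sided Wilcoxon rank-sum test (exact null
distribution when both sides ≤ 25 without ties, tie- and
continuity-corrected normal approximation otherwise); uORF presence uses
a one-tailed Fisher test.  The background is the annotated universe
minus the target list.

Motif consensus strings are parsed into per-position allowed-base sets;
scanning is exact, sense-strand, counts overlapping occurrences, and N
never matches.  Enrichment is the upper hypergeometric tail on genes
with ≥ 1 hit, with the background excluding target genes by default
(configurable), and per-region denominators restricted to genes that
have that region annotated — printed fold enrichments therefore follow
from the package's own documented denominators.  Occurrence totals are
reported alongside the gene-level counts.  PWM scoring with match
p-values is intentionally not reimplemented; exact degenerate-consensus
matching replaces it.

## Pipeline and reproducibility

`polyoccu.pipeline.run` executes simulate → gradient → differential →
density → features → motifs from a single config; every threshold that
affects a number is echoed into `manifest.json` together with SHA-256
checksums of all outputs, and identical configs reproduce every file
byte for byte (no timestamps are written).  Default problem sizes (400
genes, 1000 copies per gene, 3 replicates) keep a full run under a few
seconds while leaving each stage's statistics well resolved; all sizes
scale up via the config.

## Known limitations

* Occupancy and density truths are defined through the ≥2-ribosome
  pooling rule; schemes that pool monosomes into the polysomal fractions
  change the occupancy scale.
* The plain t (either mode) is less powerful than moderated statistics
  at 3 replicates; effect sizes below ~2.5-fold occupancy change are
  unlikely to be called at the default gates.
* Nc on short CDSs (< ~100 codons) is noisy and frequently clamps at 61.
* The Wilcoxon normal approximation is used above n = 25 even with few
  distinct values; heavy ties at small-moderate n are the worst case.
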