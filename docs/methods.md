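# Methods

## The classification problem

A +114.0429 Da diglycine on a tryptic peptide is ambiguous. The classifier
resolves it against the sequence database with a fixed dominance order:

1. no GG modification → `NO_GG`;
2. GG on a lysine side chain → `K_EPS_GG` (the canonical remnant);
3. GG on the peptide N-terminus where **any** protein containing the
   peptide encodes "GG" immediately before the match with K/R before that
   (or the GG sits at protein positions 1–2) → `INTERNAL_ENCODED_GGX`.
   The encoded explanation dominates because such a peptide is expected in
   any trypsinized lysate regardless of ubiquitination;
4. every matching protein is an 'X'-start unreviewed fragment →
   `REJECT_X_START` (the residue has no defined identity or mass, and such
   fragments' "N-termini" are database artifacts);
5. the peptide start coincides with a valid N-terminal form →
   `NTERM_UB_INITIATOR_MET` (start 1) or `NTERM_UB_NEO_NTERM` (start 2);
6. otherwise `AMBIGUOUS`.

Valid N-terminal forms are the initiator Met and the Met-clipped start 2,
the latter only when residue 2 is Ala, Cys, Gly, Pro, Ser, Thr, or Val —
the set of residues before which Met aminopeptidase typically cleaves.
Pro is kept in the set even though N-terminal acetyltransferases cannot
act on Met-Pro; callers can inspect the emitted form. A permissive mode
(`any_start_neo`) accepts any internal start as a neo-N-terminus for
signal-peptide/proteolysis exploration; it is off by default because the
reported N-terminal ubiquitination sites sit on initiator methionines.

Multi-mapping peptides follow the same dominance order (internal beats
N-terminal beats ambiguous; initiator beats clipped). Mapping is exact
substring search over target records only; decoys are never classified.

## Digestion model

LysC + trypsin are modeled as one K/R-specific protease (they coincide on
Lys). Cleavage before Pro is suppressed by default and only permissible
sites count toward missed cleavages (default maximum 2). Protein termini
count as tryptic, as does the Met-clipped start 2 under the
7-residue rule above — so an N-terminal-Ub peptide with a ragged
C-terminus is semi-tryptic while its canonical form is fully tryptic,
letting both forms of one site be enumerated. Coordinates are 1-based
inclusive throughout. Decoys are full-sequence reversals with a reserved
`REV_` accession prefix.

## Mass arithmetic

Monoisotopic residue masses are stored at 6 decimals; water is
18.0105646 Da and the proton 1.0072765 Da. A peptide's neutral mass is
the residue sum plus one water plus modification deltas; the registry
carries GG (+114.04293), carbamidomethyl (+57.02146), oxidation
(+15.99491), and TMT (+229.16293) — the conventional 4-decimal printed
values are treated as reporting precision. b/y ions carry N-terminal
modifications on the b series from b₁; figure-reported precursor m/z
values are treated as observed quantities and compared within 5 ppm.

## Identification filtering

The precursor window retains signed ppm errors in [−5, +4], bounds
inclusive. The discriminant is a two-class LDA with pooled within-class
covariance over four features (search score, |ppm error|, peptide length,
missed cleavages); a numerically degenerate covariance falls back to the
raw search score with a warning. FDR at threshold t is estimated as
(#decoys ≥ t)/(#targets ≥ t); candidate thresholds are the observed
target scores and the smallest threshold whose estimate meets the target
is chosen, ties at the threshold retained. Peptide-level filtering
collapses to the best-scoring PSM per (sequence + modification multiset);
charge is ignored in the key. Protein FDR is the decoy/target ratio after
collapsing to the best peptide per protein. The simple count-ratio
estimator (no q-value interpolation, no posterior error probabilities)
matches the target-decoy description with the fewest assumptions.

## Quantification

TMT PSMs pass five enumerated filters in order (decoy; length < 7;
isolation specificity < 50%; minimum reporter intensity < 256; summed
reporter < 30,000), label-free PSMs four (decoy; length < 7; confidence
< 71; peak area < 256); all inequalities strict as printed. The
reporter-intensity rule is applied to the per-channel minimum; an
"any channel" reading is the same predicate and the rule is configurable.
Redundant PSMs collapse to channel-wise maxima per fraction, then the
fraction with the largest summed signal (TMT), or to per-run area maxima
(LFQ). Cross-run completion transfers the maximum-area feature within
±10 ppm of the theoretical m/z and ±2 min of the shifted median anchor
retention time, after a per-run median-offset alignment (the simplest
monotone correction). Unmatched cells stay missing; nothing is imputed.

Peptidoform × sample log2 intensities are summarized per site by Tukey
median polish; the per-sample abundance is overall + column effect. The
implementation mirrors the reference R `stats::medpolish` sweep order and
stopping rule (relative change of the sum of absolute residuals, default
tolerance 0.01, 10 sweeps), which makes it directly comparable to that
oracle; the additive reconstruction is exact at observed cells by
construction. All-missing columns yield missing abundances.

Differential abundance is a per-feature fixed-effects one-way layout —
the degenerate form of the mixed-effects model in a single-batch design.
log2FC is the condition-mean difference, the standard error uses the
residual variance pooled across all conditions, and two-sided p-values
come from the t distribution with the residual degrees of freedom; for a
balanced two-condition design this is exactly the pooled two-sample
t-test. Benjamini–Hochberg adjustment is applied per contrast across
features. An optional method-of-moments variance moderation (shrinking
per-feature variances toward the cross-feature mean with a prior weight
set by the excess dispersion over chi-square sampling noise) is off by
default; the substrate gate uses the unadjusted model p, with the
adjusted value always reported alongside. Features with fewer than two
observations in either compared condition are flagged inestimable and
excluded from the adjustment.

## Substrate calling and profiles

A feature passes a contrast iff log2FC > 1 and p < 0.05, both strict. A
site is *called* when it passes at least one required contrast — the
per-experiment notion under which experiments are counted and
intersected — and *high-confidence* when it passes all of them (for the
default TMT design: UBE2W−Control and Combo−RNF4). Substrate identity is
the (accession, site-kind) pair, so fully and semi-tryptic forms of one
site yield one call. Logo matrices use pseudocount 0.5 and information
content log2(20) − H under a uniform 20-letter background; the window's
first two positions are the remnant glycines.

## Synthetic data: what it emulates, and what it does not

The generator emits the study-shaped inputs: a uniform-composition
proteome (Met-initiated, configurable length range) with planted internal
[K/R]GG motifs and 'X'-start fragments; reversed decoys; N-terminal GG
peptidoforms (fully tryptic, missed-cleavage, and ragged variants, up to
four per site) for substrate and null sites; condition-invariant internal
GGX and K-ε-GG PSMs; and decoy PSMs. Accidental [K/R]GG motifs are
scrubbed at generation so the planted motifs are the only encoded
explanations — a property real proteomes do not have, which is precisely
why classification truth is exact here.

Abundances are log-normal: per sample, log2 intensity = baseline (18) +
per-peptidoform offset N(0,1) + planted effect in the UBE2W-containing
conditions + N(0, σ) observation noise, σ = 0.25 by default, under the
four-condition 3/3/2/3 replicate design (11 samples, matching an
11-channel isobaric layout; two fractions in TMT mode). Planted effects
are drawn uniformly from log2FC ∈ [1, 2]: a range spanning the calling
threshold up to clearly detectable, reflecting the spread such
experiments report. A point mass exactly at the strict log2FC > 1 gate
would be undetectable half the time by construction (an unbiased
estimate exceeds its own true value with probability ½), so a two-point
effect set is not a meaningful recovery benchmark. Search scores are
two-Gaussian (targets N(2.5, 1), decoys N(0, 1), unit variance,
configurable separation); precursor errors are N(0, 1.2) ppm; LFQ runs
get per-run RT offsets and ~8% identification dropout so cross-run
matching is exercised. All randomness flows from one seed through one
numpy PCG64 `default_rng` stream per operation, giving byte-identical
outputs across platforms.

What passing recovery tests shows: the pipeline's stages compose
correctly and its estimators are calibrated under the assumed additive
log-normal model. What it does not show: robustness to real-data
phenomena the generator omits — ratio compression from co-isolation,
reporter-ion isotope impurities, chromatographic peak-shape artifacts,
non-uniform residue composition and homologous multi-mapping, shared
peptides between isoforms, batch effects, and missingness that is
intensity-dependent rather than random.

## Numerical choices and degenerate inputs

Threshold ties at the FDR cutoff are retained (inclusive policy).
Zero-residual-variance features with a nonzero difference get p = 0, with
a zero difference p = 1. Empty FASTA files parse to empty lists; empty
peptide sets raise in the profilers; an unachievable FDR target returns
an empty retained set with a warning rather than an error. Default sizes
used by the validation suite — 500-protein proteome, 60 substrates, 120
null sites, ~1,800–8,000 PSMs, 10,000 null features for the type-I check,
5,000 PSMs for FDR calibration — are the scales at which the estimators'
sampling noise is comfortably below the asserted tolerances.

## Known limitations

The discriminant's feature set is a reasonable stand-in; the original
search engine's features are unpublished. Empirical-Bayes moderation is
simplified to a method-of-moments shrinkage and off by default. Ub cannot
be distinguished from NEDD8/ISG15 by the GG remnant alone. Site
localization scoring, isotope envelopes, and raw spectral processing are
out of scope: the pipeline consumes PSM tables.
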