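# Methods

This note records the models, assumptions and numerical choices behind
`srfepi`, and what the synthetic-data generators do and do not emulate.

## Study design being emulated

A 2×2 cohort — genotype (CTR control vs KO, conditional neuronal SRF
knockout) × treatment (saline vs kainic acid) — with 5–6 biological
replicates per cell for expression profiling, and two EEG cohorts of 6
animals monitored for 18 days after intrahippocampal kainic acid.  The
defaults of `SimConfig` are these conditions: 6 replicates per cell
(`n_per_cell` overrides support the unbalanced 5/6 case), ~5000 probes with
216 up- and 162 down-regulated interaction genes planted at |log₂ effect| =
2 and residual sd 0.1; KO/CTR seizure rates 3.13 and 0.81 per recording
day, mean durations 35.7 s and 30.0 s, first-seizure latency ≈ 55.5 h.

## Expression cascade

Per-probe statistics come from an ordinary least-squares fit of the 2×2
cell-means model, computed for all probes at once via QR projections of the
nested design matrices.  Main effects use Type II sums of squares (the
interaction test is identical under Type II/III in a 2×2); Tukey HSD
p-values use the pooled within-cell error with the Tukey–Kramer correction
for unequal n and k = 4 groups.  Because `scipy.stats.studentized_range` is
far too slow for ~10⁴ evaluations per run (milliseconds each), the
studentized-range tail probability is computed by fixed Gauss–Legendre
quadrature of the standard double integral (outer over the chi scale
density, inner over the normal-range probability); agreement with scipy is
at machine precision (~1e-14) and it evaluates ~10⁴ values per second.
Benjamini–Hochberg adjustment delegates to
`statsmodels.stats.multitest.multipletests`.

Degenerate probes (zero within-cell variance) are flagged; their test
p-values are reported as 0 when the effect sum of squares is positive and 1
when it is exactly zero, so a pure main effect with no residual noise still
yields interaction p = 1.

Fold changes are geometric (differences of mean log₂, exponentiated), and
the classification thresholds (1.5 / 0.66; 2.5 / 0.4; 0.51 / 1.96;
p < 0.0005; FDR < 1 %; Tukey p < 0.05) are strict inequalities.  The
KA-responsiveness contrast is CTR-KA vs CTR-saline and the
genotype-difference contrast is CTR-KA vs KO-KA; a gene is flagged when any
of its probes is flagged.

### Why the synthetic baseline is uniform in log₂

Quantile normalization forces every sample onto the common distribution of
column-sorted row means.  It is faithful only where the columns' value
distributions are nearly identical and the quantile density is not sparse.
Two natural generator choices fail this at the 5000-probe scale, where
planted interaction genes are ~7.6 % of probes:

* a *shared* baseline for all null probes puts the planted probes in
  separated clusters at the distribution edges; averaging the sorted
  columns then shrinks a planted log₂ effect of 2 to ~0.8, below the fold
  thresholds (hundreds of false negatives);
* *Gaussian* per-probe baselines preserve effects in the bulk, but in the
  sparse tails a rank shift of ~200 positions translates to ≥ 0.6 log₂ of
  systematic distortion, producing tail false positives.

The generator therefore draws per-probe baselines uniformly over the
array's usable dynamic range (log₂ intensity 4–12, parameterized as mean
8, sd 2.31 = half-width/√3), and draws planted-gene baselines away from the
range edges so induction and repression stay on-scale — the synthetic
analogue of not planting a 4-fold induction on an already-saturated probe.
With constant quantile spacing, normalization neither creates nor destroys
planted effects, matching the regime of the real arrays (45k probes, < 1 %
changed) where quantile normalization is benign.

What this generator does *not* emulate: probe-level noise heterogeneity,
intensity-dependent variance, batch structure, cross-hybridization, or
many-to-one probe/gene mappings (the default plants one probe per gene;
the classifier itself supports many-to-one maps).  Passing tests therefore
show correctness of the statistical cascade, not robustness to array
artifacts.

## EEG model

Recordings are amplitude envelopes (nonnegative series, default one sample
per second), not raw multichannel EEG; the detector's baseline is the
median of unmasked samples, which is robust while discharges occupy a
minority of the recording.  Detection takes maximal unmasked runs with
envelope strictly above `threshold_ratio` × baseline (default 2), merges
runs separated by unmasked sub-threshold gaps shorter than `merge_gap`
(default 1 s, to avoid fragmenting one discharge), and keeps runs strictly
longer than `min_duration` (default 5 s).  Events starting at or after 24 h
post-injection are spontaneous; frequency is spontaneous events divided by
recording days.  The detector is invariant to uniform envelope rescaling.

The generator's baseline noise is Nakagami-*m* (the standard family for
amplitude envelopes; *m* = 1 is Rayleigh), with the scale calibrated so the
noise *median* equals `baseline_amplitude` — matching the detector's
baseline estimator.  The default *m* = 4 keeps the probability of a
baseline sample exceeding twice the median at ~3·10⁻⁴; a literal Rayleigh
would put 1/16 of baseline samples above threshold, blurring event
boundaries and occasionally fabricating events.  Planted discharges are a
flat plateau at `seizure_amplitude_ratio` × baseline (default 3) with
multiplicative jitter that never dips below threshold, aligned to the
sample grid with durations drawn from a truncated normal (> 5 s, ≥ 6
samples), so every planted event satisfies the detection rule by
construction and is recovered with ≤ 1 sample boundary error.

`seizure_rate_per_day` is defined per *recording* day — the denominator of
the frequency metric — so events are Poisson-placed in the post-latency
window (after 24 h) with intensity scaled by T/(T − t₀); the recovered
frequency is then an unbiased estimate of the configured rate.  When a
first-event latency distribution is configured, the first event time is a
truncated normal (> 24 h) and later events follow the Poisson process after
it, with the total expected count preserved.  Events are kept ≥ 2 samples
apart so the merge rule cannot fuse them.  The generator does not emulate
spike morphology, spectral content, circadian clustering of seizures, or
motion artifacts (the artifact mask is honoured by the detector and can be
set by callers).

## CArG-box scanning

The motif model is positional: flank mismatches are deviations from C at
positions 1–2 or G at 9–10; core mismatches are non-A/T bases at positions
3–8; N counts as a mismatch.  Acceptance requires total ≤ 2 and flank ≤ 1
(configurable).  Coordinates are TSS-relative, 1-based inclusive, with TSS
= +1 and no position 0, negative upstream, in promoter orientation —
reproducing labels like −309/−300 for a 10-bp site.  A site spanning the
TSS has end − start + 1 = 11 under this convention; span-10 arithmetic
holds for all one-sided sites.  Overlapping accepted windows are all
reported, and conservation requires full containment in a block.  Because
complementation maps flanks to flanks and the A/T core to itself, the
acceptance class is closed under reverse complement and single-strand
scanning is complete.

The enrichment test is a transparent reimplementation (hypergeometric
upper tail + seeded permutation over same-size gene draws); it is not
expected to reproduce numbers from proprietary promoter databases whose
backgrounds and site models are not published.

Synthetic promoters are uniform-random ACGT with planted exact-consensus
decamers; background letters are rejection-resampled until the scanner
finds exactly the planted sites, giving a clean truth set (a uniform
background is a neutral null, not a genome model: no repeats, GC structure
or real conservation).  Conserved blocks are non-overlapping 500-bp
intervals covering the configured fraction of the window; each planted site
is wholly inside or wholly outside a block according to its truth flag.

## qPCR / ChIP

Replicate Cts are averaged on the Ct scale before ΔΔCT (common practice;
amplification efficiency is assumed to be 2, with no standard-curve
correction).  Percent of input is `100 · input_fraction · 2^(Ct_input −
Ct_IP)` with the input dilution an explicit per-experiment field (default
0.1) rather than a constant folded into the math.  The binding rule
compares SRF percent-of-input against condition-matched controls — the
*Arbp exon* amplicon precipitated with SRF, and IgG on the same amplicon —
requiring both ratios strictly above 2; zero denominators are flagged and
never called bound.  The Ct-table generator inverts these formulas, so the
configured fold changes and enrichments are recovered exactly at zero Ct
noise, and with Ct noise sd 0.2 binding-call accuracy stays above 95 %.

## Orchestration and reproducibility

Every generator draws from a child stream of the configured seed (one
stream per assay, one per animal), so stages are independently reproducible
and byte-identical under a fixed seed.  The pipeline writes a manifest with
a configuration hash, the seed and the package version; a stage's outputs
are reused on rerun only when the recorded hash matches.  The report joins
classified SRF-dependent genes to their conserved-site counts and ChIP
binding calls.

Problem sizes used by the reproduction script (`scripts/acceptance.py`):
50 replicates of each 6-animal × 18-day EEG cohort and 20 replicates of the
5000-probe expression design — sizes at which the Monte-Carlo error of
every recovered group mean is well below the differences of interest, while
a full run completes in a few minutes on one core.

## Known limitations

* The seizure-amplitude criterion applies to envelopes, not raw EEG; the
  median baseline estimator and the envelope abstraction are implementation
  choices.
* Racine scores are consumed as annotations; behavior is not scored
  computationally.
* The tier thresholds are reproduced as printed and applied jointly; where
  the interaction p-filter and the FDR filter are partially redundant, both
  are enforced.
* Gene-set annotation analyses (GO/pathway services) are out of scope; only
  the generic overrepresentation test is provided.
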