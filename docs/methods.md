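# Methods

`dripchip` implements the statistical core of a genome-wide DRIP-chip
(DNA:RNA immunoprecipitation on tiling microarrays) analysis for budding
yeast: where in the genome do DNA:RNA hybrids (R loops) accumulate, which
feature classes are enriched beyond chance, and how does hybrid propensity
relate to transcription, GC content and antisense transcripts.

## Signal model and processing

The input is probe-level intensities for an S9.6 immunoprecipitation (IP)
channel and a no-antibody mock control, per replicate. Relative occupancy
is defined as the pseudocount ratio

    score(p) = (IP_p + c) / (mock_p + c),    c = 1 intensity unit,

smoothed with a 300 bp sliding window centred on the probe midpoint
(closed at both ends; edge probes use whatever probes fall in range).
Replicates are then quantile-normalized — every track receives the
rank-wise mean of the sorted score vectors; tied values get the mean of
the reference quantiles over their rank span — and averaged per probe.
Smoothing precedes quantile normalization by default
(`PipelineConfig.smooth_before_quantile`); the opposite order is one flag
away. On this scale the enrichment threshold of 1.5 reads directly as
"1.5-fold over mock". A sequence-aware probe-response model (as used by
array-normalization packages operating on vendor CEL files) is outside
scope; this package starts from probe-level intensity tables.

## Enrichment calling

A probe is contained in a feature iff its midpoint lies in `[start, end)`.
A feature is enriched on one replicate iff it has at least one probe and
at least 50 % of its probes score strictly above 1.5 (`>`; a probe at
exactly 1.5 does not count — "above" is read as strict and the choice is
configurable). Only features enriched in both replicates form the reported
consensus. Features with no probes are never enriched and are logged as
coverage gaps rather than silently dropped.

## Monte Carlo feature-class test

For a class of features (rDNA units, telomeric repeats, Ty1–Ty5, tRNAs,
snoRNAs, antisense-associated genes), each of 500 simulations re-places
every member uniformly at random — chromosome sampled with probability
proportional to the number of valid start positions
(`chrom_length − feature_length + 1`), start uniform, length and strand
kept, overlaps permitted — and recomputes the proportion of members called
enriched. With null mean μ and sample SD σ (n−1 denominator) over
simulations, the cumulative probability of seeing a lower score by chance
is

    P = Φ((observed − μ) / σ).

Degenerate σ = 0 is mapped to P = 1 (observed > μ), 0 (observed < μ) or
0.5 (equal). Placements are genome-wide by default; a same-chromosome mode
is available. All randomness flows through one recorded integer seed.

## Profiles

CHROMATRA-style matrices bin each transcript's probes into 150 bp segments
aligned at the TSS (bin 0 at the interval end for minus-strand
transcripts; integer mirroring makes genome reflection an exact symmetry),
rows sorted by length or grouped into five transcriptional-frequency /
four GC-content classes (quantiles of the supplied annotation by default,
explicit breakpoints accepted; ties go to the lower class). Meta-profiles
split gene bodies into 40 equal-width bins with exact rational edges plus
1500 bp fixed flanks ("UTRs") in 20 × 75 bp bins each side; tRNA/snoRNA
profiles use 3 body bins and no flanks. Probes are assigned to exactly one
bin by midpoint; empty bins are NaN, never zero, so sparse tiling cannot
fabricate signal. Transcripts are the supplied intervals; no UTR inference
is attempted.

## Statistics

Fisher's exact test is computed over the hypergeometric support in exact
integer arithmetic; the two-sided p sums all tables (at fixed margins)
whose probability does not exceed the observed table's — the
probability-mass definition, which differs from tail-doubling and is
therefore stated explicitly. Zero margins give p = 1 with an undefined
odds ratio. The Wilcoxon rank-sum test defaults to the exact tie-free null
for n ≤ 50 and otherwise a normal approximation with tie-corrected
variance and continuity correction. The cytological screen pools
replicates per strain into one 2×2 table against wild type (two-sided
Fisher) and applies a Bonferroni cutoff α/n_tests with α = 0.01; n_tests
is always an explicit input. Expression filtering scales every sample to
median 500, requires detection p ≤ 0.05 and signal ≥ 100 in every sample,
and calls a transcript modulated only if its treatment/control
mean-ratio fold change strictly exceeds 2 in either direction; the p
cutoff is treated as a per-sample detection p (the plausible alternative,
a differential-expression p, would need replicate-level variance modelling
that two-replicate arrays cannot support).

## Synthetic data: what it emulates and what it does not

The generator builds a ~270 kb toy genome (three chromosomes) with 150
ORFs, a 2-unit tandem rDNA array, 300 bp telomeric repeats at every
chromosome end, Ty1–Ty5 elements (expression Ty1 > Ty2 ≫ Ty3 ≈ Ty4,
Ty5 = 0; Ty3 carries the highest GC), 20 tRNAs and 10 snoRNAs. ORF GC and
log transcriptional frequency are drawn from a Gaussian copula (ρ = 0.3);
hybrid-prone ORFs are sampled with logistic probability increasing in both
(intercept −1, slopes 0.8); antisense flags are enriched among hybrid-prone
ORFs (p = 0.6) with the background solved so the overall antisense fraction
stays near 0.37. Mock intensities are lognormal (median 100, log-SD 0.2);
IP = mock × (1 + lift) × lognormal noise (log-SD 0.1), with lifts of 1.2
(rDNA, Ty1), 0.9 (telomeres, Ty2), 1.0 (hybrid-prone ORFs), ≈0 elsewhere.
Probe spacing is 25 bp against the real array's ~5 bp — chosen, with the
genome size, for second-scale runtimes.

The expression arm plants 25 up- and 10 down-responders at 4-fold,
preferentially antisense-associated (p = 0.8) and low-transcription,
with baselines floored at 1000 units so a 4-fold drop still clears the
detection floor after scaling. Because the universe is only 150 genes,
planted responders measurably shift the treatment-sample median, which
median scaling converts into a small systematic inflation of every
measured fold change; on the real array (5657 transcripts, 212 + 88
responders) this coupling is negligible. Consequently an occasional
non-responder can cross the strict 2-fold boundary (observed in ~1 % of
seeds); planted responders themselves are always recovered. Spread counts
are per-replicate binomial draws (3 × 100 nuclei; wild-type rate 0.02).

The generator does not attempt sequence-level realism (no codon structure,
no real Ty or rDNA sequence, no probe cross-hybridization or GC-dependent
probe response), so passing tests demonstrate the correctness and
calibration of the statistical machinery on data with the assumed
structure — not robustness to array-specific artifacts.

## Numerical and calibration choices

Monte Carlo calibration is demonstrated on a null track with scores
N(1.5, 0.2) — per-probe exceedance probability ½, so per-feature
enrichment is non-degenerate — using 50 class members of 200 bp over
200 seeded runs; the resulting P values are consistent with uniformity
(Kolmogorov–Smirnov α = 0.01). On a sparse null every simulated proportion
is 0 and P collapses to the degenerate-σ convention, which is why the
calibration design needs a non-trivial exceedance rate. Observed
proportions are discrete (k/50), which bounds the achievable KS distance
away from zero; 50 members keep that granularity well inside the KS
critical value at n = 200.

Determinism: every stochastic stage takes a single integer seed
(generators derive independent substreams per stage); reruns are
byte-identical up to the resolved-config file, which records the output
path. Problem sizes throughout (genome ~270 kb, 10–11 k probes per
replicate, 500 simulations, 100–1000 seeded repetitions in tests) were
chosen so the full suite runs in well under a minute of compute per
criterion on one CPU.

## Known limitations

- The enrichment scale is a pseudocount IP/mock ratio, not the output of a
  sequence-aware normalization model; absolute thresholds transfer to real
  arrays only after comparable normalization.
- The antisense-overlap computation reproduces published overlap
  percentages only when fed the corresponding deposited gene lists; the
  shipped tests exercise it on synthetic stand-in lists.
- Fold-change estimation uses condition means over two replicates; no
  shrinkage or variance moderation is attempted.
- The Monte Carlo assumes feature placements are independent (no rejection
  of overlaps), the simplest null; clustered-feature nulls are out of
  scope.
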