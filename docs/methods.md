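# Methods

`decayscan` detects transcripts that are preferentially degraded from
the 5′ end by comparing RNA-seq coverage between a strain carrying a
5′→3′ exoribonuclease ("WT") and its deletion mutant. A transcript the
enzyme attacks loses 5′-proximal read mass in the WT and accumulates
overall in the mutant; the pipeline quantifies both signatures and
intersects them. Each growth phase (logarithmic, stationary) is analysed
independently.

## Coverage profiles and the difference curve

For each annotated transcript the per-base read depth is computed from
single, unspliced alignment intervals (an archaeal genome; a read counts
toward a transcript when it overlaps it by at least one base, and toward
every base it covers). Profiles are oriented 5′→3′, so minus-strand
transcripts are reversed, and counting is strand-aware by default
(`stranded=False` supports unstranded libraries). Replicates are pooled
(depths summed) per condition before normalisation; averaging
per-replicate relative profiles instead is available as
`replicate_handling="average"`.

The per-base depth is divided by the transcript's total depth and
rescaled to a fixed length of 100 bins: base *p* of a length-*L*
transcript contributes its relative mass to bin ⌊100·p/L⌋. Summing mass
(rather than averaging depth) conserves the total exactly, so every
binned profile sums to 1 — it is a probability distribution of read
mass along the transcript. Consequences used as invariants throughout:

* the difference curve D(x) = WT(x) − mutant(x) sums to exactly 0;
* the OLS line through D against the bin midpoints x ∈ (0, 1)
  satisfies intercept = −slope/2.

The slope of that line is the coverage-shift statistic: positive when
the WT transcript is relatively 5′-depleted, i.e. when 5′→3′ decay is
faster in the presence of the enzyme. The abscissa is normalised
position, not bin index; slopes per bin are `slope/100`. r² is reported
as a diagnostic but plays no role in selection.

Eligibility: transcripts shorter than 100 nt are excluded from the
slope analysis (a 100-bin rescaling of a shorter transcript is
ill-defined; they remain eligible for differential abundance), as are
transcripts with zero coverage ("unquantifiable") or fewer than
`min_reads` pooled reads in either condition (default 50; low-coverage
profiles make the slope dominated by multinomial noise).

## Differential abundance

Counts (reads overlapping each transcript by ≥ 1 nt, per sample) enter
a negative-binomial two-condition comparison per phase:

* **Size factors** — median-of-ratios: each sample's factor is the
  median over genes (positive in all samples) of its count divided by
  the gene's geometric mean; the median is taken on the log scale.
* **Dispersion** — Var = μ + αμ². The raw per-gene estimate subtracts
  the expected shot noise from the df-pooled within-group variance of
  normalised counts, pooling over every replicate group of the
  experiment (condition × phase): with two replicates per group a
  single two-versus-two comparison leaves only 2 degrees of freedom,
  while the full design gives 4. Raw values are shrunk toward a
  least-squares trend α(μ) = a₀ + a₁/μ with an adaptive
  inverse-variance weight w = τ²/(τ² + s²), where s² ≈ (2/df)(shot/μ² +
  trend)² is the raw estimator's sampling variance and τ² the
  between-gene dispersion variance inferred from the excess spread of
  raw values around the trend. The weight matters: the test's rejection
  probability is convex in the dispersion, so plugging in noisy,
  symmetric estimates inflates the type-I error (a fixed 50/50 shrink
  left the empirical type-I rate at ~0.06–0.07 in null simulations;
  the adaptive weight brings it to ~0.05, and on data with genuinely
  heterogeneous dispersions it automatically retains the gene-specific
  signal). Estimates are floored at 10⁻⁸.
* **Test** — exact conditional-style NB test of equal per-unit means:
  the two condition sums are modelled as NB with a common per-unit mean
  estimated from their total; the p-value sums the probabilities of all
  splits of the observed total no more likely than the observed split.
* **log2 fold-change** — log₂ of the ratio of normalised condition
  means with a pseudocount of 0.5 (fold-change only, never the test),
  so zeros never produce infinities. Genes with zero counts everywhere
  in a phase are reported NA.
* **Multiple testing** — Benjamini–Hochberg step-up across tested
  genes. The conventional padj < 0.1 threshold feeds a descriptive
  summary only.

Exact numerical agreement with any particular legacy NB implementation
is not a goal; tests cross-check the elementary pieces (size factors,
BH) against independent implementations.

## Candidate selection

Per phase, over the background of all transcripts possessing both
statistics (a config switch restricts it to significant transcripts
instead): cutoffs are the arithmetic mean plus exactly one sample
standard deviation (n−1 denominator) of log2fc and of slope. A
candidate must satisfy log2fc ≥ fc-cutoff, slope ≥ slope-cutoff and
slope > 0; comparisons are inclusive, so ties at a cutoff are selected.
The background membership is recorded in the run log for
reproducibility. Selection ignores adjusted p-values entirely.

## The simulator

The generator emulates the comparative design: 2 conditions × 2 phases
× 2 biological replicates. Defaults define the standard recovery
setting: 500 transcripts of 300–2400 nt laid out on one chromosome with
random strands, log-normal abundance scatter (σ = 0.5) around 2000
expected fragments per transcript per replicate, NB dispersion
α = 0.05, 10% true targets with decay depth d = 0.6 and a mutant
abundance shift of log2fc = 2. Per-replicate counts are NB(μ, α); the
reads of each sample are drawn from an independent RNG stream derived
from the master seed by a fixed key, so adding a sample never perturbs
existing ones, and identical configs reproduce bit-identical files.

Decay is modelled as linear 5′ depletion of relative coverage:
survival ∝ 1 − d(1 − x) at normalised position x. Fragment placement
mimics random fragmentation of surviving molecules — every base of a
molecule, including its termini, is covered by some fragment — so
fragment start offsets range over [−(r−1), L−1] (r = read length,
default 36 nt) with probability proportional to the survival law at the
untrimmed fragment midpoint, and fragments are clipped to the
transcript on output. This makes the expected per-base coverage exactly
proportional to 1 − d(1 − x) at every position. The alternative of
restricting starts to the transcript and truncating only at the 3′ end
convolves the survival law with the read length and attenuates the
slope statistic by ≈ 0.8·s·r/L — several standard errors of the mean
over hundreds of targets at any realistic read length — which would
make the closed-form oracle below systematically wrong.

Under this model the noiseless 100-bin difference curve is linear with
slope

  E[slope] = d / (100 · (1 − d/2)),

e.g. 0.00667 at d = 0.5 — the analytic oracle (`expected_slope`) used
to validate the whole coverage→binning→regression chain. For linear
densities the exact per-bin integral equals the midpoint value, so the
oracle is exact, not a large-L approximation.

What the simulator does **not** model: sequencing error, GC or
positional priming bias, fragment-length variation (a single read
length stands in for the 200–300 nt fragmentation scale),
paired-end geometry, overlapping genes or operons, and non-linear decay
profiles (the linear law is a stand-in; the data it mimics constrain
only the sign of the coverage shift). Passing recovery tests therefore
demonstrates that the statistics behave as designed under their own
generative assumptions, not that real libraries are free of the biases
above.

## Numerical choices and degenerate inputs

* Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
  inclusive convention is converted only at the I/O boundary.
* An all-zero difference curve gets slope 0, intercept 0 and r² = 0.
* Size factors fall back to per-sample positive genes (with a warning)
  when no gene is positive in every sample.
* A selection background smaller than two transcripts is an error (the
  SD is undefined); a background with zero SD selects nothing unless
  slopes are strictly positive.
* p-value ties in the exact test are compared with a 10⁻⁷ log-scale
  tolerance so floating-point noise cannot split genuinely tied splits.
* The run log records a SHA-256 hash of the analysis-relevant config
  (the output directory is excluded) and contains nothing
  time-dependent, making end-to-end runs byte-reproducible.

## Problem sizes

The test suite and the acceptance studies run seeded simulations sized
to exercise each property sharply: algebraic identities on 1000
transcripts at modest depth (the identities are exact at any depth);
the slope oracle on 200 targets at 2000 fragments/replicate (d = 0.5);
null calibration on 2000 transcripts (type-I error at p < 0.05 and the
end-to-end false-candidate rate); and the standard recovery setting
(500 transcripts, defaults above), where the candidate set is scored
against the simulator's truth table for sensitivity and precision.

## Known limitations

Candidate lists from any particular sequencing experiment depend on
the original runs, the mapper and the exact legacy differential-
expression implementation used, and cannot be reproduced from
annotations alone; this package reproduces the *procedure* and
validates it on synthetic ground truth. Multi-mapping reads are counted once wherever they are
reported; spliced alignments are out of scope. With only two
replicates, the dispersion trend dominates individual genes — adequate
for the rule's fold-change filter, but per-gene dispersion estimates
should not be interpreted individually.
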