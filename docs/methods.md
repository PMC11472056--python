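# Methods

## Two-state duplex melting model

All thermodynamic analysis assumes a bimolecular two-state equilibrium
`A + B <-> AB` between two non-self-complementary strands present at equal
concentration, with total single-strand concentration `Ct` (the sum of both
strands, mol/L). The association constant follows the van't Hoff form
`K(T) = exp(-(dH - T dS)/(R T))` with temperature-independent `dH`
(kcal/mol) and `dS` (cal/(mol K)), both association-signed (negative for a
duplex that melts on heating). The gas constant is `R = 1.987204`
cal/(mol K); temperatures are kelvin internally and degrees C at every I/O
boundary.

Solving the mass-action equation `K (Ct/2 - x)^2 = x` for the duplex
concentration `x` gives the duplex fraction

    alpha = b / (b + 1 + sqrt(2 b + 1)),   b = K Ct,

a closed form chosen for numerical stability: it avoids the catastrophic
cancellation of the quadratic-formula root at small `b` and is evaluated in
log space for `ln b > 0` so that deep below the transition (`K` up to and
beyond 1e300) it saturates smoothly at `1 - sqrt(2/b)` instead of
overflowing. It agrees with a 200-iteration bisection solve of the
mass-action equation to 1e-9 across a broad random parameter sweep (tested).

Setting `alpha = 1/2` yields `K(Tm) = 4/Ct` and the linear concentration law

    1/Tm = (R ln(Ct/4) + dS) / dH,

which is both the forward predictor (`predict_tm`) and, inverted by ordinary
least squares of `1/Tm` on `log10(Ct/4)` over a concentration series, the
van't Hoff estimator (`vant_hoff_fit`): `dH = R ln(10) / slope`,
`dS = intercept * dH`. On exact inputs the fit is the algebraic inverse of
the predictor and recovers the generating parameters to better than six
significant figures (tested). `Ct/4` assumes non-self-complementary strands;
self-complementary duplexes are out of scope.

Gibbs free energy is reported as `dG(T) = dH - T dS / 1000` (kcal/mol). Note
the sign: with association-signed `dH = -118.8` and `dS = -350.9`,
`dG(310.15 K) = -10.0` kcal/mol — the entropic term *opposes* association.

### Tm extraction from measured curves

Two estimators are provided.

* `derivative` (default): the trace is smoothed with a cubic smoothing
  spline whose penalty is chosen by generalized cross-validation
  (`scipy.interpolate.make_smoothing_spline`), and the temperature of the
  maximum first derivative — the inflection point of the sigmoid — is
  returned, evaluated on a 2001-point refinement of the grid. A curve whose
  maximum slope falls within 1% of either grid edge, or whose absorbance is
  constant, raises a "no transition detected" error.
* `two_state_fit`: nonlinear least squares of the dual-baseline model
  `A(T) = alpha(T) ds(T) + (1 - alpha(T)) ss(T)` with linear baselines,
  parameterized by `(Tm, dH, baselines)` with `dS` eliminated through the
  concentration law. Baseline seeds come from the outer 20% of the grid and
  the Tm seed from the derivative method.

**Known bias of the inflection estimator.** For a bimolecular transition the
inflection of `alpha(T)` does not sit at `alpha = 1/2`: at the default
11-mer parameters it falls at `alpha ≈ 0.42`, about 0.8 °C above the
half-dissociation temperature. The derivative method therefore estimates the
*inflection point* faithfully (tested against a dense finite-difference
oracle to 0.1 °C) but is a biased estimator of the `alpha = 1/2` Tm; because
the bias is nearly constant across a concentration series it largely cancels
in the van't Hoff slope, yet the estimator's noise sensitivity over the
narrow 1/Tm range still degrades `dH`. Quantitative van't Hoff work —
including the demo pipeline — uses `two_state_fit`, which recovers the
half-dissociation Tm of noiseless synthetic curves to machine precision and
is unbiased under noise.

### Sugar pucker

`c3_endo_percent` applies the empirical two-state N/S equilibrium estimate
`C3'-endo(%) = 100 - 10 J(1'-2')` (J in Hz), clamped to [0, 100] with a flag
recording clamping. It is an affine monotone map, valid as a population
estimate only in the usual 0–10 Hz coupling range.

## Seed matching

The seed is guide positions 2–8 (5′ end, 1-based) — a 7-mer — with an
optional octamer mode (positions 1–8) motivated by reporter constructs that
pair the full 8-nt seed-containing region. The target-side motif is the
reverse complement of the seed, written 5′→3′, and a transcript is
seed-matched (SM) when its 3′UTR contains at least one exact occurrence;
multiplicity is reported but does not affect the verdict. Matching is exact:
overlapping occurrences are all reported, input is normalized (uppercase,
T→U), and ambiguity codes never match. UTRs are scanned on the given (mRNA)
strand only. Scanning is verified against a naive character-by-character
oracle on 1000 random high-density cases.

Reporter design: the CM insert is the full reverse complement of the guide;
the SM insert is `n` tandem copies of the complement of guide positions 1–8
separated by 4-nt random spacers, rejection-sampled (seeded) so that the
insert shares no 6-nt complementary run with the guide outside the seed
region and contains exactly `n` seed-complement matches.

## Off-target expression statistics

Microarray tables are filtered on six feature-quality flags (`ControlType=0`,
`gIsPosAndSignif=1`, `gIsFeatNonUnifOL=0`, `gIsWellAboveBG=1`,
`gIsSaturated=0`, `gIsFeatPopnOL=0`) and an `NM_` systematic-name prefix;
RNA-seq tables drop transcripts with reference-sample TPM strictly below 10
(the reference defaults to the mock column). Quantile normalization replaces
each column's sorted values with the across-column mean at the same rank,
with tied (fractional) ranks interpolated between adjacent reference
quantiles — this preserves within-column rank order and forces identical
sorted multisets across columns (tested against a naive reference
implementation, including ties).

Fold changes are `log2((treated + eps)/(mock + eps))` with MA x-coordinate
`mean(log10(value + eps))` over the two samples; the pseudocount `eps`
defaults to 1.0 (signal-intensity scale) and may be zero when all values are
positive. One mock and one treated column are compared per condition,
matching a single-array-per-condition design; replicate means can be
supplied as columns by the caller.

The SM vs non-SM comparison uses a two-sided Wilcoxon rank-sum test written
in this package: exact enumeration of the Mann-Whitney null distribution (a
dynamic program over the count recurrence
`f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u)`) when `min(n) <= 10` and the
pooled data are tie-free, otherwise a normal approximation with tie
correction and a 0.5 continuity correction. The exact two-sided p is
`min(1, 2 min(P(U <= u), P(U >= u)))`. When an on-target transcript id is
supplied it is excluded from both comparison groups (it is plotted
separately in MA output). If every pooled value is identical the test
returns p = 1 rather than failing: identical samples carry no evidence of a
difference. The implementation is cross-checked in tests against
`scipy.stats.mannwhitneyu` (exact and asymptotic) and the exact-vs-normal
agreement is enumerated exhaustively: the worst-case absolute p difference
is 0.011 at n = 8 per group and falls below 0.01 from n = 10 per group. No
multiple-testing correction is applied — one p-value is reported per siRNA.

Assay quantifications: relative luciferase activity is
`100 (renilla/firefly) / control_ratio`; qPCR fold change is
`2^(-ddCt)` with `ddCt = (Ct_target - Ct_ref)_sample − (Ct_target -
Ct_ref)_mock`, invariant to any constant Ct shift.

## Synthetic data generator

The generator exists to validate the analysis stages against known truth; it
emulates the study conditions, not instrument physics.

* **Melting curves**: the exact two-state signal with linear baselines
  (defaults ss = 0.0004·T + 1.00 above ds = 0.0002·T + 0.80, arbitrary
  absorbance units, enforcing hyperchromicity) plus i.i.d. Gaussian noise;
  concentration series 6, 12, 18, 24 µM total strand (3–12 µM per strand);
  grid 15–90 °C at 0.5 °C. Zero-noise curves equal the model exactly, so
  generator and analyzer are exact inverses.
* **UTR sets**: i.i.d. bases at a given GC fraction (default 0.5), lengths
  uniform in 200–1500 nt. Exactly `round(n · planted_fraction)` transcripts
  receive the motif overwritten at a uniform offset; all others are
  rejection-sampled until motif-free, so truth labels are exact by
  construction. `n_planted_motifs` records the actual occurrence count in
  the emitted sequence.
* **Expression tables**: mock values `2^N(mean, sd)` on a log2-normal scale
  (defaults mean 8, sd 2); treated values shift the exponent by −2 (on
  target), by the SM effect (default −0.5) for seed-matched transcripts, and
  by 0 otherwise, plus `N(0, 0.3)` log2 noise. Microarray tables carry the
  six QC flags (all passing; a `fail_fraction` knob flips one random flag on
  a random subset to exercise the filter) and `NM_`-prefixed names; RNA-seq
  tables emit the same values as TPM-like columns without flags.
* **Assay tables**: luciferase Renilla/firefly pairs and target/GAPDH Ct
  values realizing specified log2 effects exactly at zero noise.

All streams derive from one integer seed per spec through
`numpy.random.SeedSequence` spawning, so identical specs give byte-identical
outputs.

What the generator does **not** emulate: probe-level microarray structure
(background subtraction, spatial detrending), read-level RNA-seq sampling,
UTR base-composition structure (isochores, repeats), off-target effects of
partial or mismatched seed pairing, and correlated biological replicate
noise. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated model, not the biological effect
sizes recoverable from real arrays; the published SM transcript counts and
array p-values depend on the original GEO data plus a transcript-annotation
database and are not reproducible here.

## Problem sizes and numerical choices

The statistical property tests use a 5150-transcript set with exactly 150
seed-matched transcripts (power run: SM effect −0.5, noise 0.3; null run:
500 replicates at effect 0, empirical type-I checked against [0.025, 0.10]
at nominal 0.05); the CLI demo uses 3000 transcripts with 15% planted. Tm
grids are refined 2001-fold for derivative extraction; bisection oracles run
200 iterations; exact Wilcoxon enumeration is limited to `min(n) <= 10`
where the DP is O(n1 · n1 · n2) in memory-time product and exactness
matters most.

## Design choices

* Association-signed thermodynamics throughout (dH, dS < 0 for a stable
  duplex); dissociation-signed inputs raise rather than silently flip sign.
* Concentration convention: "total single-strand concentration" is the sum
  of both strands; per-strand series are doubled at the CLI boundary
  (`fit-thermo --ct-mode per-strand`).
* Seed width defaults to the 7-mer (positions 2–8); the 8-mer mode is an
  explicit flag. Octamer matches are a subset of heptamer matches since the
  octamer contains the heptamer.
* `delta_tm` rounds to one decimal place, matching how melting-temperature
  differences are conventionally tabulated.
* The CLI validates configs against the generator dataclasses and rejects
  unknown keys (exit code 2); data errors exit 1. All outputs are
  deterministic given `--seed`.
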