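# Methods

## Binding equilibria

Both assay geometries are one-site, single-receptor equilibria at constant
temperature; kinetics, cooperativity and multi-site binding are out of
scope. Concentrations are nM throughout the library; any µM inputs are
converted at the I/O boundary.

**Direct isotherm.** The bound probe fraction uses the depletion-aware
quadratic solution rather than the hyperbola R_t/(R_t+K_d), because the
probe concentration (3 nM) and the probe Kd (~19 nM) are of comparable
magnitude in the motivating assays, so free ligand cannot be approximated
by total ligand. The hyperbola is recovered exactly in the L_t → 0 limit.
The complex concentration is evaluated as 2·R_t·L_t/(s + √(s²−4R_tL_t))
(with s = R_t+L_t+K_d) instead of the textbook (s − √·)/2 form, which
suffers catastrophic cancellation when L_t ≪ K_d.

**Competitive equilibrium.** The ternary mass balance reduces to a cubic in
free receptor R with exactly one root in [0, R_t] for physical inputs. The
root is taken in the trigonometric (three-real-root) branch,
R = −a/3 + (2/3)·√(a²−3b)·cos(θ/3), and membership in [0, R_t] selects the
physical root; uniqueness of that membership is asserted rather than
tie-broken. Two numerical guards apply: the arccos argument is clamped to
[−1, 1] when within 1e−12 (an error beyond that signals coefficient
pathology), and a degenerate discriminant (a² − 3b ≤ 0) falls through to
bisection with a warning. The closed form is then polished with three
Newton steps on the monotone mass-balance function
g(R) = R·(1 + L_t/(K_d1+R) + I_t/(K_d2+R)) − R_t, whose derivative is ≥ 1,
removing the cancellation error of the cubic extraction; across 10,000
random systems spanning nine decades of concentration the result agrees
with the bisection oracle to ≤ 1e−9 relative on the bound probe fraction
(observed maximum ≈ 5e−10).

**Oracle.** `numeric_equilibrium` bisects g(R) on [0, R_t], where
g(0) ≤ 0 ≤ g(R_t) always brackets the unique root; it runs to bracket
exhaustion at machine precision, comfortably below the guaranteed
|g| < 1e−12·max(1, R_t). It shares no code path with the closed form and
is the independent reference in every equivalence test.

## Anisotropy model and fitting

Observed anisotropy is the intensity-weighted average of free and bound
probe signals, r = (Q·FB·r_b + (1−FB)·r_f)/(Q·FB + (1−FB)). The intensity
change on binding (Q) is fixed at 1 by default — plain linear mixing — but
exposed, since some probe/receptor pairs brighten on binding.

Fits minimize squared anisotropy residuals over (log10 K_d, r_f, r_b).
Working in log10 K_d enforces positivity and stabilizes the ~three decades
of dynamic range (tens of nM to tens of µM) the panel spans. The signal
endpoints are fitted per curve rather than shared across oligos — the
conservative choice when no evidence for a common instrument response is
available. Replicates enter as pooled points, never averaged first, so the
residual bootstrap sees the true error structure.

The optimizer is Levenberg–Marquardt (scipy `least_squares`) started from
three log-spaced Kd values spanning the titrant range, with endpoint
guesses read off the data plateaus; the lowest-rss solution wins and ties
(within 1e−10 relative) go to the smaller Kd. Tolerances are 1e−14 on
step, cost and gradient, which recovers noiseless synthetic parameters to
better than 1e−6 relative.

**Diagnostics.** A fit is *not converged* when the optimizer fails, the
input signal is constant, or the fitted endpoints invert (r_b ≤ r_f).
Competition fits additionally get a `lower_bound_only` flag when the fitted
curve at the highest competitor concentration stays above 90% of the upper
plateau: such data never exhibit the lower plateau, and the Kd estimate is
only a lower bound (the classic failure mode of an under-ranged competitor
series). The flag is computed from fitted predictions, not raw points, so
noise does not toggle it.

**Uncertainty.** Residual bootstrap: residuals of the fitted curve are
resampled with replacement onto the fitted values and each pseudo-dataset
is refitted from the original solution. Deterministic given a seed.
Asymptotic (Jacobian-based) errors were deliberately not used as the
primary measure because the log-Kd likelihood is noticeably asymmetric for
weak binders near the titrant ceiling.

## Synthetic assay designs

Defaults mirror the standard experimental layouts: direct — 3 nM probe,
receptor serially diluted from 300 nM down to 0.04 nM; competition — 3 nM
probe, 30 nM receptor, competitor diluted from 100 µM down to 0.5 nM;
triplicates. The dilution step factor is a free design parameter; the
default is two-fold, which covers the direct span in 13 points (last point
≈ 0.073 nM) and the competition span in 18 points (last ≈ 0.76 nM).
Noise is additive i.i.d. Gaussian on anisotropy with σ = 0.005, a typical
plate-reader repeatability scale chosen here as a package default, not a
measured value; it is configurable everywhere. What the simulator does not
emulate: intensity-dependent (heteroscedastic) noise, pipetting error
correlated along the dilution series, G-factor/instrument corrections, and
drift between replicates. Recovery results on these simulations therefore
demonstrate correctness of the estimator under the stated noise model, not
robustness to instrument systematics.

In panel-level recovery simulations, all oligos share the same seed set
(common random numbers). This is a paired design: the Monte Carlo error of
between-oligo comparisons cancels to first order, which is what makes
rank-order preservation a sharp test; with independent seeds, nearly tied
Kds (1170 vs 1180 nM in the reference panel) would flip by sampling noise
alone.

## Synthetic annotation corpora

Each transcript draws a signal count (default distribution: 55% one
signal, 25% two, 13% three, 7% four — a realistic skew toward single-PAS
transcripts, chosen once as a generator default) and then i.i.d. hexamers
from the configured distribution (default: the packaged panel's annotation
frequencies, renormalized). Hexamers are planted as DNA in uniform-random
ACGT background, ≥ 10 nt from transcript ends, reverse-complemented for
minus-strand transcripts; background composition is immaterial because the
census reads features by coordinates. The corpus is emitted as FASTA +
GFF3 and as a GenBank flat file (with a legacy `polyA_signal`-key dialect
option), plus a ground-truth table; every recovery test compares against
that table, never against hard-coded numbers. The generator does not model
realistic transcript architecture (exons/UTRs), cleavage sites, or
downstream elements.

## Census

Qualifying features: GFF3 types `regulatory_region`/`region` with
`regulatory_class=polyA_signal_sequence`, GFF3 type
`polyA_signal_sequence`, the legacy `polyA_signal` key, and GenBank
`regulatory` features with the same class qualifier — annotation dialects
have drifted, so all are accepted. Transcript association is by
Parent/locus-tag first, then coordinate containment within an mRNA on the
same strand; features with neither are kept on synthetic singleton
transcripts and reported, not dropped. Features whose length is not 6 nt,
or whose sequence leaves the RNA alphabet after T→U, are excluded and
counted in the skip report.

Counting is per feature–transcript association (isoform-shared signals
count once per transcript), matching a transcript-centric stratification;
genomic deduplication is available by flag and changes counts only, never
hexamer identities. Strata: `all`; `single` (transcripts with one
signal); `first`/`last` (the ends of multi-signal transcripts);
`intermediate` (interior signals, transcripts with ≥ 3). Coordinates stay
1-based inclusive end to end, matching both input formats.

## Hexamer analysis

Variant taxonomy is by Hamming distance: distance-1 variants of AAUAAA are
grouped by the varied position into the three recognition pairs (positions
1–2 → A1A2, 3 and 6 → U3A6, 4–5 → A4A5, following the protein surfaces
that read each pair); hexamers at distance ≥ 2 from AAUAAA but distance 1
from AUUAAA form the AUUAAA-derived group; everything else is `other`.
Assay oligos are the hexamer with fixed flanks UGC…CAA (SV40-late-derived,
not themselves receptor contacts).

Fold-change ratios are K_d(variant)/K_d(AAUAAA). Display values use
half-to-even rounding — to the nearest integer at or above 1, to one
decimal below 1. This is the unique simple rule consistent with the full
published ratio column of the reference panel (e.g. raw 14.5 → 14, 19.5 →
20, 62.5 → 62, 67.5 → 68, 287.5 → 288); raw ratios are always carried
alongside the display values.

The frequency–affinity relationship is summarized by OLS of
log10(frequency) on log10(Kd) (slope, intercept, Pearson r) with Spearman
ρ on the untransformed pairs as the robust headline statistic, since no
distributional claim is made. Records flagged as outliers are those with
|standardized log–log residual| > 2 — a descriptive cut, not an inference.
The FAM-labeled probe row of the reference panel is excluded from
correlation analyses: it duplicates the AAUAAA hexamer and its Kd reflects
the label's binding enhancement. Its roughly two-fold lower Kd than the
unlabeled AAUAAA oligo is a label effect, not a model inconsistency, and no
reconciliation is attempted.

## Problem sizes in the shipped tests

The test suite runs the oracle-equivalence sweep at 10,000 random systems,
parameter-recovery simulations at 50 seeds (single-oligo medians) and 16
oligos × 20 shared seeds (panel rank order), and census recovery on a
10,000-transcript corpus — sizes at which the multinomial and Monte Carlo
tolerances asserted in the tests are well separated from the expected
sampling noise.

## Known limitations

* One competitor species only; no global multi-curve fitting.
* The anisotropy model assumes a single fluorescent state per species; no
  G-factor or instrument-specific corrections.
* The census counts annotated signals only — no de novo PAS discovery —
  and the packaged panel's frequency column is annotation-version
  dependent fixture data, not a recomputation target.
* Corpus realism is deliberately minimal (see above); census correctness
  on real RefSeq files beyond the supported feature dialects is untested.
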