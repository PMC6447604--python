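# Methods

## Poisson quantification of droplet partitions

Droplet digital PCR converts quantification into counting. A reaction is
partitioned into droplets of volume *V* (0.85 nl, the droplet-generator
convention; exposed as `droplet_volume_nl` everywhere it enters a
calculation). Template molecules are assumed to load into droplets
independently at random, so per-droplet occupancy is Poisson with mean
λ = *cV*, where *c* is the concentration in the reaction. The estimator
inverts the observed negative fraction:

    λ̂ = −ln(N_neg / N_total),   ĉ = λ̂ / V

The simulator draws occupancy Poisson per droplet rather than allocating a
fixed molecule count multinomially; at 10³–10⁵ molecules over 2×10⁴ droplets
the two are indistinguishable, and the Poisson form matches the estimator's
own assumption.

**Confidence intervals.** A normal-approximation interval is placed on the
negative fraction and transformed through −ln: with p̂ = N_neg/N_total and
se = √(p̂(1−p̂)/N), the CI on concentration is [−ln(p̂+z·se), −ln(p̂−z·se)]/V.
At the ≥10,000 droplets the QC rule guarantees, negative counts are in the
thousands except near saturation, and the approximation is adequate; the
lower binomial bound is floored at 1/(10N) so the transform stays finite.
Wells with zero negative droplets are *saturated*: the inversion is
undefined, so they are returned flagged (point estimate infinite) rather
than raised, letting batch runs complete. Wells with zero positives return
concentration 0 exactly.

**Threshold calling.** A droplet is positive when its amplitude is strictly
greater than the threshold: thresholds are defined as the boundary of the
negative cloud, so a droplet exactly on the threshold is negative. Fixed
per-assay thresholds (3400 human, 6300 16S, 3000 mouse) are the default; an
NTC-derived alternative (1.2 × the 99.9th percentile of pooled NTC
amplitudes, floored at the pooled median) is available for new assays whose
fixed threshold has not been chosen yet.

## Sample-level chain

Replicate wells of one sample are averaged to ACN_sample (arithmetic mean;
the max−min range is retained for error bars, with SE of duplicates taken as
(range/2)/√n). The NTC technical replicates average to ACN_ntc. Then

    copies/μl extract = (ACN_sample − ACN_ntc) × dilution factor

relying on 1 μl of diluted extract per reaction, so copies per reaction
equals copies per μl of diluted extract. Replicates must share a dilution
factor: averaging before subtraction and dilution is only equivalent to the
reverse order under that constraint, which the sample sheet enforces. A
negative adjusted value is clipped to 0 and flagged — negative
concentrations are unphysical, but clipping events must stay auditable.

Per-mg normalisation defaults to the *literal* form, copies/μl extract ÷
stool mass (mg). A `total` mode multiplying by the elution volume first
(total copies recovered per mg) is provided because the literal form leaves
the elution volume implicit; the literal form is the default for fidelity to
the established reporting convention. The change-of-baseline summary for
preservation time courses reports value(t) − value(0) with the baseline
delta fixed at exactly 0 (SE 0) and SEs elsewhere propagated in quadrature.

## Conversions

Genomic DNA mass converts to haploid genome equivalents at 290 GE/ng
(≈3.45 pg per haploid genome). The constant is not arbitrary: it is the
unique value reproducing the three canonical mass→GE pairs
(800 ng → 232,000 GE, 80 → 23,200, 8 → 2,320) exactly, and is overridable in
`ConversionConstants`. Cell-equivalent estimates divide copies/mg by the
empirically calibrated copies per genome equivalent — the in silico
predicted 5,800 LINE-1 copies per genome times the 3.95 median yield
fraction measured on digested genomic DNA standards, i.e. 22,910 — and take
the floor, which reproduces both canonical bounds (176 and 2 cells/mg) where
rounding would not. These are estimates only: LINE-1 copy number per genome
is polymorphic across individuals. % CV uses the sample (n−1) standard
deviation, appropriate for triplicate day-to-day standard curves. A
signal-to-noise ratio with a zero-copy non-target genome is reported as a
censored lower bound (">x") rather than infinity.

## In silico PCR

A product is predicted wherever the forward primer matches one strand and
the reverse complement of the reverse primer matches downstream on the same
strand, with a non-negative gap and total length ≤ `max_product_bp`
(default 4,000, the web-tool convention). IUPAC degeneracy is matched
set-wise: two codes match when their base sets intersect, so a primer Y
against template C or T costs no mismatch, and template N matches anything.
Mismatch counting is per primer with default 0. Both strands are searched;
coordinates are 0-based half-open on the forward strand (a 1-based accessor
is provided for display), and overlapping products are all reported —
correct for repeat families, where overlapping or tandem hits are the point.
The matcher slides each primer over the template with a vectorised
compatibility table, equivalent to (and tested against) a naive quadratic
scan. Restriction-site counting is non-overlapping left-to-right, mirroring
enzymatic digestion, with expected mean fragment length len/(count+1).

Two synthetic gBlock standards ship with the assay catalog. The ND5 gBlock
is 196 nt as designed; the available transcription of the LINE-1 gBlock
totals 125 nt against its nominal 126, while its internal amplicon
arithmetic (20 + 19 + 21 = 60 bp) is exactly self-consistent — so amplicon
assertions on it are exact and full-length assertions advisory. The 16S
amplicon length is recorded as 173 bp with a note that 172 bp also appears
at source; the discrepancy is preserved, not resolved.

## Synthetic droplet data

The generator exists so every pipeline stage can be tested against known
truth. What it emulates: Poisson loading at ~20,000 generated droplets with
a fixed accepted fraction (0.9, so the ≥10,000 QC rule is exercisable); a
two-Gaussian amplitude model (negatives 1800±200, positives 6500±400,
arbitrary units) with 2% of positives re-drawn uniformly between the
cluster means ("rain") and a 5×10⁻⁵ per-droplet false-positive rate for
empty droplets; duplicate extractions with log-normal technical noise;
shared NTC wells (four technical replicates); dilution series spanning
~193–120,440 copies/reaction in five levels of three replicates; spike-in
arms at 232,000/23,200/2,320 GE with a configurable true recovery fraction;
and longitudinal designs with log-normal day-to-day biological variation
(SD 0.8 on the natural-log scale ≈ several-fold swings). The amplitude
parameters are inventions — the minimal model giving threshold-separable
clusters with rain near the fixed thresholds — and are not estimates of any
instrument; passing tests demonstrate correctness of the inference chain
under its own assumptions, not robustness to real-instrument artefacts
(drift, coalescence, multi-channel crosstalk), which the model omits.

Scale choices: the longitudinal baseline is 10,000 copies/mg in the literal
normalisation convention with 100-fold dilution and 20–80 mg stool aliquots,
placing wells at λ ≈ 0.04–1 across the simulated biological range — inside
the assay's informative regime. The spike-in generator applies one shared
`assay_dilution` (default 10⁵) to all three arms: a 232,000 GE spike carries
~1.3×10⁹ amplifiable copies, far beyond droplet saturation, and the real
workflow likewise dilutes serially before ddPCR; the dilution cancels in the
recovery ratio. Preservation time courses decay exponentially,
baseline × e^(−rate·t), with negative rates permitted to model rising
signal (bacterial growth in a permissive buffer); default rates 0/h (EDTA),
0.01/h (TEN2), 0.005/h (OMNI), with OMNI flagged single-extraction.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, sub-streams assigned in enumeration order, so identical inputs and
seed give byte-identical serialised output.

## Test design for stochastic assertions

Fixed seeds make every stochastic test deterministic, but the assertions are
still sized to the underlying sampling distribution rather than tuned to a
particular draw: estimator-recovery tests use 200 wells per concentration
(SE of the mean ≪ the 2% band asserted); CI-coverage assertions over *n*
samples use Bonferroni-adjusted per-sample intervals (level 1 − 0.01/n) so
the family-wise miss probability is ~1%; and recovery assertions at small
spike levels derive their tolerance from the observed replicate counting
noise (4 SE) instead of a fixed percentage. Problem sizes (e.g. 12-sample
end-to-end studies, 10⁶-droplet convergence checks) were chosen to keep the
whole suite under ~10 s on one CPU while leaving the statistical margins
above comfortable.

## Known limitations

Single-channel EvaGreen amplitudes only; no probe/multi-channel model, no
inhibitor or chemistry kinetics, no primer thermodynamics or design, no
proprietary instrument-file parsing. The CI method degrades near saturation
(few negative droplets); saturated wells are flagged rather than estimated.
In silico PCR with large mismatch counts is exhaustive, not heuristic —
fine for genomes at mismatch ≤ 2, not an aligner replacement.
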