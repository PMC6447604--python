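"""Sample-level assay statistics.

Everything downstream of the per-well Poisson estimate lives here: replicate
averaging, background (no-template control) subtraction and dilution
adjustment, per-milligram-of-stool normalisation, spike-in recovery,
specificity (signal-to-noise) ratios, standard-curve validation metrics
(linearity, % yield, % CV), genome-equivalent conversions, and
change-from-baseline summaries for preservation time courses.

The core bookkeeping chain for one stool sample is

    ACN_sample = mean ACN over duplicate extractions       (copies/reaction)
    copies per ul extract = (ACN_sample - ACN_ntc) * dilution factor
    copies per mg stool   = copies per ul extract / stool mass (mg)

which relies on 1 ul of diluted extract entering each 20 ul reaction, so
copies per reaction equals copies per ul of *diluted* extract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as _sps


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SampleRecord:
    """Per-extraction metadata for one stool DNA sample (or an NTC)."""

    sample_id: str
    subject_id: str = ""
    collection_day: int = 0
    stool_mass_mg: Optional[float] = None
    dilution_factor: float = 1.0
    extraction_replicate: int = 1
    is_ntc: bool = False
    buffer: str = "none"
    bristol: Optional[int] = None
    elution_volume_ul: float = 100.0

    def __post_init__(self) -> None:
        if not self.is_ntc and (self.stool_mass_mg is None or self.stool_mass_mg <= 0):
            raise ValueError(f"sample {self.sample_id!r}: stool mass must be positive")
        if self.dilution_factor < 1:
            raise ValueError(f"sample {self.sample_id!r}: dilution factor must be >= 1")
        if self.bristol is not None and not 1 <= self.bristol <= 7:
            raise ValueError(f"sample {self.sample_id!r}: Bristol score must be in 1..7")


@dataclass(frozen=True)
class ExtractQuant:
    """Background/dilution-adjusted quantification of one extract."""

    acn_sample: float
    acn_ntc: float
    copies_per_ul_extract: float
    copies_per_mg_stool: float
    clipped_flag: bool = False


@dataclass(frozen=True)
class RecoveryExperiment:
    """The three absolute-copy-number terms of the spike-in recovery equation."""

    acn_spike: float    # purified faecal lysate with gDNA spike
    acn_buffer: float   # purified faecal lysate with buffer only
    acn_alone: float    # unpurified gDNA spike alone


@dataclass(frozen=True)
class StandardCurveFit:
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float
    percent_yield_per_point: tuple[float, ...]
    median_percent_yield: float
    percent_cv_per_level: tuple[float, ...]


@dataclass(frozen=True)
class ConversionConstants:
    """Constants linking DNA mass, genome equivalents, and assay copies.

    ``ge_per_ng``: haploid genome equivalents per ng of genomic DNA (290,
    i.e. ~3.45 pg per haploid genome).  ``insilico_copies_per_genome``: in
    silico predicted amplifiable target copies per haploid genome (5,800 for
    the human 60-bp LINE-1 assay).  ``median_yield_fraction``: empirically
    measured copies per predicted copy on digested genomic DNA (3.95, i.e. a
    median yield of 395% — the prediction undercounts).
    """

    ge_per_ng: float = 290.0
    insilico_copies_per_genome: float = 5800.0
    median_yield_fraction: float = 3.95

    def __post_init__(self) -> None:
        if min(self.ge_per_ng, self.insilico_copies_per_genome, self.median_yield_fraction) <= 0:
            raise ValueError("conversion constants must all be positive")


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    range_: float
    n: int
    single_replicate_flag: bool

    @property
    def se(self) -> float:
        """Standard error of the mean from the duplicate range: (range/2)/sqrt(n)."""
        return (self.range_ / 2.0) / math.sqrt(self.n) if self.n > 1 else math.nan


# ---------------------------------------------------------------------------
# operations


def average_replicates(
    values: Sequence[float], expected_n: int = 2
) -> ReplicateSummary:
    """Average replicate per-reaction copy numbers; keep range for error bars.

    Flags the summary when fewer than ``expected_n`` replicates are present
    (e.g. a specimen with material for only one extraction).
    """
    if len(values) == 0:
        raise ValueError("no replicate values to average")
    arr = np.asarray(values, dtype=float)
    return ReplicateSummary(
        mean=float(arr.mean()),
        range_=float(arr.max() - arr.min()),
        n=len(values),
        single_replicate_flag=len(values) < expected_n,
    )


def adjust_acn(
    acn_sample: float, acn_ntc: float, dilution_factor: float
) -> tuple[float, bool]:
    """Background- and dilution-adjust: (ACN_sample - ACN_ntc) * dilution factor.

    The result is copies per ul of undiluted DNA extract.  A negative
    difference (NTC background exceeding the sample signal) is clipped to
    zero and flagged — unphysical, but the event stays auditable.
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if acn_sample < 0 or acn_ntc < 0:
        raise ValueError("ACN values must be non-negative")
    adjusted = (acn_sample - acn_ntc) * dilution_factor
    if adjusted < 0:
        return 0.0, True
    return adjusted, False


def normalize_per_mg(
    copies_per_ul_extract: float,
    stool_mass_mg: float,
    mode: Literal["literal", "total"] = "literal",
    elution_volume_ul: float = 100.0,
) -> float:
    """Normalise extract concentration to stool input mass.

    ``literal`` (default) divides copies per ul extract by the stool mass in
    mg.  ``total`` first multiplies by the elution volume, giving total copies
    recovered per mg — the physically complete accounting when elution volume
    varies between extractions.
    """
    if stool_mass_mg <= 0:
        raise ValueError("stool mass must be positive")
    if mode == "literal":
        return copies_per_ul_extract / stool_mass_mg
    if mode == "total":
        return copies_per_ul_extract * elution_volume_ul / stool_mass_mg
    raise ValueError(f"unknown normalisation mode {mode!r}")


def spike_recovery(exp: RecoveryExperiment) -> float:
    """Percent recovery R of a genomic DNA spike through DNA purification.

    R = 100 * (ACN(spiked lysate) - ACN(buffer-only lysate)) / ACN(spike alone).
    Measurement noise can push R above 100 or below 0; the value is reported
    as computed, never clipped.
    """
    if exp.acn_alone <= 0:
        raise ValueError("ACN of the unpurified spike alone must be positive")
    return 100.0 * (exp.acn_spike - exp.acn_buffer) / exp.acn_alone


@dataclass(frozen=True)
class SignalToNoise:
    ratio: float
    censored: bool = False

    def __str__(self) -> str:
        return (">" if self.censored else "") + f"{self.ratio:g}"


def signal_to_noise(
    acn_per_pg_signal: float, acn_per_pg_noise: float, epsilon: float = 1.0
) -> SignalToNoise:
    """Specificity ratio: target-genome ACN per pg input over non-target ACN per pg.

    When the non-target genome yields zero copies the ratio is a censored
    lower bound ``> signal/epsilon``, with epsilon one background-subtracted
    copy per assay input mass.
    """
    if acn_per_pg_signal < 0 or acn_per_pg_noise < 0:
        raise ValueError("S/N inputs must be non-negative")
    if acn_per_pg_noise == 0:
        return SignalToNoise(acn_per_pg_signal / epsilon, censored=True)
    return SignalToNoise(acn_per_pg_signal / acn_per_pg_noise)


def percent_yield(measured: float, expected: float) -> float:
    """100 * measured copies / expected copies; may exceed 100."""
    if expected <= 0:
        raise ValueError("expected copies must be positive")
    return 100.0 * measured / expected


def percent_cv(replicate_values: Sequence[float]) -> float:
    """Percent coefficient of variation: 100 * sample SD (n-1) / mean."""
    if len(replicate_values) < 2:
        raise ValueError("percent CV needs at least two values")
    arr = np.asarray(replicate_values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("percent CV needs a positive mean")
    return 100.0 * arr.std(ddof=1) / mean


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurveFit:
    """Fit measured vs theoretical copies by ordinary least squares (linear scale).

    ``points`` are (theoretical, measured) pairs; replicates share a
    theoretical value and define the levels over which per-level % CV is
    computed (levels with a single replicate are skipped).  Per-point % yield
    and its median summarise accuracy; slope/intercept/R^2 summarise
    linearity.
    """
    points = [(float(t), float(m)) for t, m in points]
    theoretical = np.array([t for t, _ in points])
    measured = np.array([m for _, m in points])
    if len(set(theoretical.tolist())) < 2:
        raise ValueError("need at least two distinct theoretical copy numbers")
    fit = _sps.linregress(theoretical, measured)
    yields = tuple(percent_yield(m, t) for t, m in points)
    levels = sorted(set(theoretical.tolist()))
    cvs = []
    for lev in levels:
        reps = measured[theoretical == lev]
        if len(reps) >= 2 and reps.mean() > 0:
            cvs.append(percent_cv(reps))
    return StandardCurveFit(
        points=tuple(points),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        percent_yield_per_point=yields,
        median_percent_yield=float(np.median(yields)),
        percent_cv_per_level=tuple(cvs),
    )


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def mass_to_ge(mass_ng: float, constants: ConversionConstants = ConversionConstants()) -> float:
    """Convert a genomic DNA mass in ng to haploid genome equivalents (3 s.f.)."""
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return _round_sig(mass_ng * constants.ge_per_ng, 3)


def empirical_copies_per_ge(
    constants: ConversionConstants = ConversionConstants(),
) -> float:
    """Empirically calibrated assay copies per genome equivalent.

    The in silico predicted copies per genome times the median yield fraction
    observed on digested genomic DNA standards (the in silico prediction is an
    undercount for degenerate repeat families).
    """
    return constants.insilico_copies_per_genome * constants.median_yield_fraction


def cells_per_mg(copies_per_mg: float, copies_per_ge: float) -> int:
    """Estimated whole-cell equivalents per mg stool: floor(copies per mg / copies per GE).

    An estimate only — repeat copy number per genome is polymorphic across
    individuals.
    """
    if copies_per_ge <= 0:
        raise ValueError("copies per genome equivalent must be positive")
    return math.floor(copies_per_mg / copies_per_ge)


def change_from_baseline(
    series: Sequence[tuple[float, float, float]]
) -> list[tuple[float, float, float]]:
    """Change from the time-0 value for a (time, value, se) series.

    delta(t) = value(t) - value(0); the baseline delta is exactly 0 with SE 0,
    and SEs elsewhere propagate in quadrature with the baseline SE.
    """
    series = [(float(t), float(v), float(s)) for t, v, s in series]
    baseline = [p for p in series if p[0] == 0]
    if not baseline:
        raise ValueError("series must contain a time-0 baseline")
    _, v0, s0 = baseline[0]
    out = []
    for t, v, s in series:
        if t == 0:
            out.append((t, 0.0, 0.0))
        else:
            out.append((t, v - v0, math.hypot(s, s0)))
    return out
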