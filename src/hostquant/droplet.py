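"""Droplet-level quantification: QC, threshold calling, Poisson estimation.

A droplet digital PCR reaction is partitioned into ~20,000 nanolitre droplets
and each droplet is scored positive or negative for amplification by its
end-point fluorescence amplitude.  Because template molecules load into
droplets at random, the number of molecules per droplet is Poisson, and the
mean occupancy lambda is recovered from the fraction of *negative* droplets:

    lambda = -ln(negatives / total)

Concentration in copies per microlitre of reaction is lambda divided by the
droplet volume (0.85 nl by instrument convention), and copies per reaction is
that concentration times the 20 ul reaction volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_DROPLET_VOLUME_NL = 0.85
DEFAULT_REACTION_VOLUME_UL = 20.0
MIN_ACCEPTED_DROPLETS = 10_000


@dataclass
class DropletWell:
    """One well's accepted-droplet fluorescence amplitudes plus identity."""

    well_id: str
    sample_id: str
    assay_id: str
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1:
            raise ValueError("amplitudes must be a 1-D vector")
        if self.amplitudes.size and (
            not np.all(np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0)
        ):
            raise ValueError("amplitudes must be finite and non-negative")

    @property
    def accepted_count(self) -> int:
        return int(self.amplitudes.size)


@dataclass(frozen=True)
class DropletCounts:
    positives: int
    negatives: int
    total: int
    threshold_used: float

    def __post_init__(self) -> None:
        if self.positives < 0 or self.negatives < 0:
            raise ValueError("counts must be non-negative")
        if self.positives + self.negatives != self.total:
            raise ValueError("positives + negatives must equal total")


@dataclass(frozen=True)
class Concentration:
    """Poisson-derived absolute copy number with a 95% confidence interval.

    ``copies_per_reaction`` is the absolute copy number (ACN) per reaction.
    When every droplet is positive the Poisson inversion is undefined and
    ``saturated_flag`` is set; point estimate and CI are then NaN/inf.
    """

    lambda_: float
    copies_per_ul_reaction: float
    copies_per_reaction: float
    ci_low: float
    ci_high: float
    saturated_flag: bool = False


@dataclass(frozen=True)
class WellRejection:
    well: DropletWell
    reason: str


def qc_filter(
    wells: list[DropletWell], min_accepted: int = MIN_ACCEPTED_DROPLETS
) -> tuple[list[DropletWell], list[WellRejection]]:
    """Partition wells into those meeting the accepted-droplet minimum and not.

    A well passes when it holds at least ``min_accepted`` droplets (the
    minimum is inclusive).  Rejections record the observed count.
    """
    if min_accepted <= 0:
        raise ValueError("min_accepted must be positive")
    accepted, rejected = [], []
    for w in wells:
        if w.accepted_count >= min_accepted:
            accepted.append(w)
        else:
            rejected.append(
                WellRejection(w, f"{w.accepted_count} accepted droplets < minimum {min_accepted}")
            )
    return accepted, rejected


def call_droplets(well: DropletWell, threshold: float) -> DropletCounts:
    """Score droplets positive/negative against an amplitude threshold.

    A droplet is positive when its amplitude is strictly greater than the
    threshold: the threshold defines what is negative, so a droplet sitting
    exactly on it is negative.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if well.accepted_count == 0:
        raise ValueError(f"well {well.well_id!r} has no droplets to call")
    positives = int(np.count_nonzero(well.amplitudes > threshold))
    total = well.accepted_count
    return DropletCounts(positives, total - positives, total, float(threshold))


def threshold_from_ntc(ntc_wells: list[DropletWell], multiplier: float = 1.2) -> float:
    """Derive a calling threshold from no-template-control droplet amplitudes.

    Pools all NTC droplets and returns ``multiplier`` times their 99.9th
    percentile, floored at the pooled median.  This places the threshold just
    above the negative-droplet cloud the NTCs define.  An alternative to the
    fixed per-assay thresholds, which are the default.
    """
    pooled = [w.amplitudes for w in ntc_wells if w.accepted_count > 0]
    if not pooled:
        raise ValueError(
            "no NTC droplets available; use the fixed assay thresholds instead"
        )
    amplitudes = np.concatenate(pooled)
    return float(max(multiplier * np.percentile(amplitudes, 99.9), np.median(amplitudes)))


def poisson_concentration(
    counts: DropletCounts,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL,
    ci_level: float = 0.95,
) -> Concentration:
    """Invert droplet counts to a concentration via Poisson partition statistics.

    lambda = -ln(neg/total); concentration = lambda / droplet volume (ul).
    The CI is a normal-approximation interval on the negative fraction,
    transformed through -ln — adequate at the >=10,000 droplets the QC rule
    guarantees.  Saturated wells (no negatives) are flagged, not raised, so
    batch runs complete.
    """
    if counts.total <= 0:
        raise ValueError("total droplet count must be positive")
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    v_ul = droplet_volume_nl / 1000.0

    if counts.negatives == 0:
        return Concentration(math.inf, math.inf, math.inf, math.nan, math.nan, True)

    p_neg = counts.negatives / counts.total
    lam = -math.log(p_neg)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(p_neg * (1.0 - p_neg) / counts.total)
    p_lo = max(p_neg - z * se, 1.0 / (counts.total * 10.0))  # keep -ln finite
    p_hi = min(p_neg + z * se, 1.0)
    lam_hi = -math.log(p_lo)
    lam_lo = -math.log(p_hi)
    conc = lam / v_ul
    return Concentration(
        lambda_=lam,
        copies_per_ul_reaction=conc,
        copies_per_reaction=conc * reaction_volume_ul,
        ci_low=lam_lo / v_ul,
        ci_high=lam_hi / v_ul,
        saturated_flag=False,
    )
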