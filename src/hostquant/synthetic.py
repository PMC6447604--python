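"""Forward simulation of droplet digital PCR experiments.

The generator produces droplet-amplitude wells with the statistical structure
the quantification pipeline assumes, so every downstream stage can be tested
against known ground truth without instrument data:

* molecules load into ~20,000 droplets independently, so per-droplet occupancy
  is Poisson with mean lambda = concentration x droplet volume;
* occupied droplets fluoresce in a high-amplitude cluster, empty droplets in a
  low-amplitude cluster (two Gaussians), with a small "rain" fraction of
  positives smeared uniformly between the cluster means and a rare per-droplet
  false-positive probability for empty droplets;
* the instrument accepts only a fraction of generated droplets, exercising the
  >=10,000 accepted-droplet QC rule.

Study-level generators compose wells into the designs the pipeline analyses:
dilution series (linearity), spike-in recovery arms, longitudinal multi-subject
collections with duplicate extractions and shared no-template controls, and
preservation time courses with exponential decay (or growth) of the true
signal.  All randomness flows from one explicit seed; per-well sub-streams are
derived deterministically in enumeration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .droplet import DEFAULT_REACTION_VOLUME_UL, DropletWell
from .stats import SampleRecord

DEFAULT_ASSAY = "hLINE1-60"


@dataclass(frozen=True)
class SimulationConfig:
    """Instrument-level simulation parameters.

    Amplitude-cluster parameters are a minimal invention: the pipeline only
    needs a threshold-separable two-cluster distribution with rain and rare
    NTC false positives; they are not estimates of any instrument.
    """

    droplet_volume_nl: float = 0.85
    n_droplets_generated: int = 20_000
    accepted_fraction: float = 0.9
    neg_mean: float = 1800.0
    neg_sd: float = 200.0
    pos_mean: float = 6500.0
    pos_sd: float = 400.0
    rain_fraction: float = 0.02
    false_positive_rate: float = 5e-5
    reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL

    def __post_init__(self) -> None:
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")
        if not 0 < self.accepted_fraction <= 1:
            raise ValueError("accepted fraction must be in (0, 1]")
        if self.neg_mean >= self.pos_mean:
            raise ValueError("negative cluster mean must lie below positive cluster mean")
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ValueError("cluster standard deviations must be positive")
        if not (0 <= self.rain_fraction <= 1 and 0 <= self.false_positive_rate <= 1):
            raise ValueError("rain fraction and false-positive rate must be in [0, 1]")


@dataclass(frozen=True)
class StudyDesign:
    """Design of a longitudinal stool-collection study.

    ``baseline_copies_per_mg`` and ``log_variation_sd`` set the median and the
    natural-log-scale day-to-day spread of the true host-DNA level; an SD of
    0.8 gives the several-fold day-to-day variation seen in healthy donors.
    Stool mass is per ~200 ul homogenate aliquot; per-mg normalisation here is
    in the literal convention (copies per ul extract / mg).
    """

    subjects: tuple[str, ...] = ("D-145x", "D-165x", "D-166x")
    timepoints: tuple[int, ...] = tuple(range(10))
    log_variation_sd: float = 0.8
    baseline_copies_per_mg: float = 10_000.0
    stool_mass_range: tuple[float, float] = (20.0, 80.0)
    dilution_factor: float = 100.0
    extraction_cv: float = 0.05
    elution_volume_ul: float = 100.0
    n_ntc_wells: int = 4

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.log_variation_sd < 0:
            raise ValueError("log-scale variation SD must be non-negative")
        if self.stool_mass_range[0] <= 0 or self.stool_mass_range[1] < self.stool_mass_range[0]:
            raise ValueError("stool mass range must be positive and ordered")


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def simulate_well(
    true_copies_per_ul_reaction: float,
    cfg: SimulationConfig = SimulationConfig(),
    seed: int | np.random.SeedSequence = 0,
    *,
    well_id: str = "A01",
    sample_id: str = "sample",
    assay_id: str = DEFAULT_ASSAY,
) -> DropletWell:
    """Simulate one well's accepted-droplet amplitude vector.

    Each accepted droplet draws a Poisson occupancy with mean
    ``concentration x droplet volume``; occupied droplets emit
    positive-cluster amplitudes (a ``rain_fraction`` of them re-drawn
    uniformly between the cluster means), empty droplets emit
    negative-cluster amplitudes except for rare false positives.  Identical
    (inputs, seed) give bit-identical wells.
    """
    if true_copies_per_ul_reaction < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    n_accepted = int(round(cfg.n_droplets_generated * cfg.accepted_fraction))
    lam = true_copies_per_ul_reaction * (cfg.droplet_volume_nl / 1000.0)
    occupied = rng.poisson(lam, n_accepted) > 0

    amplitudes = np.empty(n_accepted, dtype=float)
    n_pos = int(occupied.sum())
    n_neg = n_accepted - n_pos

    pos_amp = rng.normal(cfg.pos_mean, cfg.pos_sd, n_pos)
    if cfg.rain_fraction > 0 and n_pos:
        rain = rng.random(n_pos) < cfg.rain_fraction
        pos_amp[rain] = rng.uniform(cfg.neg_mean, cfg.pos_mean, int(rain.sum()))
    neg_amp = rng.normal(cfg.neg_mean, cfg.neg_sd, n_neg)
    if cfg.false_positive_rate > 0 and n_neg:
        fp = rng.random(n_neg) < cfg.false_positive_rate
        neg_amp[fp] = rng.normal(cfg.pos_mean, cfg.pos_sd, int(fp.sum()))

    amplitudes[occupied] = pos_amp
    amplitudes[~occupied] = neg_amp
    np.clip(amplitudes, 0.0, None, out=amplitudes)
    return DropletWell(well_id, sample_id, assay_id, amplitudes)


@dataclass
class SimulatedStudy:
    """Wells plus metadata and ground truth for one simulated experiment."""

    wells: list[DropletWell]
    samples: list[SampleRecord]
    truth: pd.DataFrame  # sample_id, true_copies_per_ul_reaction, true_copies_per_mg


def simulate_dilution_series(
    stock_copies: float,
    dilution_factors: Sequence[float] = (1.0, 5.5, 30.6, 170.0, 624.0),
    replicates_per_level: int = 3,
    cfg: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    *,
    measurement_yield: float = 1.0,
    assay_id: str = DEFAULT_ASSAY,
) -> tuple[list[DropletWell], pd.DataFrame]:
    """Simulate a standard-curve dilution series with known theoretical copies.

    The default factors span five levels from the stock down ~624-fold; with
    the default stock of 120,440 copies per reaction the series covers ~193
    to 120,440 copies, the validated linear range.  ``measurement_yield``
    scales the true concentration relative to theory (detection efficiency of
    the standard), leaving the theoretical truth table untouched.
    """
    if stock_copies <= 0:
        raise ValueError("stock copies must be positive")
    if len(dilution_factors) == 0:
        raise ValueError("at least one dilution factor required")
    if any(d < 1 for d in dilution_factors):
        raise ValueError("dilution factors must be >= 1")
    wells, rows = [], []
    seeds = _child_seeds(seed, len(dilution_factors) * replicates_per_level)
    k = 0
    for i, d in enumerate(dilution_factors):
        theoretical = stock_copies / d
        conc = measurement_yield * theoretical / cfg.reaction_volume_ul
        for r in range(1, replicates_per_level + 1):
            sid = f"std-L{i + 1}-r{r}"
            wells.append(
                simulate_well(conc, cfg, seeds[k], well_id=sid, sample_id=sid, assay_id=assay_id)
            )
            rows.append(
                {"sample_id": sid, "level": i + 1, "dilution_factor": d,
                 "theoretical_copies_per_reaction": theoretical}
            )
            k += 1
    return wells, pd.DataFrame(rows)


@dataclass
class SpikeInFixture:
    """Wells for the three arms of a spike-in recovery experiment.

    Keys of each dict are the genome-equivalent spike levels; the buffer-only
    arm is shared across levels (it contains no spike).
    """

    with_spike: dict[float, list[DropletWell]]
    spike_alone: dict[float, list[DropletWell]]
    buffer_only: list[DropletWell]
    true_recovery: float
    truth: pd.DataFrame


def simulate_spikein_experiment(
    spike_ge_levels: Sequence[float] = (232_000.0, 23_200.0, 2_320.0),
    copies_per_ge: float = 5800.0,
    true_recovery: float = 0.62,
    background_acn: float = 2000.0,
    replicates: int = 3,
    cfg: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    *,
    assay_dilution: float = 1e5,
    assay_id: str = DEFAULT_ASSAY,
) -> SpikeInFixture:
    """Simulate the three arms of a genomic-DNA spike-in recovery experiment.

    Truths, in copies per reaction after an ``assay_dilution``-fold dilution
    shared by all arms (the dilution cancels in the recovery ratio):

    * with-spike arm: background + spike GE x copies/GE x true recovery
    * buffer-only arm: background
    * spike-alone arm: spike GE x copies/GE (no purification loss)

    ``background_acn`` is already on the per-reaction scale of the diluted
    stool extract and is therefore not divided further.
    """
    if not 0 <= true_recovery <= 1:
        raise ValueError("true recovery must be a fraction in [0, 1]")
    if background_acn < 0:
        raise ValueError("background ACN must be non-negative")
    levels = list(spike_ge_levels)
    seeds = iter(_child_seeds(seed, (2 * len(levels) + 1) * replicates))
    with_spike: dict[float, list[DropletWell]] = {}
    spike_alone: dict[float, list[DropletWell]] = {}
    rows = []

    def _arm(truth_acn: float, tag: str) -> list[DropletWell]:
        conc = truth_acn / cfg.reaction_volume_ul
        arm_wells = []
        for r in range(1, replicates + 1):
            sid = f"{tag}-r{r}"
            arm_wells.append(
                simulate_well(conc, cfg, next(seeds), well_id=sid, sample_id=sid, assay_id=assay_id)
            )
        rows.append({"arm": tag, "true_copies_per_reaction": truth_acn})
        return arm_wells

    buffer_only = _arm(background_acn, "buffer")
    for ge in levels:
        spike_acn = ge * copies_per_ge / assay_dilution
        with_spike[ge] = _arm(background_acn + spike_acn * true_recovery, f"spike-{ge:g}GE")
        spike_alone[ge] = _arm(spike_acn, f"alone-{ge:g}GE")
    return SpikeInFixture(with_spike, spike_alone, buffer_only, true_recovery, pd.DataFrame(rows))


def simulate_longitudinal_study(
    design: StudyDesign = StudyDesign(),
    cfg: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    *,
    assay_id: str = DEFAULT_ASSAY,
) -> SimulatedStudy:
    """Simulate a multi-subject longitudinal collection with duplicate extractions.

    Per (subject, day): stool mass is uniform over the design range, the true
    copies-per-mg level is log-normal around the baseline, and each of two
    extraction replicates perturbs the true extract concentration by a
    log-normal factor with coefficient of variation ``extraction_cv``.  Four
    (by default) shared NTC wells contain no template beyond instrument false
    positives.
    """
    if not design.subjects or not design.timepoints:
        raise ValueError("study design needs at least one subject and one timepoint")
    n_samples = len(design.subjects) * len(design.timepoints)
    seeds = iter(_child_seeds(seed, n_samples * 3 + design.n_ntc_wells))
    wells: list[DropletWell] = []
    samples: list[SampleRecord] = []
    truth_rows = []

    for subject in design.subjects:
        for day in design.timepoints:
            sid = f"{subject}-d{day:03d}"
            rng = np.random.default_rng(next(seeds))
            mass = rng.uniform(*design.stool_mass_range)
            true_cpm = design.baseline_copies_per_mg * math.exp(
                rng.normal(0.0, design.log_variation_sd)
            )
            true_cue = true_cpm * mass  # copies per ul extract, literal convention
            true_conc = true_cue / design.dilution_factor / cfg.reaction_volume_ul
            truth_rows.append(
                {"sample_id": sid, "subject_id": subject, "collection_day": day,
                 "stool_mass_mg": mass,
                 "true_copies_per_ul_reaction": true_conc,
                 "true_copies_per_mg": true_cpm}
            )
            for rep in (1, 2):
                rep_rng = np.random.default_rng(next(seeds))
                factor = (
                    rep_rng.lognormal(0.0, design.extraction_cv)
                    if design.extraction_cv > 0 else 1.0
                )
                samples.append(
                    SampleRecord(
                        sample_id=sid, subject_id=subject, collection_day=day,
                        stool_mass_mg=mass, dilution_factor=design.dilution_factor,
                        extraction_replicate=rep, buffer="EDTA",
                        elution_volume_ul=design.elution_volume_ul,
                    )
                )
                wells.append(
                    simulate_well(
                        true_conc * factor, cfg, rep_rng,
                        well_id=f"{sid}-r{rep}", sample_id=sid, assay_id=assay_id,
                    )
                )

    samples.append(
        SampleRecord(sample_id="NTC", is_ntc=True, dilution_factor=1.0, buffer="none")
    )
    for i in range(design.n_ntc_wells):
        wells.append(
            simulate_well(
                0.0, cfg, next(seeds),
                well_id=f"NTC-{i + 1}", sample_id="NTC", assay_id=assay_id,
            )
        )
    return SimulatedStudy(wells, samples, pd.DataFrame(truth_rows))


def simulate_preservation_timecourse(
    buffers: Sequence[str] = ("EDTA", "TEN2", "OMNI"),
    decay_rate_per_hour: Optional[dict[str, float]] = None,
    timepoints_hours: Sequence[float] = (0.0, 4.0, 24.0, 72.0, 96.0),
    cfg: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    *,
    baseline_copies_per_ul_extract: float = 50_000.0,
    dilution_factor: float = 100.0,
    stool_mass_mg: float = 50.0,
    single_extraction_buffers: Sequence[str] = ("OMNI",),
    assay_id: str = DEFAULT_ASSAY,
) -> SimulatedStudy:
    """Simulate a room-temperature stool-preservation stability time course.

    True extract concentration at time t is ``baseline x exp(-rate x t)``; a
    negative rate models rising signal (e.g. bacterial growth in a permissive
    buffer).  Default rates: 0/h for EDTA (stable), 0.01/h for TEN2
    (progressive degradation), 0.005/h for OMNI.  Buffers listed in
    ``single_extraction_buffers`` get one extraction per timepoint instead of
    duplicates.
    """
    if 0.0 not in [float(t) for t in timepoints_hours]:
        raise ValueError("timepoints must include the time-0 baseline")
    rates = {"EDTA": 0.0, "TEN2": 0.01, "OMNI": 0.005}
    if decay_rate_per_hour:
        rates.update(decay_rate_per_hour)
    n_max = len(buffers) * len(timepoints_hours) * 2
    seeds = iter(_child_seeds(seed, n_max + 4))
    wells: list[DropletWell] = []
    samples: list[SampleRecord] = []
    truth_rows = []
    for buf in buffers:
        if buf not in rates:
            raise ValueError(f"no decay rate given for buffer {buf!r}")
        n_reps = 1 if buf in single_extraction_buffers else 2
        for t in timepoints_hours:
            sid = f"{buf}-t{t:g}h"
            true_cue = baseline_copies_per_ul_extract * math.exp(-rates[buf] * float(t))
            true_conc = true_cue / dilution_factor / cfg.reaction_volume_ul
            truth_rows.append(
                {"sample_id": sid, "buffer": buf, "time_hours": float(t),
                 "true_copies_per_ul_extract": true_cue,
                 "true_copies_per_ul_reaction": true_conc}
            )
            for rep in range(1, n_reps + 1):
                samples.append(
                    SampleRecord(
                        sample_id=sid, subject_id=buf, collection_day=0,
                        stool_mass_mg=stool_mass_mg, dilution_factor=dilution_factor,
                        extraction_replicate=rep, buffer=buf,
                    )
                )
                wells.append(
                    simulate_well(
                        true_conc, cfg, next(seeds),
                        well_id=f"{sid}-r{rep}", sample_id=sid, assay_id=assay_id,
                    )
                )
    samples.append(SampleRecord(sample_id="NTC", is_ntc=True, buffer="none"))
    for i in range(4):
        wells.append(
            simulate_well(0.0, cfg, next(seeds),
                          well_id=f"NTC-{i + 1}", sample_id="NTC", assay_id=assay_id)
        )
    return SimulatedStudy(wells, samples, pd.DataFrame(truth_rows))
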