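"""End-to-end assembly: droplet files + sample sheet + config -> results table.

The per-sample chain follows the assay's data-analysis procedure exactly:
QC (>=10,000 accepted droplets) -> amplitude threshold calling -> Poisson
concentration -> average over duplicate extractions -> NTC background
subtraction and dilution adjustment -> per-mg-of-stool normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .droplet import (
    Concentration,
    DropletWell,
    WellRejection,
    call_droplets,
    poisson_concentration,
    qc_filter,
)
from .stats import (
    RecoveryExperiment,
    SampleRecord,
    adjust_acn,
    average_replicates,
    normalize_per_mg,
    spike_recovery,
)

logger = logging.getLogger("hostquant")

RESULT_COLUMNS = [
    "sample_id", "assay_id", "n_wells", "positives", "total_droplets",
    "lambda", "copies_per_ul_reaction", "acn_per_reaction",
    "copies_per_ul_extract", "copies_per_mg_stool",
    "clipped", "single_replicate", "saturated",
]


class PipelineError(RuntimeError):
    pass


def quantify_well(well: DropletWell, config: RunConfig) -> Concentration:
    """Threshold-call one well and invert to a concentration."""
    counts = call_droplets(well, config.threshold_for(well.assay_id))
    return poisson_concentration(
        counts, config.droplet_volume_nl, config.reaction_volume_ul
    )


@dataclass
class PipelineResult:
    results: pd.DataFrame
    rejections: list[WellRejection]


def run_pipeline(
    wells: list[DropletWell],
    samples: list[SampleRecord],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Quantify every (sample, assay) pair in a study.

    Returns one result row per (sample, assay) with droplet counts, the
    Poisson estimate, the background/dilution-adjusted extract concentration,
    the per-mg normalisation, and audit flags; QC-rejected wells are listed
    separately and excluded from every estimate.  Deterministic given inputs
    and config.
    """
    config = config or RunConfig()
    sample_meta: dict[str, SampleRecord] = {}
    ntc_ids = set()
    for rec in samples:
        sample_meta.setdefault(rec.sample_id, rec)
        if rec.is_ntc:
            ntc_ids.add(rec.sample_id)

    accepted, rejections = qc_filter(wells, config.min_accepted_droplets)
    for rej in rejections:
        logger.warning("QC-rejected well %s: %s", rej.well.well_id, rej.reason)

    for w in accepted:
        if w.sample_id not in sample_meta:
            raise PipelineError(f"well {w.well_id!r}: sample {w.sample_id!r} not in sample sheet")

    # Per-assay NTC background: mean ACN over the NTC technical-replicate wells.
    assays = sorted({w.assay_id for w in accepted})
    ntc_acn: dict[str, float] = {}
    for assay in assays:
        ntc_wells = [w for w in accepted if w.assay_id == assay and w.sample_id in ntc_ids]
        if ntc_wells:
            ntc_acn[assay] = float(
                np.mean([quantify_well(w, config).copies_per_reaction for w in ntc_wells])
            )
        elif config.acn_ntc_override is not None:
            ntc_acn[assay] = float(config.acn_ntc_override)
        else:
            raise PipelineError(
                f"no NTC wells for assay {assay!r}; supply acn_ntc_override "
                "(e.g. 0.0) to run without background subtraction"
            )

    rows = []
    keys = sorted({(w.sample_id, w.assay_id) for w in accepted if w.sample_id not in ntc_ids})
    for sample_id, assay in keys:
        rec = sample_meta[sample_id]
        sample_wells = [w for w in accepted if w.sample_id == sample_id and w.assay_id == assay]
        concs = [quantify_well(w, config) for w in sample_wells]
        saturated = any(c.saturated_flag for c in concs)
        usable = [c for c in concs if not c.saturated_flag]
        if not usable:
            rows.append({
                "sample_id": sample_id, "assay_id": assay, "n_wells": len(sample_wells),
                "positives": sum(
                    call_droplets(w, config.threshold_for(assay)).positives for w in sample_wells
                ),
                "total_droplets": sum(w.accepted_count for w in sample_wells),
                "lambda": np.nan, "copies_per_ul_reaction": np.nan,
                "acn_per_reaction": np.nan, "copies_per_ul_extract": np.nan,
                "copies_per_mg_stool": np.nan,
                "clipped": False, "single_replicate": len(sample_wells) < 2,
                "saturated": True,
            })
            continue
        summary = average_replicates([c.copies_per_reaction for c in usable])
        cue, clipped = adjust_acn(summary.mean, ntc_acn[assay], rec.dilution_factor)
        if clipped:
            logger.warning(
                "sample %s assay %s: NTC background exceeds signal; clipped to 0",
                sample_id, assay,
            )
        cpm = normalize_per_mg(
            cue, rec.stool_mass_mg, config.normalisation_mode, rec.elution_volume_ul
        )
        positives = sum(
            call_droplets(w, config.threshold_for(assay)).positives for w in sample_wells
        )
        totals = sum(w.accepted_count for w in sample_wells)
        rows.append({
            "sample_id": sample_id, "assay_id": assay, "n_wells": len(sample_wells),
            "positives": positives, "total_droplets": totals,
            "lambda": float(np.mean([c.lambda_ for c in usable])),
            "copies_per_ul_reaction": float(np.mean([c.copies_per_ul_reaction for c in usable])),
            "acn_per_reaction": summary.mean,
            "copies_per_ul_extract": cue,
            "copies_per_mg_stool": cpm,
            "clipped": clipped,
            "single_replicate": summary.single_replicate_flag or saturated,
            "saturated": saturated,
        })
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return PipelineResult(results, rejections)


def estimate_spike_recovery(fixture, config: RunConfig | None = None) -> dict[float, float]:
    """Estimate percent spike-in recovery per genome-equivalent level.

    Quantifies each arm of a simulated (or measured) spike-in experiment,
    averages ACN per reaction within arms, and applies the recovery equation
    R = 100 x (ACN_spike - ACN_buffer) / ACN_alone.
    """
    config = config or RunConfig()

    def _mean_acn(arm_wells: list[DropletWell]) -> float:
        return float(
            np.mean([quantify_well(w, config).copies_per_reaction for w in arm_wells])
        )

    acn_buffer = _mean_acn(fixture.buffer_only)
    out = {}
    for ge, arm in fixture.with_spike.items():
        exp = RecoveryExperiment(
            acn_spike=_mean_acn(arm),
            acn_buffer=acn_buffer,
            acn_alone=_mean_acn(fixture.spike_alone[ge]),
        )
        out[ge] = spike_recovery(exp)
    return out
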