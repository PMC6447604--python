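# hostquant

Absolute quantification of host DNA in stool by droplet digital PCR (ddPCR).

Stool carries DNA shed from the cells lining the gastrointestinal tract, a
non-invasive window on the gut in health and disease. The host fraction is
tiny (typically under 1% of total stool DNA) and often fragmented, so it is
quantified with short-amplicon ddPCR assays against multicopy targets —
LINE-1 nuclear repeats and mitochondrial genes (ND5, CO2) for human samples,
mouse LINE-1 for animal models, and a bacterial 16S assay for the microbial
background. `hostquant` implements the complete computational side of that
workflow for assay developers and analysts: droplet-level threshold calling
and Poisson copy-number estimation, sample-level background/dilution
adjustment and per-mg normalisation, spike-in recovery, specificity ratios,
standard-curve validation statistics, genome-equivalent and cell-count
conversions, in silico PCR, and a forward simulator that generates realistic
droplet data with known ground truth for testing all of it.

## The model

A 20 μl reaction is partitioned into ~20,000 droplets of volume
*V* = 0.85 nl. Template molecules load independently, so the copies per
droplet are Poisson with mean λ, and the fraction of negative droplets
estimates e^−λ:

    λ = −ln(N_neg / N_total)
    concentration (copies/μl reaction) = λ / V
    ACN (copies/reaction) = concentration × 20 μl

Droplets are called positive when their fluorescence amplitude strictly
exceeds the assay threshold (3400 for human assays, 6300 for 16S, 3000 for
mouse); wells with fewer than 10,000 accepted droplets are rejected. For a
stool sample diluted *d*-fold with 1 μl loaded per reaction:

    copies/μl extract = (ACN_sample − ACN_ntc) × d
    copies/mg stool   = copies/μl extract ÷ stool mass (mg)

where ACN_sample averages duplicate extractions and ACN_ntc averages the
no-template controls. Spike-in recovery follows
R = 100 × (ACN_spike − ACN_buffer) / ACN_alone, and copies-per-mg values
convert to whole-cell equivalents through the empirically calibrated
22,910 LINE-1 copies per genome equivalent (5,800 in silico copies × 3.95
median yield on digested genomic DNA).

## Worked example

Simulate a three-subject longitudinal study (10 collection days, duplicate
extractions, shared NTCs), quantify it, and compare to the generative truth:

```sh
hostquant simulate study --seed 7 --out-dir demo
hostquant quantify --droplets demo/droplets.csv --sheet demo/samples.csv --out demo/results.tsv
```

`demo/results.tsv` holds one row per sample with droplet counts, λ, and the
derived concentrations; the first rows of selected columns:

```
sample_id      assay_id   copies_per_ul_reaction  acn_per_reaction  copies_per_ul_extract  copies_per_mg_stool
D-145x-d000    hLINE1-60  1138.91                 22778.17          2277685.79             33558.77
D-145x-d001    hLINE1-60  189.23                  3784.55           378323.80              4792.59
D-145x-d002    hLINE1-60  333.83                  6676.61           667530.75              28757.30
```

Read left to right: ~1139 copies/μl of reaction means λ ≈ 0.97 copies per
droplet; times the 20 μl reaction gives ~22,800 copies per reaction; the
100-fold extract dilution scales that to ~2.3 million copies per μl of
extract; dividing by the stool mass in the aliquot yields ~33,600 copies/mg
— this subject's host-DNA level on day 0, several-fold above its day-1
sample, the kind of day-to-day biological swing the simulator reproduces.
Against `demo/truth.tsv` the mean absolute relative error of copies/mg is
2.8% in this run. Other subcommands: `hostquant inspcr` (in silico PCR on
FASTA), `hostquant convert` (ng → genome equivalents),
`hostquant analyze standard-curve | recovery | stability | cells-per-mg`.

As a library:

```python
from hostquant import simulate_well, call_droplets, poisson_concentration

well = simulate_well(235.4, seed=1)            # copies/μl reaction
conc = poisson_concentration(call_droplets(well, 3400.0))
print(round(conc.copies_per_ul_reaction, 1))   # 230.8 (95% CI 222.9–238.9)
```

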