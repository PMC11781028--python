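# porekinetics

Analysis pipeline for **real-time solid-state nanopore endonuclease
assays**: a glass nanopore immersed in a polymer-electrolyte bath records
conductive translocation pulses while an enzyme (a restriction enzyme such
as SwaI, or a Cas9 ribonucleoprotein) digests a 3 kbp double-stranded DNA
substrate into two 1.5 kbp fragments.  Because the reactant and products
produce distinguishable peak amplitudes (~0.25 nA vs ~0.15 nA), the
amplitude population shift over time is a label-free, single-molecule
read-out of cleavage kinetics.

The package is aimed at nanopore/biophysics groups who want a tested,
reproducible version of this analysis — and a ground-truthed simulator to
validate it against.

## What it computes

1. **Sweep segmentation** — the voltage program alternates +100 mV rest
   (3.5 s) and −700 mV capture (6 s); analysis uses seconds 4–9 of each
   9.5 s sweep.
2. **Event detection** — per-window robust baseline (median/MAD); events
   are contiguous excursions beyond *baseline + 10σ*; peak amplitude and
   FWHM dwell per event.
3. **Population quantification** — per-minute Gaussian-KDE probability
   density functions (PDF) of peak amplitude.  With boundaries fixed at
   ±10% of the reactant peak located in the minute-1 PDF, the probability
   of detecting the uncleaved reactant at minute *t* is the bounded AUC

   P(t) = 100 × ∫[0.9·a₁, 1.1·a₁] f̂ₜ(a) da ,

   where f̂ₜ is the minute-*t* PDF and a₁ the minute-1 reactant peak.
4. **Kinetics** — the reaction rate is −m, where m is the least-squares
   slope of P(t) over the initial-velocity window (first 15 min);
   rate-vs-enzyme-amount linearity (R²) across concentrations; condition
   classification (inactive m > −0.1, active m < −1).
5. **Statistics** — equal-variance two-tailed unpaired t-tests between
   replicate probabilities at minute 1 vs minute 30, gated on Levene's
   homoscedasticity test, with ns/*/**/**** significance codes.

A fully seeded synthetic-data module generates complete experiments
(trace + ground truth) with Poisson event arrivals, per-species
amplitude/dwell distributions, and first-order multi-turnover or
single-turnover-burst digestion kinetics, so every stage is testable
without any instrument data.

## Worked example

Run the bundled demo (a 16-minute digestion with 5 enzyme units,
first-order kinetics at 0.02 min⁻¹ per unit, simulated at 25 kHz):

```bash
porekinetics run --out-dir demo_run --seed 1
```

`demo_run/probability.tsv` starts:

```
minute  n_events  probability_pct  lower_nA  upper_nA
1       53        40.34            0.2200    0.2689
2       54        29.26            0.2200    0.2689
3       57        28.92            0.2200    0.2689
4       71        23.85            0.2200    0.2689
5       64        17.87            0.2200    0.2689
```

The boundaries (0.2200–0.2689 nA) are ±10% around the reactant peak found
in the minute-1 PDF; the probability of detecting the uncleaved 3 kbp
reactant falls from 40% as digestion proceeds.  `demo_run/kinetics.json`
reports the initial-velocity fit:

```
slope_pct_per_min = -1.82    (reaction rate 1.82 %/min)
r_squared         = 0.80
classification    = "active"
```

A slope below −1 %/min classifies the condition as active digestion; a
no-enzyme or pre-digested control stays flat (|m| < 0.1).  The other
subcommands (`simulate`, `detect`, `quantify`, `kinetics`, `compare`) run
the same stages individually from each other's on-disk outputs, and
`manifest.json` records per-stage SHA-256 checksums — identical seeds and
configs reproduce identical outputs.

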