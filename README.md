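# estroscreen

Analysis pipeline for quantitative high-throughput screening (qHTS) of
compounds that inhibit **estrogen-driven growth** of endometrial stromal
cells — the screening strategy used to find drug-repurposing candidates
for endometriosis, an estrogen-dependent disease. It is written for
screening scientists and computational biologists who have per-well cell
counts from high-content imaging of paired 384-well plates (one plate
run under vehicle, its twin under estradiol-17β) and need a tested,
reproducible path from raw counts to lead compounds.

## What it computes

**Plate quality control.** For every plate and condition, the Z′ factor
over the DMSO (negative, MAX-signal) and QC-positive inhibitor
(positive, MIN-signal) control wells,

    Z′ = 1 − 3(δₙ + δₚ)/(µₙ − µₚ),

classified as ideal (= 1), excellent ([0.5, 1)), marginal ([0, 0.5)), or
unacceptable (< 0), and the replicate-well %CV = 100·δ/µ with a < 25%
gate. QC compounds themselves are accepted or rejected from their
two-condition titrations (a positive must inhibit > 70% at the screening
dose under estrogen *without* being estrogen-specific; a negative must
not inhibit in either condition).

**Normalization and triage.** Counts are normalized per plate to the
mean of the retained DMSO vehicle wells (image-flagged wells excluded
first, then a single-pass 3-SD control-outlier rule). Compounds whose
normalized vehicle-condition viability falls below 0.5 are excluded per
cell line: they are toxic with or without estrogen and cannot speak to
estrogen-driven growth.

**Hit calling.** Per compound and cell line, the percent estrogen-driven
inhibition from the paired normalized viabilities α (vehicle) and β
(estrogen):

    %E-DI = 100·(1 − β/α),

with the relative-survival form 100·(β/α) available behind a flag (the
two are complements; the form in use is carried in all outputs). The hit
threshold is adaptive — mean + 2.5 SD of all analyzed %E-DI values —
with an optional fixed override (e.g. 70); hits are strict exceedances.

**Confirmation and leads.** Confirmation dose-responses (5-point 1:5
series from 10 µM; screen 1 singlet, screen 2 duplicate, screens
averaged with equal weight) are fit with the four-parameter logistic
y(c) = B + (T − B)/(1 + (c/IC₅₀)^h), adjudicated into a numeric IC₅₀,
"ND", or ">top dose", and triaged: IC₅₀ ≤ 1 µM in a line makes a
compound a lead for that line, with compounds categorized by line
membership.

A synthetic-screen generator (`estroscreen.synthetic_screen`) emulates
the whole design — paired 384-well plates, estrogen growth stimulation,
vehicle-toxic compounds, a rare tail of strong estrogen-specific
inhibitors, multiplicative well noise — and emits a truth ledger with
every dataset, so each stage is testable for parameter recovery.

## Worked example

```sh
estroscreen demo --seed 1 --out demo_out
```

or equivalently `from estroscreen import pipeline; pipeline.demo(seed=1,
output_dir="demo_out")`, prints:

```
library compounds tested: 3520
excluded by vehicle-toxicity filter (any line): 285 (8.1%)
analyzed: 3235 (91.9%)
unevaluable (missing vehicle measurement): 0
%E-DI form: inhibition
hit threshold: derived 53.74 (mean 5.50 + 2.5 x SD 19.29); applied 53.74
hits per line: 1455: 39, 1458: 53
hits (union over lines): 91 (2.8%)
lead categories: {'1455_only': 8, '1458_only': 20, 'both': 0, 'neither': 63}
```

Reading this: a 10-plate, two-cell-line synthetic screen of 3520
compounds lost 285 compounds (8.1%) to vehicle toxicity; the adaptive
threshold landed at 53.7% inhibition, calling 39 and 53 hits in the two
lines (91 distinct compounds, 2.8% of those analyzed); the simulated
confirmation follow-up then confirmed 28 of them as sub-µM leads in at
least one line. The QC report for the same run shows every plate's Z′ ≥
0.59 (all "excellent") and every control group's %CV under the 25% gate.
Output CSVs (counts, truth ledger, QC report, hit table, fits, lead
table) land in `demo_out/`.

To analyze real data instead, write the plate layout and counts in the
two long-form CSV dialects documented in `estroscreen.plate_model` and
run `estroscreen primary --layout layout.csv --counts counts.csv --out
results/`, then `estroscreen confirm --doses doses.csv --out results/`
for the confirmation screen.

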