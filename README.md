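# srmquant

Post-acquisition workflow for a dual-method (HILIC + reversed-phase)
scheduled-SRM targeted metabolomics assay of plasma, built for analysts who
run large multi-analyte panels on a triple-quadrupole instrument with a
"dilute and shoot" preparation (every sample injected at 1:5 and 1:100).

The package covers everything that happens after peak integration:

* **Method registry** — analytes, quantifier/qualifier SRM transitions, LC
  gradient programs; run-duration and solvent polarity-index arithmetic;
  structural validation (one quantifier per analyte/method, two transitions
  per analyte unless flagged single-transition).
* **Scheduled-SRM dwell budgeting** — per-time-point concurrency from the
  retention-time windows, equal-split dwell allocation under a target cycle
  time *T* with per-transition pause *p* and polarity-switch settling *s*:
  at a moment with *n* concurrent transitions,
  `dwell = (T − overhead − n·p) / n`, `overhead = 2s` when both polarities
  are active, floored at the instrument's 3 ms minimum.
* **Calibration** — 1/x-weighted linear or quadratic least squares on the
  nominal concentration *x* (zero levels excluded), LOD (S/N ≥ 3), LLOQ
  (S/N ≥ 10, with a carryover-plateau fallback), ULOQ (descending search
  requiring r² > 0.995 and 95–105% back-calculation accuracy), reference
  ion ratios, and stable curve inversion.
* **Validation statistics** — carryover (blank area / standard area × 100),
  standard-addition apparent recovery `R_A = 100 · (c_sp − c_NS) / c_A`
  (level-wise) or as spiked/neat slope ratios, repeatability RSD over the
  6 levels × 3 replicates (n = 18), and 70–130% acceptance flags.
* **Quantification** — bracket- or QC-anchored drift correction, two-dilution
  selection (most dilute in-range measurement wins), recovery correction
  `c_corr = c · 100 / R_A` when `R_A` is outside 70–130%, ion-ratio identity
  confirmation, leucine/isoleucine-style isomer deconvolution, and trueness
  reporting against certified reference concentrations.
* **Synthetic data** — a generator standing in for the instrument: response
  curves with per-dilution matrix factors, constant-CV lognormal measurement
  noise, additive baseline noise, carryover into following blanks, and
  linear-in-index drift, with ground truth retained for parameter-recovery
  testing.

## Worked example

```python
import srmquant as sq
from srmquant import datasets

# Trueness of the assay against the NIST SRM 1950 certified plasma values
t = datasets.nist_srm1950_table()
rep = sq.trueness_report(t["measured_ugL"], t["certified_ugL"], analytes=t["analyte"])
print(rep.table.head(3).to_string(index=False))
print(f"{rep.n_within} of {rep.n_evaluable} within 70-130%")
```

prints

```
   analyte  certified_ugL  measured_ugL  trueness_pct
Methionine         3325.0        2146.0          65.0
   Leucine        13158.0        9038.0          69.0
   Proline        20298.0       15859.0          78.0
11 of 15 within 70-130%
```

i.e. methionine was recovered at 65% of its certified concentration, and 11
of the 15 metabolites evaluable in the reference plasma fall inside the
70–130% trueness band. Fitting a calibration curve works statsmodels-style:

```python
result = sq.CalibrationModel([1, 10, 100, 1000], [210, 2005, 20100, 199000]).fit()
print(result.summary())
```

```
Calibration fit (linear, 1/x weighted)
  levels: 4 non-zero (1 – 1000 µg/L)
  weighted r²: 0.999992
   intercept:  12.4807  (se 12.2)
       slope:  199.158  (se 0.386)
```

A CLI mirrors the pipeline for shell use: `srmquant schedule | simulate |
calibrate | validate | quantify | report` (see `--help` on each).

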