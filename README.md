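# dvjrel

Multi-site drop-vertical-jump (DVJ) motion-analysis reliability pipeline.

Prospective ACL-injury-risk screening uses 3D motion capture of a drop
vertical jump — drop from a 31 cm box, land on two force plates, jump
maximally — to measure lower-extremity kinematics and kinetics such as the
knee abduction angle and moment.  Scaling such screening beyond one
laboratory requires knowing how reliable those measurements are
trial-to-trial within a lab and, critically, between labs with different
cameras, plates and staff.  `dvjrel` is a reusable implementation of that
whole measurement chain for biomechanists and methodologists:

* **I/O** for trials (markers + force plates) in a plain-text TSV dialect
  ([docs/format.md](docs/format.md)) and, optionally, C3D;
* **preprocessing**: cubic-spline and virtual-pelvis-marker gap filling,
  zero-phase 4th-order Butterworth low-pass (12 Hz cutoff), stance
  detection by the 10 N vertical-GRF rule, 101-point time normalization;
* **kinematics**: anatomical frames from a neutral static trial,
  least-squares rigid cluster tracking, clinical Cardan joint angles;
* **kinetics**: bottom-up Newton–Euler internal joint moments (N·m/kg);
* **QC**: a simplified-skeleton tracking check and confidence-band
  outlier-curve screening;
* **reliability**: peak extraction, 3-trial averaging, Shrout–Fleiss
  two-way ICC, SEM and Kadaba's CMC across within-site, between-site-pair
  and among-sites designs, with the published classification rule
  (ICC > 0.75 excellent, 0.4–0.75 good, < 0.4 poor);
* a **synthetic multi-site DVJ cohort generator** with exact ground truth
  (true angles, moments, stance, injected gaps), so every stage is
  testable without raw study data.

The core statistics, with BMS/EMS the between-subject and residual mean
squares of the two-way ANOVA over an *n* subjects × *k* raters table:

    ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS)
    ICC(3,k) = (BMS − EMS) / BMS
    SEM      = SD · √(1 − ICC)
    CMC      = √(1 − [ΣᵢΣₜ(Yᵢₜ−Ȳₜ)² / (T(M−1))] / [ΣᵢΣₜ(Yᵢₜ−Ȳ)² / (MT−1)])

where "raters" are trials (within-site) or laboratories (between/among),
and the CMC compares M stance curves over T = 101 normalized time points.

## Worked example

Simulate a 6-subject, 3-laboratory cohort (3 trials each, default noise:
0.5 mm marker noise, 2 mm/8 Hz soft tissue, 7 mm inter-site
marker-placement offsets, ASIS gap dropouts), run the full pipeline, and
summarize reliability of two knee variables:

```python
from dvjrel.simulate import DVJSpec, NoiseSpec, generate_cohort
from dvjrel.pipeline import PipelineConfig, process_cohort
from dvjrel.reliability import reliability_report

cohort = generate_cohort(DVJSpec(n_subjects=6), NoiseSpec(), seed=0)
peaks, waveforms, qc, results, excluded = process_cohort(cohort, PipelineConfig())
print(f"processed {len(results)} of {len(cohort.items)} trials; QC failures: {qc.n_failed}")

rep = reliability_report(peaks, waveforms, side="r").to_frame()
sel = rep[rep["variable"].isin(["knee_flexion_angle", "knee_abduction_angle"])]
cols = ["design", "unit", "variable", "icc_form", "icc", "classification", "sem", "cmc_mean"]
print(sel[cols].round(3).to_string(index=False))
```

which prints:

```
processed 54 of 54 trials; QC failures: 0
 design unit             variable icc_form    icc classification   sem  cmc_mean
 within    A knee_abduction_angle      3,k  0.997      excellent 0.331     0.939
 within    B knee_abduction_angle      3,k  0.994      excellent 0.345     0.942
 within    C knee_abduction_angle      3,k  0.979      excellent 0.447     0.894
between  A-B knee_abduction_angle      3,1 -0.380           poor 5.613     0.917
between  A-C knee_abduction_angle      3,1 -0.035           poor 5.093     0.495
between  B-C knee_abduction_angle      3,1 -0.275           poor 3.948     0.961
  among  all knee_abduction_angle      3,k -1.335           poor   NaN     0.281
 within    A   knee_flexion_angle      3,k  0.962      excellent 1.032     0.997
 within    B   knee_flexion_angle      3,k  0.884      excellent 1.589     0.996
 within    C   knee_flexion_angle      3,k  0.907      excellent 1.480     0.997
between  A-B   knee_flexion_angle      3,1  0.905      excellent 1.477     0.998
between  A-C   knee_flexion_angle      3,1  0.923      excellent 1.331     0.999
between  B-C   knee_flexion_angle      3,1  0.893      excellent 1.416     0.998
  among  all   knee_flexion_angle      3,k  0.967      excellent   NaN     0.998
```

Reading it: trial-to-trial reliability within each lab is excellent for
both variables (ICC(3,k) ≥ 0.88, SEM ≈ 0.3–1.6°).  Between labs, peak
knee *flexion* — a large-range sagittal variable — stays excellent, while
peak knee *abduction* collapses (here negative ICCs at n = 6): the 7 mm
marker-placement offsets tilt the anatomical axes, and the resulting
crosstalk from the ~95° flexion excursion swamps the few degrees of
genuine between-subject abduction variance.  That sagittal-robust /
frontal-fragile pattern is the characteristic finding of multicenter DVJ
reliability studies, reproduced here as a controlled simulation property.

## Command line

```sh
dvjrel run --out runs/demo --subjects 25 --seed 0        # full pipeline + plots
dvjrel simulate --subjects 5 --out trials/ --seed 1      # TSV trials + ground truth
dvjrel process --in trials/ --out processed/
dvjrel qc --in trials/                                   # nonzero exit on failures
dvjrel reliability --peaks processed/peaks.tsv --waveforms processed/waveforms.tsv --out rel.tsv
dvjrel report --reliability-tsv rel.tsv                  # side-by-side vs packaged reference tables
```

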