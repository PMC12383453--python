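# arcqa

Virtual QA toolkit for single-isocenter SRS (stereotactic radiosurgery)
arcs.  It predicts the patient-specific QA outcome — the gamma passing
rate (GPR) of a dynamic arc — from plan-complexity features extracted from
the arc's MLC trajectory, using a time-series-aware random-forest
pipeline, and quantifies the workload impact of using such a model as a
pre-measurement triage step.

## What's inside

| Module | Role |
| --- | --- |
| `arcqa.plan_model` | Domain types (`MachineSpec`, `ControlPoint`, `ArcBeam`, `QARecord`), RTPLAN-subset read/write, mechanical arc validation |
| `arcqa.complexity` | 18 per-arc complexity features (aperture geometry, delivery-dynamics via a max-of-constraints time model, gap statistics, MCS, tongue-and-groove index, modulation index, beam irregularity/modulation, edge metric, leaf travel) |
| `arcqa.gamma` | 2D gamma-index maps (dose difference / distance-to-agreement with sub-pixel search) and passing rates |
| `arcqa.cohort` | Synthetic cohort generator: mechanically valid arcs whose modulation scales with a complexity level, plus a calibrated statistical GPR simulator and a physical (fluence + gamma) simulator |
| `arcqa.feature_selection` | Spearman correlation, Ward clustering on `1 - |r_s|`, representative selection (medoid rule or the published 15-feature preset) |
| `arcqa.pipeline` | Hybrid time-series/stratified split, low-GPR sample weighting, leakage-safe robust scaling, randomized hyperparameter search, threshold-limit calibration |
| `arcqa.evaluation` | Regression/classification reports, ROC/PR curves, partial dependence, workload-reduction model |

The RTPLAN I/O uses a small built-in DICOM codec (explicit VR little
endian) covering the dynamic-arc subset; files it writes are
standard-conformant and readable by pydicom, but reading arbitrary
transfer syntaxes is out of scope.

## CLI

```bash
# generate a synthetic cohort with simulated measured GPRs + features
arcqa simulate --n-patients 592 --seed 0 --out cohort/ --features

# extract the 18 features from RTPLAN files
arcqa extract plan1.dcm plan2.dcm --out features.csv

# correlation clustering / feature selection (figures optional)
arcqa select-features --features cohort/features.csv \
    --rule published --report selection.json --figures figs/

# split, search, train, calibrate the threshold limit
arcqa train --features cohort/features.csv --selected published \
    --n-iter 1000 --seed 0 --bundle model.joblib --report train.json

# evaluate on a labelled feature table
arcqa evaluate --bundle model.joblib --features cohort/features.csv \
    --report eval.json --figures figs/ --pdp "Area,Median MLCGap,MeanRR,BM"
```

## Notes

* The synthetic generator is calibrated so its marginal GPR distribution
  matches a clinical SRS cohort summary (median 98.3%, Q1–Q3 95.1–99.6%,
  ≈75% of arcs ≥ 95%), with a planted, recoverable dependence of failures
  on small apertures, narrow leaf gaps, high beam modulation and high
  modulation index.
* The workload model is a reconstruction: flagged arcs get a quick
  reoptimization, missed true failures cost a full replanning cycle, and
  the reduction is reported relative to handling every true failure with
  a full cycle.
* Synthetic gamma comparisons default to a 1.0 mm grid (not the 0.336 mm
  EPID panel resolution) for tractability.
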