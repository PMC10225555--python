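# hcscreen

Analysis toolkit for a cell-based high-content GFP-reporter screen, exercised
end to end on synthetic data with planted ground truth. It covers:

- **synthetic_data** — seeded generators for plate maps, per-well measurement
  tables, two-channel phantom field images (16-bit TIFF), serial-dilution
  concentration–response series, flow-cytometry-like event samples, and qPCR
  Ct quadruples. Every generator plants a known truth that downstream tests
  recover.
- **imaging** — nucleus segmentation on the DNA channel (Gaussian smoothing +
  Otsu), per-nucleus cytoplasmic ring masks (exact Euclidean dilation,
  contested pixels to the nearest nucleus centre), per-cell mean GFP, and
  field-to-well aggregation.
- **plate_stats** — per-plate control statistics, percent activity
  `100*(x − µn)/(µp − µn)`, the Z′-factor `1 − 3(δp + δn)/|µp − µn|`, and QC
  pass/fail reports.
- **hit_calling** — the dual criterion: percent activity strictly above a
  threshold (default 40) AND cell count inside the negative-control viability
  band (mean ± k·SD), plus confusion counts against planted truth.
- **dose_response** — serial dilutions, four-parameter-logistic least-squares
  fits on log-concentration, and validated-active classification per
  dilution series.
- **validation_assays** — flow MFI, top-percentile gating with tie handling,
  double-delta-Ct relative quantification, and µM → µg/mL conversion from a
  molecular formula.
- **pipeline / cli** — seeded orchestration (table mode or image-rendering
  mode) with byte-deterministic outputs.

## CLI

```bash
# one-shot pipeline: simulate -> screen (-> validate), outputs under out/
hcscreen run --config run.json --seed 42 --out-dir out --with-validation

# individual stages
hcscreen simulate --seed 1 --out-dir sim/
hcscreen screen --plates sim/plate_map.csv --measurements sim/measurements.csv \
    --activity-threshold 40 --k 1 --sided both --out calls.csv
hcscreen validate --series series.csv --activity-threshold 40 --sided lower \
    --out fits.json
hcscreen quantify --images fields/ --plate-map sim/plate_map.csv --out wells.csv
hcscreen report --hits calls.csv --truth sim/ground_truth.csv --out report.json
```

`run.json` is the JSON form of `hcscreen.pipeline.RunConfig`
(see `RunConfig().to_json()` for a template); identical configs produce
byte-identical outputs.

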