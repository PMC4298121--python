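# vascmark

Site-specific vascular marker pipeline: transit-time aortic pulse wave
velocity (PWV) from velocity-encoded flow curves, carotid normalized wall
index (NWI) from vessel-wall contour stacks, 27-segment peripheral stenosis
scoring, and a cohort association analysis (Pearson/Spearman correlations
with cell-wise outlier handling and pairwise-complete Ns, multiple linear
regression with standardized coefficients, interaction scan) — exercised
end-to-end on synthetic cohorts with known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `vascmark.pwv` | wave-foot onset (diastolic baseline x systolic upslope intersection), transit time, centerline path length, PWV = Δx/Δt |
| `vascmark.carotid` | shoelace contour areas, per-slice wall measures, NWI over slices 2–5 as a ratio of means |
| `vascmark.stenosis` | percent → 5-class mapping (0→1, 1–50→2, 51–75→3, 76–99→4, 100→5), per-segment max, per-patient Max SC / Mean SC |
| `vascmark.stats` | KS normality (Lilliefors or conservative plug-in), correlations, cell-wise outlier removal, OLS with standardized β, interaction scan |
| `vascmark.synthetic` | flow-curve pairs with known foot shift, carotid contour stacks, latent-variable cohort generator calibrated to published cohort summaries, deterministic 42-row fixture cohort |
| `vascmark.pipeline` / `vascmark.cli` | orchestration, config, manifests, CLI |

The cohort generator couples a standard-normal latent severity score to age
and to the continuous markers through configurable path coefficients;
segment stenosis classes arise by ordinal thresholding of
`lambda * severity + noise`, and Mean SC / Max SC are always computed from
the simulated segment classes through the stenosis module. The shipped
defaults were calibrated by Monte-Carlo coordinate search
(`scripts/calibrate_cohort.py`).

## CLI

```bash
vascmark simulate --seed 1 --n-patients 42 --out-dir out/        # full synthetic run
vascmark measure  --cohort cohort.csv --grades grades.csv --out-dir out/
vascmark associate --cohort cohort.csv --flag P001:mean_sc --flag P002:pwv_proximal
vascmark pwv --proximal prox.csv --distal dist.csv --centerline cl.csv [--centerline2 cl2.csv]
vascmark nwi --contours stack.csv
vascmark stenosis --grades grades.csv
```

A YAML config (`--config`) can override any generator/pipeline field
(nested `cohort:` and `waveform:` sections; unknown keys are rejected).
Outputs per run: `cohort.csv`, `association.json` / `association.txt`,
`regression.json`, and `manifest.json` (config digest, seed, checksums);
identical config + seed reproduces byte-identical outputs.

## File formats

All interchange files are UTF-8 CSV with a header row: curves
`(time_ms, velocity_cms)`, centerlines `(x_mm, y_mm[, z_mm])`, contour
stacks `(slice, ring, vertex_index, x_mm, y_mm)`, stenosis grades
`(patient_id, segment_id, reading_type, value)`, and the cohort table with
blank cells marking invalid values.

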