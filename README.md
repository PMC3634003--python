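# famap — fluorescein-angiography permeability mapping

`famap` turns a time-resolved fundus fluorescein-angiography (FA) sequence
into a per-pixel vascular permeability map. The pipeline:

1. **Preprocess** — flag noisy / non-retinal frames (correlation against the
   pixel-wise median frame) and classify eye laterality from the optic-disc
   center of mass.
2. **Register** — sub-pixel translation alignment by phase correlation with
   upsampled-DFT refinement on Laplacian-of-Gaussian (8×8, σ = 1.4) filtered
   frames, chained outward from an automatically selected reference frame.
3. **Normalize** — divide every pixel's time course by the arterial input
   function (mean intensity of a manually selected artery region).
4. **Slope fitting** — ordinary-least-squares slope of normalized intensity
   versus time over the late phase (default from 120 s). Positive slopes
   indicate dye accumulation, i.e. blood-retinal-barrier leakage.
5. **Calibrate & render** — a pathological-slope threshold is read off the
   mean cumulative histogram of a healthy cohort (default 99.5th
   percentile); maps are rendered blue below the threshold and yellow-to-red
   above it.
6. **Rater statistics** — Fleiss' kappa, a paired bootstrap for correlated
   kappa differences, rater-averaged sensitivity/specificity, 3×3-grid
   consensus scoring, and the exact one-tailed McNemar test.

A synthetic phantom generator (`famap.synthetic`) produces FA studies with
known dye kinetics, regional leak rates, inter-frame motion and noise; it is
the ground-truth substrate for the test suite.

## CLI

```bash
famap simulate  --spec phantom.json --out study/           # synthetic study
famap preprocess --input study/frames --meta study/frames/meta.json --report qc.csv
famap register  --input study/frames --meta study/frames/meta.json \
                --out registered/ --shifts shifts.csv
famap slope     --registered registered/ --artery study/artery.json --out slope.tif
famap calibrate --healthy s1_slope.tif --healthy s2_slope.tif --out threshold.json
famap render    --slope slope.tif --threshold threshold.json --out map

# end-to-end, single subject
famap analyze --input study/frames --meta study/frames/meta.json \
              --artery study/artery.json --disc study/disc.json --out analysis/

# end-to-end, whole cohort (healthy calibration + scoring) from one command
famap analyze --config cohort.json --out cohort_out/

# agreement statistics from rater grid CSVs
famap rater-stats --grids fa.csv --map-grids maps.csv --gold gold.csv \
                  --seed 1 --boot 10000 --out stats.json
```

Frames are single-channel TIFF/PNG files with a JSON sidecar mapping each
filename to its acquisition time in seconds since injection. Regions of
interest are JSON (polygon vertex list or run-length mask) tagged with a
role (`artery`, `optic_disc`, `other`). Rater grids are CSV with columns
`rater_id,eye_id,sq_1..sq_9,overall`. Slope maps are 32-bit float TIFFs with
NaN marking unfitted pixels.

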