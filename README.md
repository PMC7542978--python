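# gaitglove

Analysis pipeline for data-glove recordings of cyclic in-hand object
manipulation. A 20 s run (1000 frames at 50 Hz, 29 calibrated sensors in
[0, 1000]) is trimmed to its last 800 frames and 19 manipulation-relevant
channels, then decomposed and characterized:

- **decomposition** — per-run covariance PCA (expression coefficients, time
  courses, eigenvalues), Guttman–Kaiser salience, and two-stage sign
  alignment of ECs (within subject, then across subjects, then a canonical
  global sign).
- **clustering** — k-means taxonomy of the aligned ECs under correlation
  distance, cluster→component-rank labeling by maximum-agreement matching,
  misassignment tables, and Kruskal–Wallis sensor-salience tests with
  Dunn-type Bonferroni-corrected post-hocs.
- **temporal** — unit-max normalized component spectra, signed bounded-lag
  (±25 frame) delays between component time courses with the within-1 s
  "gaiting fraction", and peak-interval channel frequencies after zero-phase
  10 Hz FIR filtering, with between-hand rank-sum and within-hand Friedman
  tests of sensor-group means.
- **network** — signed weighted 12-node joint-correlation graphs (negative
  weights retained), thresholded subnetworks, global efficiency on
  inverse-magnitude edge lengths, small-world σ and propensity φ against
  weight-shuffled null ensembles, and signed Louvain modules (γ = 1,
  consensus over seeded restarts).
- **trajectory** — segmentation of 23-point 3D hand-model series (36.97 Hz)
  into per-fingertip trajectories at thumb-extension maxima; path lengths,
  speeds (cm/s), repetition frequencies, 100-point arc-length-resampled
  mean trajectories and 95% error ellipsoids.
- **synthetic** — a seeded generator of glove-like runs (K latent ~1 Hz
  pulse-train components with signed sensor loadings, sub-second delays,
  noise, per-run/subject jitter) and 3D fingertip loops, with full ground
  truth for parameter-recovery testing.

## CLI

```sh
gaitglove simulate --spec spec.yaml --seed 1 --out runs/     # run TSVs + groundtruth.json
gaitglove decompose --runs runs/ --hand left --out decomp.json
gaitglove cluster   --runs runs/ --seed 7 --out taxonomy.json
gaitglove temporal  --runs runs/ --out temporal.json
gaitglove network   --runs runs/ --seed 7 --out network.json
gaitglove trajectory --points points.tsv --out summary.json
gaitglove run-all   --seed 1 --out report_dir/               # full pipeline
gaitglove validate  --seed 1                                  # parameter-recovery checks
```

`run-all` and `validate` accept `--config config.yaml` (see
`gaitglove.pipeline.PipelineConfig` for the schema); every stochastic stage
takes an explicit seed and identical config + seed reproduces byte-identical
reports.

Run files are UTF-8 TSV: `#key=value` metadata lines (subject, hand, run,
rate), one header row of channel labels, then one row per frame with a
1-based frame column. Point files are TSV with `frame` plus
`<point>_x/_y/_z` columns in mm for the 23 hand-model points. The canonical
29-channel layout (labels, roles, the 19-channel analysis subset and the
12-channel graph subset) ships as a packaged JSON resource.

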