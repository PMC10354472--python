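# nestwatch

Within-nest behavioural and thermal analysis for tagged bumblebee colonies
under combined cold and neonicotinoid stress. The pipeline goes from
tag-detection trajectories and thermal frame stacks to:

* **thermal calibration** — per-frame linear (gain + offset) calibration
  against in-nest temperature probes, non-rigid B-spline registration of
  tracking-camera coordinates into thermal frames, and disc-mean body/brood
  temperature extraction;
* **behavioural metrics** — eleven per-bee, per-video metrics (element
  interaction rates, spatial correlation to nest-mates, contact rate, degree
  centrality, moving speed and five distance metrics), plus contact networks,
  a bimodal-speed activity threshold and on/off-nest classification;
* **spatial centrality** — PCA of the scaled metrics, PC1 oriented so higher
  scores mean closer to the nest centre, Yeo-Johnson transformed;
* **activity Markov analysis** — active/inactive state labelling and
  transition-probability estimation per body-temperature bin with Wilson CIs,
  plus a treatment-arm contrast below/above a threshold temperature;
* **mixed-model stats** — LMM/GLMM structures with an AIC selection ledger
  (simplest model within ΔAIC 4 of the best) and a Poisson productivity model
  with the colony-size × cold × imidacloprid interaction;
* **a synthetic colony generator** — seeded, fully deterministic simulation of
  two-state bee motion with temperature-dependent transition rates,
  cold-induced thermotaxis toward the brood, a collective 2-D thermal field,
  a smooth dual-camera warp, and Poisson colony censuses — with complete
  ground truth for every stage, so the whole pipeline is testable offline.

## CLI

```bash
nestwatch simulate --config sim.yaml --out data/ --seed 1   # synthetic dataset
nestwatch validate data/                                    # invariant checks
nestwatch metrics --detections data/detections.csv --nest data/nest.json --out metrics.csv
nestwatch centrality --metrics metrics.csv --variant queenright_11 --out scores.csv
nestwatch thermal --stack s.tif --probes p.csv --warp w.json \
    --detections d.csv --out bodytemps.csv
nestwatch run --config pipeline.yaml --out results/         # full pipeline
```

`nestwatch run` writes stage outputs (behaviour table, centrality scores,
transition estimates, arm contrast, productivity predictions, a
centrality-by-temperature report table) plus a `manifest.json` recording the
seed, config hash and per-stage record counts. Runs are byte-identical under a
fixed seed.

Configuration is YAML over documented defaults (see
`nestwatch.pipeline_cli.DEFAULT_CONFIG`); unknown keys are rejected before any
stage runs.

## Data formats

CSV for tabular data (detections, behaviour records, probe logs, censuses),
JSON for nest maps, warp models and PCA models, multipage TIFF (+ JSON
sidecar) for thermal stacks, YAML for pipeline configuration. Pixel
coordinates are 0-based with the origin at the top-left; times are seconds
from video start.
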