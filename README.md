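# cafcd

Functional-connectivity dynamics analysis for single-cell calcium-imaging
recordings, plus a synthetic calcium-network simulator that provides ground
truth for every stage.

Given a fluorescence intensity matrix (active neurons × frames) and its
sampling period, the pipeline computes:

1. **Preprocessing** — per-neuron baseline subtraction (8th-percentile
   fluorescence) and amplitude-threshold event detection (40% of the trace
   maximum) with half-width kinetics.
2. **Static topology** — whole-recording Pearson FC matrix, functional graph
   thresholded at |r| > 0.4, and degree-distribution fits (Poisson, Binomial,
   power law via log10–log10 regression of degree frequency).
3. **Dynamic FC** — sliding-window FC series (default width 70 frames,
   step 1) and the window × window FCD correlation matrix.
4. **Meta-states** — per-network FastICA into four correlation patterns,
   per-window regression weights, and signed-quartile discretization into
   meta-state 4-tuples with codes in ±(1..4).
5. **FC variables** — nine per-network dynamics statistics (visited
   meta-states, change points, dwell times, Manhattan-distance travel and
   range, hub statistics).
6. **Group statistics** — linear mixed model with a random intercept per cell
   line, Wald Z on the diagnosis effect, and deviance-based selection of
   neuron-count covariates.

The synthetic-data module simulates recordings with planted switching
connectivity states, assembly co-activation, difference-of-exponentials
calcium transients, and a structural graph whose degree frequencies follow a
truncated discrete power law — everything needed for end-to-end recovery
tests without external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (window bookkeeping,
time conversions, power-law recovery, oracle equivalence, planted-state
recovery, statistical calibration, window-width sensitivity).

## CLI

All stages are exposed as subcommands of `cafcd`:

```sh
cafcd simulate  --config sims.yaml --out simdir/       # synthetic networks
cafcd events    --input net.tsv --out events.tsv       # transient detection
cafcd topology  --input net.tsv --out topo.tsv --cutoff 0.4 --bins 11
cafcd dfc       --input net.tsv --out dfc.h5 --width 70 --width 100
cafcd metastates --input net.tsv --out ms.h5 --components 4 --seed 0
cafcd variables --input net.tsv --out outdir/ --width 70
cafcd compare   --table outdir/variables_w70.tsv --variable n_visited_ms --out stats.tsv
cafcd run       --config run.yaml --out outdir/        # all-in-one
```

A `run` config lists simulated networks (or `input_paths`) plus options:

```yaml
# run.yaml
simulate:
  - {n_neurons: 30, n_frames: 1877, n_states: 2, seed: 1,
     network_id: net1, plate_id: p1, cell_line_id: lineA, diagnosis: HC}
  - {n_neurons: 40, n_frames: 1877, n_states: 2, seed: 2,
     network_id: net2, plate_id: p1, cell_line_id: lineB, diagnosis: SZ}
window_widths: [70, 100, 200]
fc_cutoff: 0.4
baseline_quantile: 0.08
ica_seed: 0
```

Exit codes: 2 configuration error, 3 data error, 4 ICA non-convergence,
1 otherwise.

## Conventions

- Windowed FC vectors hold the strictly-lower-triangle entries in pair order
  (i, j), i > j, lexicographic by (j, i) (tag `lower-colmajor-v1`).
- ICA sign indeterminacy is fixed so each pattern's weight series has
  nonnegative skewness; all count/distance variables are invariant to global
  sign flips regardless.
- Negative weights are ranked by ascending magnitude into codes −1..−4;
  quartile boundary ties resolve to the lower quartile; exact zeros map
  to +1 (logged).
- Time conversions use the sampling period (default 0.1506 s per frame).
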