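# entrainalyze

Analyses of single-neuron entrainment to isochronous visual stimuli in an
oddball-detection task, packaged as a reusable pipeline with a fully
synthetic data generator so every stage is testable offline:

- **core_io** — session data model (trials, spikes, eye traces), plain-text
  CSV/JSON session containers, trial filtering (correct trials, fixation
  > 1500 ms) and event-aligned 1 ms rasters.
- **synthetic_data** — task-structured trial generator, deterministic rate
  profiles (striatal increase/decrease transients peaking ~160 ms after
  each stimulus; cerebellar-nucleus-like troughs at ~200 ms whose linear
  recovery scales with the inter-stimulus interval), inhomogeneous Poisson
  spiking, saccade latencies with controllable rate covariation, and 1 kHz
  eye traces. Fully deterministic under a seed.
- **spike_density** — Gaussian-kernel spike density (σ = 30 ms default),
  firing modulation (max − min), sliding 100 ms window rate extrema,
  per-stimulus series, population averages with 95% CIs.
- **response_profile** — increase/decrease classification, missing-vs-
  deviant condition contrast (ratio, paired t), contra-vs-ipsi direction
  bias (through-origin slope), ISI duration tuning with long/short labels.
- **timing_decoder** — threshold-crossing decoder of next-stimulus timing:
  trough/peak normalization, 1% threshold grid search minimizing Σ Δt²
  across ISIs 300/400/600 ms, neuron-resampling bootstrap CIs.
- **latency_variation** — latency sextile splits, normalized group
  population traces, one-way ANOVA at every millisecond, onset/offset
  detection with a >100 ms consistency-run rule, neuron bootstrap.
- **behavior** — saccade detection from eye velocity (60°/s criterion),
  microstimulation latency tables (rank-sum, paired t, F-tests) and the
  condition × direction two-way ANOVA on latency-change scores.

## CLI

```bash
entrainalyze simulate --config sim.yaml --out pop/ --seed 7   # synthetic population + manifest
entrainalyze validate pop/                                    # check session containers
entrainalyze filter pop/sim-000 --min-fixation 1500 --out filtered/
entrainalyze density pop/ --align oddball --window -1600 200 --sigma 30 --out trace.csv
entrainalyze tune pop/ --out tuning.csv
entrainalyze decode pop/ --isis 300 400 600 --boot 1000 --seed 7 --out decoder.json
entrainalyze variation pop/ --boot 1000 --seed 7 --out variation.json
entrainalyze behavior stim_sessions/ --out behavior.json
```

A session container is a directory with `trials.csv`, `spikes.csv`,
optional `eye.csv` and `meta.json` (see `entrainalyze/core_io.py` for the
exact columns). All times are integer milliseconds, trial clock zero at
the first stimulus onset, half-open `[start, end)` windows.

## Layout

```
src/entrainalyze/    package modules (one per pipeline stage)
tests/               pytest suite; test_acceptance.py holds the
                     acceptance criteria at their stated tolerances
scripts/acceptance.py  end-to-end acceptance report
```
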