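# fretkin

Simulation and kinetic analysis of single-molecule FRET (smFRET)
trajectories of protein-filament assembly dynamics at a DNA strand.

The package pairs a ground-truth stochastic generator with the full
inference chain used to analyze such experiments:

* **`fretkin.simulate`** — continuous-time Markov (Gillespie) simulation of
  two kinetic schemes, rendered into donor/acceptor intensity traces with
  exact time-weighted frame integration, Gaussian detection noise and
  acceptor photobleaching:
  * *nucleation*: two states, `unbound` (E ≈ 0.7) ↔ `nucleated` (E ≈ 0.2),
    the multimeric cluster binding/unbinding as one atomic step;
  * *end dynamics*: monomer occupancy chain `M0 ↔ M1 ↔ M2`
    (E ≈ 0.7/0.5/0.3), binding steps scaled by protein concentration.
* **`fretkin.fret`** — proximity-ratio FRET efficiency, per-molecule
  histograms (mean of the first 10 frames), Gaussian-mixture fits with an
  optional donor-only zero peak.
* **`fretkin.hmm`** — pooled Baum–Welch training of a Gaussian-emission
  HMM (vectorized across traces), per-trace Viterbi idealization,
  photobleach (dark-state) truncation.
* **`fretkin.kinetics`** — dwell-time sets with censoring, exponential
  lifetime fits, nucleation frequency, transition density plots (TDP),
  binding/dissociation rate constants from transition counts over
  occupancy time, and the net growth rate
  `k_growth = k_on × [protein] − k_off`.
* **`fretkin.report`** — end-to-end pipeline over multiple sequence
  conditions plus cross-condition correlation summaries (R², linear fit),
  with a deterministic run manifest.

## CLI

```sh
# generate traces (see tests/test_cli.py for config examples)
fretkin simulate --config sim.yaml --out data/ --mode end-dynamics

# per-molecule histogram + mixture fit
fretkin histogram --in data/traces.csv --out hist/ --components 3 --zero-peak

# HMM idealization
fretkin idealize --in data/traces.csv --states 3 --model model.json --out ideal.csv

# kinetic rates (condition CSV: label,reca_uM,atpase_rate)
fretkin rates --in ideal.csv --condition conditions.csv --out rates.json
fretkin nucleation --in ideal.csv --out nucleation.json

# correlations and the full demo pipeline
fretkin correlate --table rates_table.csv --x atpase_rate --y k_off
fretkin run --out results/            # built-in 5-condition demo
fretkin run --config my.yaml --out results/ --seed 7
```

Trace CSVs carry `trace_id,time_s,donor,acceptor`; idealized CSVs carry
`trace_id,state,start_s,duration_s,mean_e`.

## Reproducibility

Every simulation is driven by one experiment seed; each trace uses an
independent substream derived from `(seed, trace_index)`, so any subset of
molecules regenerates bit-identically. `fretkin run` writes a manifest
(config snapshot, seed, version, output checksums) and its outputs are
byte-identical on rerun.
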