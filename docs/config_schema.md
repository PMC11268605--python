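# JSON configuration reference

`nervesim run <config.json> --out <dir>` (or
`nervesim.configio.run_config`) executes the task named by the
top-level `task` key.  Every run writes `summary.json` embedding the
package version, the SHA-256 hash of the canonicalized config, and the
seed.  Unknown tasks and missing required keys raise a config error
naming the offending keys.

Common building blocks:

```jsonc
// material: preset name or explicit tensor
"material": "endoneurium"
"material": {"sigma": 0.2}                        // isotropic
"material": {"sigma_xx": 0.57, "sigma_yy": 0.085, "sigma_zz": 0.085}

// stimulus: explicit event list or generator
"stimulus": {"times": [0, 0.1], "values": [-50, 0], "interpolation": "hold"}
"stimulus": {"kind": "pulse", "start": 0.1, "amplitude": -50, "duration": 0.1,
             "shape": "monophasic"}
"stimulus": {"kind": "sine", "start": 3.0, "freq": 4.0,
             "amplitude_pp": 800.0, "duration": 20.0}

// fiber
"fiber": {"type": "myelinated", "diameter": 10.0, "n_nodes": 51}
"fiber": {"type": "unmyelinated", "diameter": 1.0, "length": 5000.0}

// sim
"sim": {"dt": 0.001, "t_sim": 15.0, "record_gates": true}
```

## Tasks

`simulate-axon` — one fiber with optional `context`
(material + `sources`: electrode/stimulus pairs) and `clamps`
(kind/compartment/stimulus); traces are written as `axon/header.json`
plus CSV files, optionally downsampled via `output_downsample`.

`pack` — generate (`population`: n, myelinated_fraction, per-type
stats) and pack a population; writes `population.csv` (columns
type, diameter_um, y_um, z_um) and reports the fitted radius.

`simulate-fascicle` — a packed population (inline spec or
`population.csv` path), broadcast `clamps`, optional `context` and
`recorder` (material/method/points); reports recruitment and writes
`ecap.csv` (time, one column per recording point) when a recorder is
attached.

`threshold` — activation threshold of one fiber for a cathodic pulse
(`pulse.duration`, `electrode`, `material`, optional `search` bounds
and tolerance).

`block-threshold` — kilohertz block threshold
(`diameter`, `freq_khz`, `distance_um`, optional `search`).

`recruit` — recruitment curve of a population over `amplitudes`;
writes `recruitment.csv` and reports the 0.2–0.8-band rate.

`ecap` — simulate-fascicle plus an amplitude–latency fit of the
recorded eCAP.

`optimize` — particle-swarm waveform optimization on one fiber:
`parameterization` ({"kind": "square" | "spline_N", t_start, t_end}),
`bounds` ([lower, upper] vectors), `cost` (alpha_e, alpha_r),
`n_particles`, `n_iterations`, `seed`; writes `optimization.jsonl`
(iteration, best, mean).
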