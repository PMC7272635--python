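# spheropore

Finite-element simulation of electroporation in prolate-spheroidal cells,
with the downstream analyses used to study how cell **orientation** relative
to the applied field changes the electroporation outcome:

- transient membrane charging of a spheroidal cell in a uniform pulsed
  field (P1 tetrahedral FEM, contact-impedance membrane boundary
  condition, backward-Euler time stepping);
- asymptotic pore-density dynamics on the membrane, two-way coupled to the
  field through the pore-dependent membrane conductivity;
- duration/orientation/aspect-ratio sweeps with amplitudes taken from a
  strength-duration (iso-effect) curve, pore-count ratios and the
  orientation **crossover duration** where parallel- and
  perpendicular-oriented cells porate equally;
- a synthetic ratiometric (340/380 nm) calcium-imaging experiment:
  rendered two-channel time-lapses, segmentation, moment-based ellipse
  fits, orientation classification, and Kruskal-Wallis/Dunn statistics.

Everything is deterministic for a fixed configuration and seed; no
simulation data ships with the package.

## Worked example: the orientation crossover

Short pulses porate cells oriented perpendicular to the field more (the
short semi-axis charges faster), long pulses porate parallel cells more
(the long semi-axis reaches higher steady-state voltage). With amplitudes
scaled along a strength-duration curve, the pore-count ratio crosses 1 at
a few microseconds:

```python
from spheropore.protocols import run_crossover_config

frame, report = run_crossover_config("A")   # 1:4 cell, hyperbolic curve
print(frame[["t_pulse_s", "orientation", "pore_count"]].head(4))
print("ratios:", report.ratios.round(3))
print(f"crossover at {report.t_crossover * 1e6:.2f} us, "
      f"bracket {report.bracket}")
```

Output (about 20 s on one CPU at the default 5 µm mesh resolution):

```
   t_pulse_s    orientation    pore_count
0   0.000001       parallel  2.804339e+05
1   0.000001  perpendicular  1.068765e+06
2   0.000002       parallel  1.525007e+05
3   0.000002  perpendicular  3.784050e+05
ratios: [0.262 0.403 0.572 0.761 1.011 1.338 2.258 3.733]
crossover at 4.96 us, bracket (4e-06, 5e-06)
```

Configuration `"B"` (aspect 1:2, half-amplitude curve) crosses at 3.32 µs;
configuration `"C"` (aspect 1:2, full-amplitude curve) never crosses —
perpendicular cells dominate at every tested duration.

Lower-level entry points: `build_mesh` (geometry), `solve_transient` /
`run_coupled_pulse` (solver), `run_condition` / `sweep_durations` /
`find_crossover` / `onset_field` (sweeps), `generate_scene` /
`measure_scene` / `kruskal_dunn` (synthetic experiment and statistics).

## Command line

```sh
spheropore simulate  --config run.yaml --out-dir runs/sim      # one pulse
spheropore sweep     --config run.yaml --out-dir runs/sweep    # duration sweep
spheropore crossover runs/sweep/sweep.csv --out-dir runs/x     # locate crossover
spheropore synth     --config run.yaml --out-dir runs/synth    # render a scene
spheropore analyze   --config run.yaml --out-dir runs/exp      # full synthetic study
```

Every command writes a `manifest.json` (resolved config, package version,
seed, mesh hash, timings, outputs) beside its results; re-running a
manifest's configuration reproduces the outputs byte-for-byte.

A config file is YAML with optional sections `material`, `geometry`,
`pulse`, `sweep`, `synth` and a master `seed`; all keys fall back to
defaults (90 µm cell, aspect ratio 4, 400 µm box, 5 µm resolution,
hyperbolic dose curve). Example:

```yaml
geometry: {aspect_ratio: 2.0, resolution_um: 5.0}
pulse:    {curve: hyperbolic, scale_factor: 0.5}
sweep:    {durations_s: [1e-6, 2e-6, 3e-6, 4e-6, 5e-6, 6e-6, 8e-6, 1e-5]}
seed: 42
```

## Acceptance targets

`scripts/acceptance.py` recomputes the six headline numbers from scratch
and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Repository layout

| Path | Contents |
| --- | --- |
| `src/spheropore/params.py` | material/membrane parameters, pore conductivity |
| `src/spheropore/geometry.py` | spheroid-in-box octant mesh, membrane pairing |
| `src/spheropore/solver.py` | transient FEM solver, coupled pulse runner |
| `src/spheropore/pores.py` | asymptotic pore ODE, exponential integrator |
| `src/spheropore/pulses.py` | pulse shapes, strength-duration curves, field grid |
| `src/spheropore/sweep.py` | condition runner, crossover and onset analysis |
| `src/spheropore/protocols.py` | named study configurations (A/B/C, extremes, onsets) |
| `src/spheropore/synthexp.py` | synthetic imaging experiment + analysis pipeline |
| `src/spheropore/stats.py` | Kruskal-Wallis + Dunn vs control |
| `src/spheropore/config.py`, `cli.py` | YAML configs, manifests, CLI |
| `docs/methods.md` | model equations, numerical methods, design choices |

See `docs/methods.md` for the governing equations, discretisation,
verification oracles and known limitations.
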