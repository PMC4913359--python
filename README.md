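# clpsim — a closed-loop perception simulator

`clpsim` simulates *closed-loop perception*: the idea that perceiving an
external feature is not a feed-forward read-out but the convergence of a
motor-sensory-motor (MSM) loop — a dynamical system spanning the motor
plant, the physical world and the brain — onto an attractor that is
uniquely associated with that feature.  The package is aimed at
computational neuroscientists and roboticists who want a small, fully
reproducible test bed for active-sensing dynamics: every experiment is one
JSON config, every result a CSV/JSON file.

## The model

A camera-like event sensor rides on a 1-D pan axis in front of a luminance
field containing a single contrast edge (Michelson contrast
γ = (L_bright − L_dark)/(L_bright + L_dark)).  Each pixel emits an ON/OFF
event whenever its luminance changes by one threshold quantum, so sweeping
the edge at angular velocity ω yields the sensory contingency

    r_on − r_off = C₁ γ ω ,       C₁ = 2·L̄ / (threshold · pixel pitch).

The loop is closed by one neuronal and one motor equation,

    ṅ₁ = C₂ (r_on − r_off)
    ω̇  = μ (1 − C₄ n₁²) ω − n₁ / C₃ ,

which, after the rescaling x = √C₄·n₁, is exactly a Van der Pol oscillator
with small-signal frequency ω₀ = √(C₁C₂γ/C₃).  For any γ > 0 the loop
therefore converges to a unique limit cycle — independently of initial
conditions — whose period and amplitudes encode the contrast:

    period ≈ 2π √(C₃/(C₁C₂γ)),   |n₁| ≈ 2/√C₄,   |ω| ≈ 2/(√C₄ √(C₁C₂C₃γ)).

On top of the loop the package provides: a contrast decoder (inverting the
period, with simulation-matched refinement), a convergence-confidence
signal C_j with a decision threshold C_d, perceptual-time "ticks"
(completed loop cycles), open-loop ablation by motor replay, and
smooth-pursuit dwell detection for moving edges.

## Worked example

```python
import clpsim as cs

params = cs.LoopParams()
scene = cs.make_edge_scene(gamma=0.9, mean_luminance=0.5)
traj = cs.run_sensor(scene, params, cs.SensorConfig(), cs.EngineConfig(duration=30.0))

summary, percept = cs.analyze(traj, params)
print(f"converged:        {summary.converged}")
print(f"cycle period:     {summary.period:.3f} s")
print(f"decoded contrast: {percept.gamma_hat:.3f}   (true: 0.9)")
print(f"decision time:    {percept.decision_time:.2f} s  (C_d = 0.9)")
print(f"perceptual ticks: {percept.ticks}")
```

prints

```
converged:        True
cycle period:     0.890 s
decoded contrast: 0.884   (true: 0.9)
decision time:    4.59 s  (C_d = 0.9)
perceptual ticks: 33
```

The loop facing a 0.9-contrast edge settles on a 0.89 s cycle; inverting
the period recovers the contrast to within 2% even though the loop only
ever saw threshold-quantised ON/OFF events.  Confidence crossed the 0.9
decision threshold after 4.6 s, i.e. after about five perceptual ticks.

The same pipeline is available from the shell:

```bash
clpsim fixtures --out fixtures
clpsim simulate --config fixtures/static_edge_gamma09.json --out traj.csv
clpsim analyze  --traj traj.csv --out report.json
clpsim sweep    --config fixtures/static_edge_gamma05.json --mode sensor --out sweep.csv
clpsim pursuit  --config fixtures/moving_edge_pursuit.json --out dwells.csv
```

## Layout

| module | contents |
| --- | --- |
| `clpsim.scene` | luminance fields: contrast edge, drift / triangle-wave motion, periodic or bounded wrap |
| `clpsim.sensor` | event camera: per-pixel threshold crossings, event batches, rates |
| `clpsim.dynamics` | loop equations, general f/g/h composition, Van der Pol analytics |
| `clpsim.engine` | closed-loop integration: ideal / sensor / replay modes, trajectories |
| `clpsim.percept` | limit-cycle detection, contrast decoding, confidence, ticks, pursuit |
| `clpsim.config`, `clpsim.fixtures`, `clpsim.cli` | JSON configs, canned experiments, command line |

See `docs/methods.md` for the modelling choices and their rationale.
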