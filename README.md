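# ephmap

Agent-based simulation of retinotopic map formation driven by ephrin-A/EphA
forward and reverse signaling, with **co-adaptation** of the two guidance
sensors, plus the matching **gap-assay image quantifier**.

Growth-cone terminals are circular discs carrying Gaussian-shaped sensor
distributions (EphA receptors `R_F`, ephrin-A ligands `L_F`). Each terminal
performs a biased random walk on a rectangular target field, minimizing a
guidance potential

```
D = | ln( Σ L_F(x) [R_T(x) + R_F(x) + C(i) R_f(x)]
        / Σ R_F(x) [L_T(x) + L_F(x) + C(i) L_f(x)] ) |
```

(total reverse over total forward signaling, summed over the footprint;
`R_T/L_T` target cues, `R_f/L_f` other fibers weighted by `C(i)`). A common
adaptation coefficient `a(i) = 1 + ln(1 + μ · weighted-mean of recent D)`
multiplies *both* sensors each iteration while a Hookian resetting force
`λ(S(0) − S)` pulls them back — so the ratio `R_F/L_F`, the terminal's
topographic identity, is preserved exactly. A canonical (per-channel)
adaptation variant is included for contrast; it destroys the map.

## What's inside

| module | contents |
|---|---|
| `ephmap.gradients` | cue gradient specs, target fields, retinal sensor baselines |
| `ephmap.model` | guidance potential, adaptation dynamics, biased walk, vectorized engine |
| `ephmap.scenarios` | builders: mapping, gap assays, tectal entry, EphA knock-in, expansion/compression/mismatch/reversal |
| `ephmap.metrics` | topography (Spearman ρ, diagonal fraction, span), stopping/entry fractions, knock-in displacement |
| `ephmap.imaging` | gap-assay fiber counting (threshold → two ROIs → peaks per pixel line → % stopping) + synthetic image generator |
| `ephmap.cli` | `ephmap` command-line tool |

## CLI

```bash
ephmap list-scenarios                       # bundled per-figure configs
ephmap simulate --config fig4b_coadapt --seed 1 --out out/
ephmap simulate --config my_scenario.yaml   # your own YAML
ephmap reproduce fig4c --out figures/       # gap assays 20/40/100 + naive
ephmap quantify-gap image.png --gap-far-edge 200 --roi-width 20
```

A scenario config is either a builder call

```yaml
builder: gap_assay
args: {first_cue: ephrin, second_cue: Eph, gap: 20, seed: 1}
params: {beta: 3.5}        # any ModelParams override
```

or a full structural dump (`Scenario.to_dict()`), and every run writes a
tidy CSV (iteration, terminal, position, sensors, D), a metrics JSON, a
plot, and a manifest sufficient to reproduce the run bit-identically.

## Python API

```python
import ephmap as em

scn = em.mapping_scenario(n=200, adaptation_mode="coadaptation", seed=1)
res = em.simulate(scn)
summary = em.mapping_summary(res)      # rank_correlation, diagonal_fraction, ...
```

Default parameters: μ=0.006, λ=0.0045, h=10, n=200, i=30000; fiber–fiber
weight C(i) ramps from 0 to C0 after onset j (constant C0 with the ramp
off); cue-free squares carry a forward walk bias q_x=0.37. The move rule,
gradient constants and ramp shape are calibrated stand-ins and are all
exposed through `ModelParams` / builder arguments.

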