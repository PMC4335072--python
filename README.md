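# cellregen

Simulator for regeneration of lattice cell structures driven by signal
memory.

Cells sit on the nodes of a 2D square grid and emit a signal that decays
with Euclidean distance, either polynomially (`d^-n`) or exponentially
(`e^-nd`). Each cell receives the summed signal of all others; that
received-signal distribution encodes the geometry of the structure. After a
part of the structure is amputated, the surviving ("control") cells remember
their pre-amputation signal `u*` while measuring the diminished current
signal `u(t)`. A greedy algorithm then places one new cell per time step —
adjacent to the wound edge (blastema) or to earlier new cells, never pushing
any remembered signal above `u*` beyond a relative tolerance ε — choosing
the site that either adds the most signal to the measured cells (rule 3a) or
receives the most deficit-weighted signal from them (rule 3b). Within the
model's validity range the original shape is restored exactly, cell for
cell; outside it the run reports where and how it failed.

The package also includes the analytic companions used as oracles: exact
restoration of a single removed cell by circle intersection, and the
closed-form steady state `u(x) = (1 + c x)^(-2/k)` of the nonlinear
diffusion problem `(u^-k u')' - b u = 0`, which motivates the polynomial
kernels.

## Layout

| Module | Contents |
| --- | --- |
| `cellregen.structures` | lattice `CellStructure`, shape generators (rectangle, ellipse, letter glyphs), amputation + blastema, CSV/JSON serialization |
| `cellregen.signals` | `Kernel` families, received-signal fields `u`, `u*`, `u(t)`, deficit signal `z` |
| `cellregen.engine` | the greedy regeneration loop (rules 3a/3b, admissibility, violation detection), organizer-driven morphogenesis |
| `cellregen.analytic` | circle-intersection restoration, nonlinear-diffusion closed form + ODE residual |
| `cellregen.specio` / `cellregen.render` / `cellregen.cli` | run-spec YAML/JSON, PNG rendering, command-line interface |

A note on numerics: every field value and candidate score is a correctly
rounded, order-independent sum (`math.fsum` over cached scalar kernel
values), so runs are bit-reproducible and an independent naive
reimplementation (`tests/_oracle.py`) matches the engine's step-by-step
choices exactly, ties included.

## CLI

```sh
# full regeneration run from a spec file (trace CSV, final CSV, PNG)
cellregen simulate examples/rect.yaml --rule 3b --epsilon 1e-14

# organizing-center growth towards the spec's shape
cellregen morphogenesis examples/rect.yaml

# closed-form printouts
cellregen analytic diffusion --k 1 --b 1 --x 1
cellregen analytic restore --control 0,0 --control 2,0 \
    --distance 1.4142135623730951 --distance 1.4142135623730951

# parameter scan: status per kernel exponent
cellregen sweep examples/rect.yaml --param n --values 1,1.6,2,2.4

# re-render a saved structure CSV
cellregen render out/final.csv out/final.png
```

A minimal spec file:

```yaml
shape: {kind: rectangle, width: 12, height: 8}
amputation: {kind: half_plane, axis: y, op: ge, value: 4}
kernel: {family: polynomial, n: 2.0}
config: {rule: 3b, epsilon: 1.0e-14}
output_dir: out
```

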