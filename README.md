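# ngnmm

Next-generation neural mass modelling of whole-brain dynamics: a simulator
and analysis library for networks of exact mean-field E–I neural masses —
derived from quadratic integrate-and-fire (QIF) populations with
conductance-based chemical synapses and gap junctions — coupled through a
structural connectome with conduction delays, together with linear
stability / eigenmode analysis and MEG/BOLD functional-connectivity (FC)
observables.

## What is in the box

| Module | Purpose |
| --- | --- |
| `ngnmm.connectome` | Load/save/validate weighted connectomes with tract distances, row normalisation, delay computation, synthetic two-hemisphere generator |
| `ngnmm.model` | The 12-dimensional E–I mean-field node (rates, voltages, second-order synaptic filters), network right-hand side with per-edge delayed filters, Kuramoto order-parameter maps |
| `ngnmm.dde` | Adaptive embedded Runge–Kutta 3(2) integrator for delay differential equations with cubic Hermite dense output, sparse delayed-state recording and history pruning |
| `ngnmm.qif` | Microscopic QIF population simulator (the independent check of the mean-field reduction) |
| `ngnmm.stability` | Uniform steady states, mode-reduced spectral eigenvalue equations with delays, dense Jacobian oracle, Hopf-point location, structural/Jacobian eigenmode FC proxies and iterative eigenmode fitting |
| `ngnmm.fc` | Cross-spectral densities, GIM/MIM/PLV, band filtering, Balloon–Windkessel BOLD forward model, sliding-window and Hilbert-phase dynamic FC, Pearson distance, structure–function clustering coefficient, across-band FC diversity |
| `ngnmm.pipeline` / `ngnmm.cli` | Configured end-to-end runs with manifests, and the `ngnmm` command-line workbench |

## Quick start

```python
import numpy as np
from ngnmm import (
    NetworkParameters, generate_synthetic_connectome, row_normalize,
)
from ngnmm.pipeline import simulate_network
from ngnmm.fc import get_band, meg_fc

conn = row_normalize(generate_synthetic_connectome(16, seed=0))
t, sig, stats = simulate_network(conn, net=NetworkParameters(k_ext=0.2),
                                 duration=30.0, transient=4.0)
fc = meg_fc(sig, 600.0, get_band("alpha"))
```

Command line:

```sh
ngnmm synth-connectome --n-regions 16 --out conn/
ngnmm stability --weights conn/weights.csv --distances conn/distances.csv --k-ext 0.02
ngnmm simulate --config src/ngnmm/data/near-hopf.toml --out run/
ngnmm qif-oracle --neurons 10000 --duration 2.0 --out qif/
```

Exit codes: 0 success, 2 validation error, 3 numerical failure.

Two example configurations ship with the package
(`src/ngnmm/data/near-hopf.toml`, `src/ngnmm/data/nonlinear.toml`): the
weakly coupled regime near the network Hopf bifurcation, and the strongly
coupled nonlinear regime in which no uniform steady state exists and FC
becomes band-specific.

## Verification

`tests/` contains unit and property tests for every module plus
`tests/test_acceptance.py`, one test per acceptance criterion (printed
model counts; microscopic-vs-mean-field oracle; spectral-vs-dense Jacobian
and Hopf/simulation consistency; solver order and interpolation checks;
metric identities; qualitative regime comparisons). The same quantities
can be exported as JSON:

```sh
python scripts/acceptance.py --seed 0 --out results/acceptance.json
```

Numerical methods, conventions and the reasoning behind the non-obvious
choices are documented in `docs/methods.md`.
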