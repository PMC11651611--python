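# Methods and numerical conventions

This note records the mathematical conventions, numerical methods, and the
reasoning behind the package's non-obvious choices. Symbols follow the code:
each region holds an excitatory (E) and an inhibitory (I) population with
rates `R_a`, voltages `V_a`, and second-order synaptic filter pairs
`(g_ab, s_ab)`; regions are coupled E-to-E through a row-normalised weight
matrix with per-edge conduction delays `T_ij = d_ij / speed` and per-edge
long-range filter pairs `(g_ij, s_ij)` with rate `alpha_net`.

## Model

### Local node (12 equations)

Each population obeys the exact mean-field reduction of a heterogeneous QIF
population (Lorentzian-distributed background drives, all-to-all coupling):

    tau_a dR_a/dt = Delta_a/(pi tau_a) + 2 R_a V_a - R_a (sum_b g_ab + sum_b kappa_v^ab)
    tau_a dV_a/dt = eta0_a + V_a^2 - (pi tau_a R_a)^2
                    + sum_b g_ab (v_syn^ab - V_a) + sum_b kappa_v^ab (V_b - V_a)
                    + long-range input (E only)

with four synaptic filter pairs per region,
`(1 + alpha_ab^{-1} d/dt)^2 g_ab = kappa_s^ab R_b`. Gap junctions enter
through `kappa_v^ab`; within-population gap terms cancel in `V` but damp `R`.

### Long-range coupling and the two input conventions

Each directed edge carries `(1 + alpha_net^{-1} d/dt)^2 g_ij
= k_ext w_ij R_E^j(t - T_ij)`. The summed edge conductance `G_i` drives the
target's excitatory voltage either as a conductance-based (shunted) current
`G_i (v_syn_net - V_E^i)` — the simulation default — or as the non-shunted
current `G_i v_syn_net`, which is the convention under which the linear
stability analysis is exact; `NetworkParameters.shunting_network_input`
selects between them. Results that compare linear predictions against
simulations use the non-shunted convention in both.

### Microscopic oracle

`ngnmm.qif` simulates the corresponding finite network of P QIF neurons
(Euler stepping, finite threshold ±100 with spike-transit correction and a
refractory hold of `2 tau / v_threshold`). Two deliberate deviations from
the idealised model are documented because they matter quantitatively:

- **Drive truncation.** Lorentzian drives are truncated at
  `|eta - eta0| <= v_threshold^2`. The removed tail carries rate mass
  `~ Delta/(pi^2 tau) * 2/sqrt(cutoff)` (2.0% of the uncoupled fixed-point
  rate at the defaults); beyond `eta ~ v_threshold^2` the finite-threshold
  scheme misrepresents single-neuron rates anyway, so a larger cutoff buys
  no additional fidelity.
- **Stratified sampling.** One drive is drawn per equal-probability stratum
  of the truncated Lorentzian (assignment shuffled). This is an unbiased,
  seed-reproducible sample whose population rate does not hinge on the
  lottery of a handful of rare fast-firing tail neurons; with iid draws
  those neurons alone contribute several percent of seed-to-seed scatter
  at P = 10^4.

With both in place the time-averaged population rate and voltage of an
uncoupled population at P = 10^4 reproduce the closed-form fixed point to
within ~2–3%.

## DDE integration

The integrator is an embedded Bogacki–Shampine 3(2) pair (FSAL) with
predictive proportional-integral step control (Gustafsson), cubic Hermite
dense output, and a history buffer storing only the components that are
actually looked up with delay (the per-node `R_E`), pruned to the maximum
lag. Because the step is capped at the smallest positive lag, all three
stage lookups of a step attempt lie at or before the current time and are
served by one batched history evaluation, which matters at desk scale
where per-call overhead dominates. Two details are load-bearing:

- **A duplicate knot at t0.** With a constant history the state is
  continuous at t0 but its derivative is not. The first accepted segment
  therefore appends a second knot at t0 carrying the right-side slope;
  without it, delayed lookups in the first lag interpolate with the wrong
  slope and the global order degrades from 3 to 2.
- **Pruning is bitwise-invariant.** Dropping history knots strictly older
  than the horizon never changes which polynomial piece a lookup uses, so
  trajectories with and without pruning are identical to the last bit —
  asserted in the tests.

Verification: the benchmark `y' = -y(t) - y(t-1)` (known method-of-steps
solution) shows order ≥ 2.8 across a 4-point step-halving ladder; the pure
delay benchmark `y' = -y(t-1)` with piecewise-polynomial solution is
reproduced to round-off when steps align with the breakpoints; the Hermite
interpolant is exact on cubics and (deliberately checked) not on quartics.

## Steady states and linear stability

Uniform steady states are found by parameter continuation from the
uncoupled closed form with damped Newton stages. Past `k_ext ~ 0.32`
(shunted convention) the uniform branch folds and no uniform steady state
exists; `simulate_network` then initialises from the zero-coupling
equilibrium and discards the transient (logged).

The linearisation block-diagonalises in the eigenbasis of the structural
matrix: for each structural eigenvalue `nu_mu` the spectral equation
`det(lambda I - Df - gamma_mu(lambda) K) = 0` is solved by Newton's method
from a grid of seeds, where `gamma_mu(lambda)` folds the squared low-pass
filter and the delay distribution, and `K` is the single-entry long-range
drive matrix. The zero-delay cross-validation against a dense
finite-difference Jacobian of the full `(12 + 2 per edge) x N` system is
exact to ~5e-10 with two caveats that are mathematical, not implementation,
facts:

- the dense Jacobian has *defective* (Jordan) eigenvalue clusters at the
  synaptic filter rates, whose eigenvalues are conditioned like the square
  root of the perturbation — a 1e-9 Jacobian difference moves them by
  ~1e-6, so no comparison at those points can be tighter;
- the dense system carries unobservable edge-filter modes pinned exactly
  at `-alpha_net` which the mode-reduced equations provably do not contain.

Comparisons therefore exclude eigenvalues within 1e-2 of a filter rate and
match everything else bijectively to 1e-6.

Hopf points are located by bisection on the sign of the rightmost root's
real part; consistency is confirmed by simulating on either side of the
crossing (decay/growth of the perturbation RMS between two fixed windows)
and comparing the oscillation frequency against `Im(lambda)/2pi`.

## Functional connectivity

Cross-spectra use Welch's method (1 s Hann windows, 50% overlap). GIM and
MIM follow the standard imaginary-coherence constructions; the GIM
denominator `c_AA c_BB - (c^R)^2` is floored at `max((c^I)^2, eps^2)` —
by Cauchy–Schwarz the true denominator never falls below `(c^I)^2`, so
this floor enforces `GIM <= 1` instead of letting phase-locked bins blow
up. Band filtering is a 4th-order Butterworth applied forward-backward.
The BOLD forward model is the Balloon–Windkessel system integrated with
RK4 substeps from its resting state `(0, 1, 1, 1)`; its constant-drive
steady state has the closed form `f = 1 + S/gamma`, `v = f^alpha`,
`q = v (1 - (1-rho)^{1/f})/rho`, used as an oracle.

**Across-band FC diversity** (`band_fc_diversity`) is the power-weighted
mean pairwise Pearson distance between the 8 band-wise FC matrices, each
band pair weighted by the product of the bands' shares of node-averaged
spectral power. The weighting is part of the definition: a
coherence-normalised metric carries no information in a band the signal
does not occupy (its value there reflects the numerical noise floor), and
a single narrowband rhythm should — and with this definition does — score
low across-band diversity, while broadband dynamics with band-specific
patterns score high.

## Problem sizes for the qualitative comparisons

The regime comparisons (default vs stronger coupling; gap junctions
present vs absent) run at desk scale as package choices: 12-region
synthetic connectomes, 60 s simulated per run (a 12 s discarded
transient — the runs relax onto their attractors over roughly ten
seconds, and any remnant of that relaxation registers as spurious
temporal variability — followed by 48 s of analysed signal), output at
600 Hz, solver tolerances rtol = 3e-3 / atol = 1e-6 (the compared
quantities are attractor statistics rather than pointwise trajectories),
five seeds per comparison with each inequality evaluated on the
statistic averaged over the five seeds.

The gap-junction comparison runs at the default coupling strength and
measures, per frequency band, the standard deviation over sliding 10 s
windows (90% overlap) of the network-mean structure–function clustering
coefficient, then averages over all eight bands. Three choices are
load-bearing and were fixed from first principles, not from outcomes:

- **Window length.** Each 10 s window's cross-spectrum is estimated
  from 19 Welch segments; with much shorter windows the window-to-window
  spread of an imaginary-coherence FC estimate is dominated by estimator
  sampling noise — phase-randomised stationary surrogates of the same
  signals reproduce nearly the full measured spread — so the window must
  be long enough that the slow FC reorganisation under study, not the
  estimator, sets the variability.
- **No per-window rescaling of the FC layer.** GIM already lies in
  [0, 1]; min–max rescaling each window's FC matrix would erase global
  waxing and waning of FC strength, which is precisely the signal the
  comparison measures. The structural layer is min–max rescaled once.
- **Band averaging.** The compared effect is broadband, so the per-band
  window-stds are averaged over the whole band table, which also
  suppresses residual per-band estimator noise.

The effect itself is weak at this scale — single-seed comparisons go
either way, which is why the criterion is evaluated on the five-seed
average. All other tolerances and thresholds are stated at the point of
use in `tests/`.
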