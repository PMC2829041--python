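# Methods

## Model structure and assumptions

The model describes a fixed region of a cell's leading edge as a well-mixed
pool (or, in the spatial variant, a periodic chain of pools) of six species.
The design assumptions are:

* **Nascent adhesions are slaved to protrusion.** Their formation rate is
  `k_ecm · v`: protrusion exposes fresh substratum and delivers integrins,
  and the efficiency of engagement grows with ECM density through `k_ecm`
  (a monotone, not necessarily linear, function of ECM density — the model
  treats it as the control parameter directly). Turnover, `k_d,n · v · n`,
  is likewise convective: adhesions transit out of the lamellipodium as the
  edge advances.
* **Maturation converts nascent to stable adhesions one-for-one**
  (`k_a,s f(m) n`), reinforced by myosin through the linear gain
  `f(m) = 1 + E_s m`. Stable adhesions disassemble slowly (`k_d,s`) and
  their influence also fades convectively (`k_d,s C_s v s`, with `C_s = 10`
  fixed). Myosin relaxes toward the stable-adhesion density
  (`dm/dt = k_d,m (s − m)`, so `m = s` at steady state).
* **The signaling circuit is fast and carried by nascent adhesions.**
  `x ⊆ n` carries phosphorylated paxillin, recruiting the GIT1/βPIX/PAK
  module; `r` (active Rac, activated by βPIX in proportion to `x`) relaxes
  as `dr/dt = k_d,r (x − r)`; `p ⊆ x` carries Rac-activated PAK, which
  closes the loop by phosphorylating paxillin (`k_a,x (p + p₀)(n − x)`).
  A small basal phosphorylation activity `p₀` ignites the loop once
  adhesions exist.
* **Velocity is a derived, saturable readout**:
  `v = (r + v₀)/(1 + r + v₀)/g(s)` with `g(s) = 1 + I_n s`. `v` is
  dimensionless (fraction of the maximal velocity). The small basal drive
  `v₀` represents Rac-independent polymerization; it is required for the
  system to leave the all-zero state at all, because nascent-adhesion
  formation is proportional to `v` and the signaling species are subsets of
  `n`. With `I_n > 0`, `v` is capped at `1/g(s)`: only at low stable-adhesion
  density are appreciable velocities possible.
* **Subset-consistency couplings.** Because `x` and `p` label subsets of the
  nascent-adhesion pool, removal of a nascent adhesion removes its labels
  with it. The `λ x` and `λ p` loss terms (`λ = k_d,n v + k_a,s f(m)`), and
  the `k_d,x p` term (dephosphorylation of a PAK-bearing complex), keep the
  mean-field equations exactly equal to the expected drift of the discrete
  jump process and guarantee `p ≤ x ≤ n` along every trajectory. They are
  numerically small (about 1% of `k_d,x`).

Setting `E_s = 0` or `I_n = 0` removes the corresponding stable-adhesion
feedback entirely; the Rac/PAK positive feedback loop alone is sufficient
for bistability in an intermediate band of `k_ecm`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k_ecm` | 0.1 (varied 0.03–3) | min⁻¹ | ECM coupling of nascent-adhesion formation |
| `E_s` | 0 (varied 0–30) | – | myosin → maturation gain |
| `I_n` | 0 (varied 0–10) | – | stable-adhesion → protrusion inhibition gain |
| `C_s` | 10 | – | convective removal of stable adhesions |
| `k_d,n` | 0.05 | min⁻¹ | v-coupled nascent turnover coefficient |
| `k_a,s`, `k_d,s` | 0.01, 0.02 | min⁻¹ | maturation, stable-adhesion disassembly |
| `k_a,m`, `k_d,m` | 20, 2 | min⁻¹ | myosin recruitment/release (K_m = 10) |
| `k_a,x`, `k_d,x` | 40, 4 | min⁻¹ | paxillin (de)phosphorylation |
| `k_a,r`, `k_d,r` | 40, 4 | min⁻¹ | Rac activation/deactivation (K_r = 10) |
| `k_a,p`, `k_d,p` | 80, 4 | min⁻¹ | PAK activation/deactivation |
| `p₀` | 0.005 | – | basal paxillin phosphorylation |
| `v₀` | 0.01 | – | basal protrusion drive |
| `D_r` | 15 | µm²/min | active-Rac diffusion coefficient |

Anchored values: `k_d,r = 4.0 min⁻¹` (membrane lifetime of active Rac),
`D_r = 15 µm²/min = 0.25 µm²/s`, `C_s = 10`, `K_m = K_r = 10`. The remaining
rate constants are the package's base case, chosen once so that the
deterministic system reproduces the qualitative steady-state structure the
circuit is known for: with `E_s = I_n = 0` it is bistable in a band of
`k_ecm` around 0.1 min⁻¹ (monostable low at 0.03, monostable high at 0.3);
raising `E_s` first carries the bistable region out to arbitrarily large
`k_ecm` and eventually (E_s ≳ 15–20) leaves only the low-protrusion state;
raising `I_n` compresses the attainable velocities toward zero. The
signaling constants (4 min⁻¹ decay) put the circuit an order of magnitude
faster than the adhesion variables, which justifies the quasi-steady
reduction used in the phase-plane analysis.

## Deterministic analysis

* **Quasi-steady reduction.** With `m = s` and the fast subsystem at steady
  state, `r = x`, `p` follows from a rational expression in `(x, r)`, and
  the `x`-balance reduces to one scalar equation on `[0, n]`. All roots are
  isolated by a dense sign scan and polished with bracketed root finding
  (`brentq`, residual < 1e−10); the fast subsystem itself can be three-valued
  near the bistable regime, and every branch is reported with a stability
  label from the 3×3 fast Jacobian.
* **Fixed points** are found by multistart 2-D root finding in `(x, s)`
  space, where `n(x)` is smooth and single-valued (this avoids choosing a
  signaling branch). Starts are laid out geometrically up to
  `x ≤ 2 k_ecm/k_a,s + 1` and `s ≤ 2 k_ecm/k_d,s + 10`; duplicates are
  merged at 1e−5 relative tolerance and accepted at residual < 1e−9.
  Stability is judged on the reduced `(n, s)` Jacobian (central differences,
  quasi-steady fast variables, branch continuity by nearest `x`); the full
  6-variable system is cross-checked in the tests.
* **Nullclines** are sampled per `s`-row by the same scalar reduction, with
  the window in `s` set adaptively to 3× the largest s-nullcline value, and
  branch ids assigned by continuity.
* **ODE integration** uses LSODA at rtol 1e−8 / atol 1e−10; the output grid
  does not affect the solution. Degenerate input `k_ecm = 0` relaxes to the
  all-zero state.
* **Multiplicity maps** count fixed points per grid cell; cells with an even
  count (bifurcation boundaries) are flagged rather than rounded.

## Stochastic engines

Counts scale as `N = N* n`, `S = N* s`, `X = N* x`, `P = N* p`,
`M = K_m N* m`, `R = K_r N* r`; the amplified formation constants
`k_a,m = K_m k_d,m` and `k_a,r = K_r k_d,r` follow from the `K` ratios, and
time-averaged output is insensitive to `K_m, K_r` over 5–20. Each additive
term of the equations is one channel; nascent-adhesion removal is split over
the `(N−X, X−P, P)` sub-populations so that stoichiometries are fixed
integer vectors and `X ≤ N`, `P ≤ X` hold after every event. The summed
channel drift equals the count-scaled deterministic right-hand side exactly
(a tested identity).

The First Reaction Method redraws one exponential candidate per channel per
event (ties, a probability-zero event, resolve to the lowest channel index);
the Next Reaction Method keeps absolute candidate times and rescales
unexpired ones by propensity ratios. The Next Subvolume Method gives every
subvolume its own event clock and RNG stream; active Rac alone hops to each
neighbor at `D_r/L²` per direction with `L = sqrt(D_r/k_d,r) = 1.94 µm`, so
the hop frequency equals `k_d,r = 4 min⁻¹`. A single-subvolume lattice
degenerates exactly to the well-mixed engine (self-hops are no-ops).

The model's 18-channel network runs in numba-compiled loops with an explicit
splitmix64 counter generator (reproducible from the integer seed;
per-subvolume streams are derived from the master seed so enlarging the
lattice does not perturb existing streams). Generic pure-Python engines
accept arbitrary channel lists and are validated against the analytic
birth–death process. Protrusion velocity is always a deterministic function
of the current counts, recomputed at every recorded sample (0.5 min grid by
default), never a stochastic species.

## Phenotype metrics and segmentation

A trace `v(t)` is classified after a burn-in (default 100 min) by its
median: a high baseline (median ≥ 0.5) is *stable protrusion*, or
*protrusion with pauses* if any maximal sub-0.5 dip lasts ≥ 2 min; a low
baseline is *transient protrusions* if any sample exceeds 0.5, else
*minimal protrusion*. Only the 0.5 excursion rule is anchored; the pause
duration, burn-in and median baseline call are package choices exposed as
arguments. Labels are invariant to uniform time rescaling when the two
explicit time parameters are rescaled alongside.

On velocity maps (position × time), protrusion events are 4-connected
regions above 1 nm/s containing at least one cell above 5 nm/s; above-low
regions that never touch a seed are discarded, and masked (undetermined)
cells break connectivity. Total protrusive activity is the summed event
area (cells × spatial step × frame interval) divided by the map duration,
in units of length. Simulated (dimensionless) maps are segmented by
supplying an explicit nm/s-per-unit conversion. Temporal smoothing of
velocity series is a centered 20-frame moving average with shrinking
windows at the boundaries.

The synthetic-map generator places non-adjacent rectangular supra-threshold
event blocks, sub-threshold patches and optional masked regions on a
uniform background with optional Gaussian noise, and emits ground-truth
labels. It emulates the piecewise structure of experimental protrusion
velocity maps — regions above/below the two thresholds — but not their
correlated noise, drift, or irregular event shapes; segmentation tests on
these fixtures therefore validate the connectivity/threshold logic, not
robustness to realistic imaging artifacts.

## Problem sizes used in the checks

The shipped verification runs use scaled study conditions chosen for a
single-CPU workstation: phenotype matrices at `t_end = 300 min` with 5
seeds per cell (15 in the reporting script), engine-consistency comparisons
at 600 min with 8–20 seeds, mean-field convergence at `N* = 300` over
400 min (burn-in 250 min, past the ~200-min deterministic transient), the
multiplicity scan on a 10 × 10 `(k_ecm, E_s)` grid, and 50 synthetic maps
for the segmentation oracle. The full published-scale conditions
(`t_end = 1000 min`, 20 subvolumes) run in seconds to minutes with the
compiled engines and are the library defaults.

## Known limitations

* The base-case rate constants are a reconstruction: they reproduce the
  qualitative bifurcation structure and phenotype ordering described above,
  not a fitted dataset; no fitting to experimental TIRF data is attempted.
* At strong myosin feedback without protrusion inhibition
  (`E_s = 10, I_n = 0`, high ECM) the model is bistable with the high state
  near `v ≈ 0.5`, and small-number (`N* = 3`) trajectories mostly hover low
  with transient bursts rather than protruding stably.
* The lattice is a fixed 1-D virtual edge: no moving boundary, no 2-D Rac
  diffusion, and no exchange of PAK between adhesion-bound and cytosolic
  pools.
* Phase-plane stability labels rest on the quasi-steady reduction; very
  close to fold points the reduced and full Jacobians can disagree, which
  the even-multiplicity flag surfaces.
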